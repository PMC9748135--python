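"""High-level fit pipeline: preprocess -> build -> pretrain -> cluster.

Presets bundle the architecture and loss weights per assay type:

* ``cite`` (RNA + ADT): 16-d latent, encoder {256,64,32,16}, RNA decoder
  {16,64,256}, ADT decoder {16,20}, tau=1, phi=0.001, sigma 2.5/1.5.
* ``smage`` (RNA + ATAC gene activity): 64-d latent, encoder {256,128,64},
  both decoders {64,128,256}, tau=0.1, phi=0.005, sigma 2.5/2.5.

gamma (clustering-loss weight) is 0.1 and the inflation exponent is 2 for
both. Batch conditioning switches on automatically when the dataset carries
batch labels; `conditional=False` forces it off for ablation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data import MultimodalDataset, PreprocessedData, preprocess
from .losses import LossWeights
from .network import Model, NetworkConfig, UnimodalModel
from .trainer import (ClusterResult, TrainConfig, fit_clustering, pretrain,
                      streams_from_preprocessed)

PRESETS = {
    "cite": dict(weights=dict(gamma=0.1, phi=0.001, tau=1.0, alpha_inflation=2.0)),
    "smage": dict(weights=dict(gamma=0.1, phi=0.005, tau=0.1, alpha_inflation=2.0)),
}


def preset_network(data_type: str, n_batches: int = 0) -> NetworkConfig:
    if data_type == "cite":
        return NetworkConfig.cite_preset(n_batches)
    if data_type == "smage":
        return NetworkConfig.smage_preset(n_batches)
    raise ValueError(f"unknown data type {data_type!r}")


def preset_weights(data_type: str) -> LossWeights:
    return LossWeights(**PRESETS[data_type]["weights"])


@dataclass
class FitResult:
    result: ClusterResult
    model: object
    pre: PreprocessedData
    streams: list
    weights: LossWeights
    train_config: TrainConfig


def fit(dataset: MultimodalDataset, k: int, data_type: str = "cite",
        mode: str = "both", n_hvg: Optional[int] = 2000,
        conditional: Optional[bool] = None, seed: int = 0,
        train_config: Optional[TrainConfig] = None,
        net_config: Optional[NetworkConfig] = None,
        weights: Optional[LossWeights] = None) -> FitResult:
    """Run the full clustering pipeline on a paired dataset.

    `mode` selects the model variant: "both" (full bimodal model), "rna" /
    "second" (single-modality sub-models), or "concat" (concatenated input,
    single decoder).
    """
    pre = preprocess(dataset, n_hvg=n_hvg)
    if conditional is None:
        conditional = pre.batch_onehot is not None
    n_batches = pre.batch_onehot.shape[1] if (conditional and pre.batch_onehot is not None) else 0
    batches = pre.batch_onehot if n_batches else None

    cfg = net_config or preset_network(data_type, n_batches)
    if net_config is not None and n_batches and cfg.n_batches != n_batches:
        cfg.n_batches = n_batches
    w = weights or preset_weights(data_type)
    tc = train_config or TrainConfig(K=k, seed=seed)
    tc.K = k

    streams = streams_from_preprocessed(pre, mode)
    if mode == "both":
        model = Model(cfg, (pre.norm_rna.shape[1], pre.norm_second.shape[1]), seed=seed)
    else:
        model = UnimodalModel(cfg, streams[0].norm.shape[1], seed=seed)

    history: list = []
    pretrain(model, streams, tc, w, batches=batches, history=history)
    result = fit_clustering(model, streams, tc, w, batches=batches, history=history)
    return FitResult(result=result, model=model, pre=pre, streams=streams,
                     weights=w, train_config=tc)
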