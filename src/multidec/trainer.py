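"""Two-stage optimization: denoising ZINB pretraining, then deep K-means.

Stage 1 (pretraining, Adam/AMSGrad): minibatch descent on the per-modality
ZINB reconstruction losses; after a configurable number of reconstruction-only
epochs the pairwise-similarity KL self-training term is added. Stage 2
(clustering, Adadelta): K centroids are initialized by K-means on the
pretrained latent space and then optimized jointly with all network weights
under the total loss (reconstruction + gamma * clustering + phi * KL). After
each epoch cells are hard-assigned to the nearest centroid; training stops
when the fraction of cells changing label drops below the tolerance.

Each loss term is averaged over the cells of the minibatch (feature sums are
kept), which leaves the relative term weights unchanged and keeps gradient
scale independent of batch size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from sklearn.cluster import KMeans

from ._autodiff import DTYPE, Tensor, parameter
from ._nn import Adadelta, Adam
from .data import PreprocessedData
from .losses import LossWeights, cluster_loss_t, kl_selftrain_loss_t, zinb_nll_t
from .network import corrupt


@dataclass
class TrainConfig:
    K: int = 8
    pretrain_epochs: int = 400
    pretrain_recon_only_epochs: int = 200
    batch_size: int = 256
    pretrain_lr: float = 0.001
    cluster_lr: float = 1.0
    cluster_rho: float = 0.95
    max_cluster_epochs: int = 500
    label_change_tol: float = 0.001
    kmeans_restarts: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if self.pretrain_recon_only_epochs > self.pretrain_epochs:
            raise ValueError("recon-only epochs cannot exceed pretrain epochs")
        if not 0 < self.label_change_tol < 1:
            raise ValueError("label_change_tol must lie in (0, 1)")


@dataclass
class StreamData:
    """One modality's training arrays: normalized input, raw counts, size factors."""

    norm: np.ndarray
    raw: np.ndarray
    size_factors: np.ndarray


@dataclass
class ClusterResult:
    labels: np.ndarray
    embedding: np.ndarray
    centroids: np.ndarray
    loss_history: List[dict] = field(default_factory=list)
    n_epochs_run: dict = field(default_factory=dict)
    converged: bool = False
    empty_clusters: list = field(default_factory=list)


def streams_from_preprocessed(pre: PreprocessedData, mode: str = "both"):
    """Build trainer streams: 'both', 'rna', 'second', or 'concat'."""
    rna = StreamData(pre.norm_rna.astype(DTYPE), pre.raw_rna, pre.sf_rna)
    sec = StreamData(pre.norm_second.astype(DTYPE), pre.raw_second, pre.sf_second)
    if mode == "both":
        return [rna, sec]
    if mode == "rna":
        return [rna]
    if mode == "second":
        return [sec]
    if mode == "concat":
        raw = np.concatenate([pre.raw_rna, pre.raw_second], axis=1)
        lib = raw.sum(axis=1)
        return [StreamData(
            np.concatenate([pre.norm_rna, pre.norm_second], axis=1).astype(DTYPE),
            raw, lib / np.median(lib))]
    raise ValueError(f"unknown mode {mode!r}")


def _minibatches(n, batch_size, rng):
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start:start + batch_size]


def _recon_loss(model, streams, idx, rng, batches, training=True):
    """Corrupted forward pass and per-stream ZINB losses (mean over cells)."""
    inputs = [Tensor(corrupt(s.norm[idx], sig, rng))
              for s, sig in zip(streams, model.sigmas)]
    b = None if batches is None else batches[idx].astype(DTYPE)
    Z = model.encode_inputs(inputs, b, training=training)
    outs = model.decode_all(Z, [s.size_factors[idx] for s in streams], b,
                            training=training)
    losses = []
    for s, (mu, theta, pi) in zip(streams, outs):
        x = Tensor(s.raw[idx].astype(DTYPE))
        losses.append(zinb_nll_t(x, mu, theta, pi).sum() * (1.0 / len(idx)))
    return Z, losses


def _check_finite(value, epoch, stage):
    if not np.isfinite(value):
        raise FloatingPointError(
            f"non-finite loss ({value}) at {stage} epoch {epoch}")


def pretrain(model, streams, cfg: TrainConfig, weights: LossWeights,
             batches: Optional[np.ndarray] = None, history: Optional[list] = None):
    """Stage-1 training; returns the model (modified in place)."""
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.pretrain_lr, amsgrad=True)
    n = streams[0].norm.shape[0]
    for epoch in range(cfg.pretrain_epochs):
        use_kl = epoch >= cfg.pretrain_recon_only_epochs and weights.phi > 0
        ep_recon = ep_kl = 0.0
        nb = 0
        for idx in _minibatches(n, cfg.batch_size, rng):
            if len(idx) < 2:
                continue
            Z, losses = _recon_loss(model, streams, idx, rng, batches)
            loss = losses[0]
            for extra in losses[1:]:
                loss = loss + extra
            ep_recon += float(loss.data)
            if use_kl:
                lkl = kl_selftrain_loss_t(Z)
                ep_kl += float(lkl.data)
                loss = loss + weights.phi * lkl
            opt.zero_grad()
            loss.backward()
            opt.step()
            nb += 1
        _check_finite(ep_recon, epoch, "pretrain")
        if history is not None:
            history.append({"stage": "pretrain", "epoch": epoch,
                            "recon": ep_recon / nb, "kl": ep_kl / nb})
    return model


def extract_embedding(model, streams, batches: Optional[np.ndarray] = None) -> np.ndarray:
    """Clean-input, evaluation-mode latent coordinates for all cells."""
    inputs = [Tensor(s.norm) for s in streams]
    b = None if batches is None else batches.astype(DTYPE)
    return model.encode_inputs(inputs, b, training=False).data.astype(np.float64)


def init_centroids(Z: np.ndarray, K: int, seed: int = 0, restarts: int = 20) -> np.ndarray:
    """Seeded multi-restart K-means centroids on the latent space."""
    Z = np.asarray(Z, dtype=np.float64)
    if np.unique(Z, axis=0).shape[0] < K:
        raise ValueError("K exceeds the number of distinct latent points")
    km = KMeans(n_clusters=K, n_init=restarts, random_state=seed)
    km.fit(Z)
    return km.cluster_centers_


def predict_labels(Z, V) -> np.ndarray:
    """Nearest-centroid hard assignment; ties go to the lowest centroid index."""
    Z = np.asarray(Z, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    d2 = ((Z[:, None, :] - V[None, :, :]) ** 2).sum(-1) if Z.shape[0] * V.shape[0] < 4_000_000 \
        else (Z * Z).sum(1)[:, None] + (V * V).sum(1)[None, :] - 2 * Z @ V.T
    return np.argmin(np.round(d2, 9), axis=1)


def fit_clustering(model, streams, cfg: TrainConfig, weights: LossWeights,
                   batches: Optional[np.ndarray] = None,
                   history: Optional[list] = None) -> ClusterResult:
    """Stage-2 joint optimization of network weights and centroids."""
    rng = np.random.default_rng(cfg.seed + 1)
    Z0 = extract_embedding(model, streams, batches)
    V = parameter(init_centroids(Z0, cfg.K, cfg.seed, cfg.kmeans_restarts))
    opt = Adadelta(model.parameters() + [V], lr=cfg.cluster_lr, rho=cfg.cluster_rho)
    n = streams[0].norm.shape[0]
    labels = predict_labels(Z0, V.data)
    hist = history if history is not None else []
    converged = False
    epochs_run = 0
    for epoch in range(cfg.max_cluster_epochs):
        ep = {"stage": "cluster", "epoch": epoch, "recon": 0.0, "kl": 0.0,
              "cluster": 0.0}
        nb = 0
        for idx in _minibatches(n, cfg.batch_size, rng):
            if len(idx) < 2:
                continue
            Z, losses = _recon_loss(model, streams, idx, rng, batches)
            loss = losses[0]
            for extra in losses[1:]:
                loss = loss + extra
            ep["recon"] += float(loss.data)
            lc = cluster_loss_t(Z, V, weights.tau, weights.alpha_inflation)
            ep["cluster"] += float(lc.data)
            loss = loss + weights.gamma * lc
            if weights.phi > 0:
                lkl = kl_selftrain_loss_t(Z)
                ep["kl"] += float(lkl.data)
                loss = loss + weights.phi * lkl
            opt.zero_grad()
            loss.backward()
            opt.step()
            nb += 1
        _check_finite(ep["recon"] + ep["cluster"], epoch, "cluster")
        Zc = extract_embedding(model, streams, batches)
        new_labels = predict_labels(Zc, V.data)
        change = float(np.mean(new_labels != labels))
        labels = new_labels
        ep = {k: (v / nb if k not in ("stage", "epoch") else v) for k, v in ep.items()}
        ep["label_change"] = change
        hist.append(ep)
        epochs_run = epoch + 1
        if change < cfg.label_change_tol:
            converged = True
            break
    Zf = extract_embedding(model, streams, batches)
    labels = predict_labels(Zf, V.data)
    empty = [k for k in range(cfg.K) if not np.any(labels == k)]
    return ClusterResult(labels=labels, embedding=Zf, centroids=V.data.copy(),
                         loss_history=hist, n_epochs_run={"cluster": epochs_run},
                         converged=converged, empty_clusters=empty)
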