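"""Perturbation-based marker ranking for clusters.

For a source cluster, we search for the smallest (L1-sparse) shared shift
delta of the normalized feature values that moves the cluster's cells across
the decision boundary toward a target cluster in the latent space. Features
with large |delta| are the ones the encoder relies on to separate the
clusters — the cluster's markers. Cluster membership confidence is the log
softmax of negative (beta-scaled) Euclidean distances to the centroids. A
hinge with margin keeps the objective zero once the assignment has flipped;
the L1 term is handled by proximal soft-thresholding. The resulting ranking
is signed by the log-fold-change direction of each feature and can be
exported as a preranked two-column .rnk file for gene-set enrichment tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np

from ._autodiff import DTYPE, Tensor, maximum, parameter

REST = "rest"


@dataclass
class MarkerConfig:
    lambda_tradeoff: float = 100.0
    margin: float = 1.0
    beta: float = 1.0
    optimizer_steps: int = 500
    step_size: float = 0.01
    mode: str = "one_vs_rest"

    def __post_init__(self):
        if self.lambda_tradeoff < 0 or self.margin < 0 or self.beta <= 0:
            raise ValueError("invalid marker config")


@dataclass
class MarkerTable:
    feature_ids: list
    delta_magnitude: np.ndarray
    direction: np.ndarray
    directed_rank: np.ndarray
    error: Optional[str] = None

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "feature": self.feature_ids,
            "delta_magnitude": self.delta_magnitude,
            "direction": self.direction,
            "directed_rank": self.directed_rank,
        })


def confidence(z, V, beta: float = 1.0) -> np.ndarray:
    """Per-cluster log-softmax confidence of latent point(s) z."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    V = np.asarray(V, dtype=np.float64)
    d = np.sqrt(np.maximum(
        (z * z).sum(1)[:, None] + (V * V).sum(1)[None, :] - 2 * z @ V.T, 0.0))
    logits = -beta * d
    m = logits - logits.max(axis=1, keepdims=True)
    log_softmax = m - np.log(np.exp(m).sum(axis=1, keepdims=True))
    return log_softmax[0] if log_softmax.shape[0] == 1 else log_softmax


def _confidence_t(Z: Tensor, V: Tensor, beta: float) -> Tensor:
    """Differentiable log-softmax confidence matrix (cells x K)."""
    sqz = (Z * Z).sum(axis=1, keepdims=True)
    sqv = (V * V).sum(axis=1, keepdims=True).transpose2()
    d = ((sqz + sqv - 2.0 * (Z @ V.transpose2())).clamp(lo=0.0) + 1e-12).sqrt()
    logits = -beta * d
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    ex = (logits - shift).exp()
    return logits - shift - ex.sum(axis=1, keepdims=True).log()


def find_perturbation(inputs: List[np.ndarray], model, V: np.ndarray,
                      source: int, target: Union[int, str], cfg: MarkerConfig,
                      stream: int = 0, batches: Optional[np.ndarray] = None) -> np.ndarray:
    """Shared per-feature perturbation flipping source-cluster cells to target.

    `inputs` holds the normalized source-cluster cells for each modality
    stream; the perturbation applies to `stream` (0 = RNA). `target` is a
    cluster index or "rest" (flip to whichever other cluster is closest).
    """
    if target == source:
        raise ValueError("source and target clusters must differ")
    n = inputs[0].shape[0]
    if n == 0:
        raise ValueError("source cluster is empty")
    K = V.shape[0]
    p = inputs[stream].shape[1]
    delta = parameter(np.zeros(p))
    Vt = Tensor(np.asarray(V, dtype=DTYPE))
    consts = [Tensor(x.astype(DTYPE)) for x in inputs]
    b = None if batches is None else batches.astype(DTYPE)
    src_mask = np.zeros((1, K), dtype=DTYPE)
    src_mask[0, source] = 1.0
    # exclude the source column (and, in one-vs-one mode, everything else)
    if target == REST:
        excl = -1e9 * src_mask
    else:
        excl = np.full((1, K), -1e9, dtype=DTYPE)
        excl[0, int(target)] = 0.0

    # proximal gradient descent (ISTA): smooth hinge step, then the exact
    # soft-threshold proximal operator of the L1 term
    for _ in range(cfg.optimizer_steps):
        xs = list(consts)
        xs[stream] = consts[stream] + delta
        Z = model.encode_inputs(xs, b, training=False)
        m = _confidence_t(Z, Vt, cfg.beta)
        m_s = (m * Tensor(src_mask)).sum(axis=1)
        m_t = (m + Tensor(excl)).max(axis=1)
        hinge = maximum(cfg.margin + m_s - m_t, 0.0).mean()
        loss = cfg.lambda_tradeoff * hinge
        delta.grad = None
        loss.backward()
        d = delta.data - cfg.step_size * delta.grad
        delta.data = np.sign(d) * np.maximum(np.abs(d) - cfg.step_size, 0.0)
    return delta.data.astype(np.float64).copy()


def direction_vector(norm_counts: np.ndarray, labels: np.ndarray, source: int,
                     target: Union[int, str] = REST, pseudocount: float = 1e-6) -> np.ndarray:
    """Sign (+1/-1) of the log fold change of group means, source vs target."""
    labels = np.asarray(labels)
    in_src = labels == source
    in_other = (labels != source) if target == REST else (labels == target)
    if not in_src.any() or not in_other.any():
        raise ValueError("empty comparison group")
    mu_s = norm_counts[in_src].mean(axis=0) + pseudocount
    mu_o = norm_counts[in_other].mean(axis=0) + pseudocount
    lfc = np.log(mu_s / mu_o)
    return np.where(lfc >= 0, 1, -1).astype(int)  # exact ties map to +1


def rank_and_export(delta: np.ndarray, direction: np.ndarray, feature_ids: list,
                    path: Optional[str] = None) -> MarkerTable:
    """Rank features by |delta| descending, sign by direction, write .rnk."""
    delta = np.asarray(delta, dtype=np.float64)
    direction = np.asarray(direction)
    if delta.shape != direction.shape or len(feature_ids) != delta.size:
        raise ValueError("shape mismatch")
    if np.all(delta == 0):
        return MarkerTable(feature_ids=[], delta_magnitude=np.array([]),
                           direction=np.array([], dtype=int),
                           directed_rank=np.array([]),
                           error="no discriminative signal")
    mag = np.abs(delta)
    order = np.argsort(-mag, kind="stable")
    p = delta.size
    rank_score = np.empty(p)
    rank_score[order] = np.arange(p, 0, -1)  # top feature scores P
    directed = rank_score * direction
    table = MarkerTable(
        feature_ids=[feature_ids[i] for i in order],
        delta_magnitude=mag[order],
        direction=direction[order].astype(int),
        directed_rank=directed[order],
    )
    if path is not None:
        export_order = np.argsort(-directed, kind="stable")
        with open(path, "w") as f:
            for i in export_order:
                f.write(f"{feature_ids[i]}\t{directed[i]:.6g}\n")
    return table


def load_rnk(path: str):
    """Read back a preranked file as (features, scores)."""
    feats, scores = [], []
    with open(path) as f:
        for ln in f:
            if not ln.strip():
                continue
            a, b = ln.rstrip("\n").split("\t")
            feats.append(a)
            scores.append(float(b))
    return feats, np.asarray(scores)
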