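"""Loss functions: ZINB likelihood, pairwise-similarity KL, deep soft K-means.

The reconstruction loss is the zero-inflated negative binomial negative
log-likelihood of the raw counts given per-entry mean, dispersion, and dropout
probability. The self-training loss is a KL divergence between the pairwise
t-kernel similarity of cells in the latent space (Q) and a sharpened target
distribution (P): Q squared, divided by column frequency, renormalized per
row — the classic deep-embedded-clustering target. The clustering loss is a
soft K-means objective with Gaussian-kernel weights sharpened by an inflation
exponent; the weights are treated as constants for gradient purposes.

Each public function has a numpy-facing form; `*_t` variants operate on
autodiff tensors and are used inside training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, maximum

_EPS = 1e-12
# additive guard inside logs of the ZINB mixture; small enough not to distort
# the zero-case likelihood even for very unlikely zeros (P(0) ~ 1e-25)
_TINY = 1e-30


@dataclass
class LossWeights:
    """Term weights: gamma (clustering), phi (KL), tau (distance temperature),
    alpha_inflation (weight-sharpening exponent)."""

    gamma: float = 0.1
    phi: float = 0.001
    tau: float = 1.0
    alpha_inflation: float = 2.0

    def __post_init__(self):
        if min(self.gamma, self.phi, self.tau, self.alpha_inflation) < 0:
            raise ValueError("loss weights must be non-negative")


# ---------------------------------------------------------------------------
# ZINB negative log-likelihood
# ---------------------------------------------------------------------------

def nb_nll_t(x: Tensor, mu: Tensor, theta: Tensor) -> Tensor:
    """Elementwise -log NB(x | mu, theta) via log-gamma, in tensor space."""
    log_theta_mu = (theta + mu).log()
    t1 = (theta + 1e-10).lgamma() + (x + 1.0).lgamma() - (x + theta).lgamma()
    t2 = (theta + x) * log_theta_mu - theta * (theta + 1e-10).log() \
        - x * (mu + 1e-10).log()
    return t1 + t2


def zinb_nll_t(x: Tensor, mu: Tensor, theta: Tensor, pi: Tensor) -> Tensor:
    """Elementwise -log[ pi*I(x=0) + (1-pi)*NB(x|mu,theta) ], tensor space."""
    nb = nb_nll_t(x, mu, theta)
    nonzero_case = -((1.0 - pi) + _EPS).log() + nb
    # P(0) under NB is (theta/(theta+mu))^theta; the mixture probability
    # pi + (1-pi) * P(0) is assembled with a two-term log-sum-exp so that
    # very small P(0) values are not swamped by an additive epsilon
    log_nb0 = theta * ((theta + 1e-10).log() - (theta + mu).log())
    a = (pi + _TINY).log()
    b = ((1.0 - pi) + _TINY).log() + log_nb0
    m = maximum(a, b)
    zero_case = -(m + ((a - m).exp() + (b - m).exp()).log())
    is_zero = Tensor((np.asarray(x.data) < 1e-8).astype(x.data.dtype))
    return is_zero * zero_case + (1.0 - is_zero) * nonzero_case


def nb_nll(x, mu, theta) -> np.ndarray:
    """-log NB(x | mean mu, dispersion theta) (numpy in, numpy/scalar out)."""
    x, mu, theta = (np.asarray(a, dtype=np.float64) for a in (x, mu, theta))
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mu and theta must be positive")
    if np.any(x < 0) or not np.allclose(x, np.round(x)):
        raise ValueError("x must be a non-negative integer count")
    out = nb_nll_t(Tensor(x, dtype=np.float64), Tensor(mu, dtype=np.float64),
                   Tensor(theta, dtype=np.float64)).data
    return out if out.shape else float(out)


def zinb_nll(x, mu, theta, pi) -> np.ndarray:
    """ZINB negative log-likelihood (numpy in, numpy/scalar out)."""
    pi = np.asarray(pi, dtype=np.float64)
    if np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("pi must lie in [0, 1]")
    x, mu, theta = (np.asarray(a, dtype=np.float64) for a in (x, mu, theta))
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mu and theta must be positive")
    out = zinb_nll_t(Tensor(x, dtype=np.float64), Tensor(mu, dtype=np.float64),
                     Tensor(theta, dtype=np.float64), Tensor(pi, dtype=np.float64)).data
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# pairwise similarity Q, target P, and their KL divergence
# ---------------------------------------------------------------------------

def _pairwise_q_data(Z: np.ndarray) -> np.ndarray:
    sq = (Z * Z).sum(axis=1, keepdims=True)
    d2 = np.maximum(sq + sq.T - 2.0 * Z @ Z.T, 0.0)
    kern = 1.0 / (1.0 + d2)
    np.fill_diagonal(kern, 0.0)
    return kern / kern.sum(axis=1, keepdims=True)


def pairwise_q(Z) -> np.ndarray:
    """Row-normalized t-kernel similarity with zero diagonal."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape[0] < 2:
        raise ValueError("at least two cells are required")
    return _pairwise_q_data(Z)


def target_p(Q) -> np.ndarray:
    """Sharpened target: square Q, divide by column frequency, renormalize."""
    Q = np.asarray(Q, dtype=np.float64)
    f = Q.sum(axis=0)  # column frequencies (diagonal is zero already)
    num = Q ** 2 / np.maximum(f, _EPS)
    np.fill_diagonal(num, 0.0)
    denom = num.sum(axis=1, keepdims=True)
    if np.any(denom <= 0):
        raise ValueError("a row of Q is entirely zero")
    return num / denom


def kl_loss(P, Q) -> float:
    """KL(P || Q) with the 0*log(0/.)=0 convention."""
    P, Q = np.asarray(P, dtype=np.float64), np.asarray(Q, dtype=np.float64)
    if P.shape != Q.shape:
        raise ValueError("shape mismatch")
    mask = P > 0
    if np.any(Q[mask] <= 0):
        raise ValueError("Q has zero mass where P is positive")
    return float(np.sum(P[mask] * np.log(P[mask] / Q[mask])))


def kl_selftrain_loss_t(Z: Tensor) -> Tensor:
    """Differentiable KL(P || Q) on a minibatch latent matrix.

    Q is the row-normalized t-kernel with zero diagonal; P is the detached
    sharpened target computed from the current Q.
    """
    n = Z.shape[0]
    sq = (Z * Z).sum(axis=1, keepdims=True)
    sqT = sq.transpose2()
    d2 = sq + sqT - 2.0 * (Z @ Z.transpose2())
    d2 = d2.clamp(lo=0.0)
    kern = 1.0 / (1.0 + d2)
    off = Tensor(1.0 - np.eye(n, dtype=Z.data.dtype))
    kern = kern * off
    Q = kern / kern.sum(axis=1, keepdims=True)
    P = Tensor(target_p(Q.data.astype(np.float64)).astype(Z.data.dtype))
    log_ratio = ((P + _EPS) / (Q + _EPS)).log()
    return (P * log_ratio).sum() * (1.0 / n)


# ---------------------------------------------------------------------------
# deep soft K-means
# ---------------------------------------------------------------------------

def _dists_t(Z: Tensor, V: Tensor) -> Tensor:
    """Euclidean distance matrix between rows of Z (n x d) and V (K x d)."""
    sqz = (Z * Z).sum(axis=1, keepdims=True)
    sqv = (V * V).sum(axis=1, keepdims=True).transpose2()
    d2 = sqz + sqv - 2.0 * (Z @ V.transpose2())
    return (d2.clamp(lo=0.0) + 1e-12).sqrt()


def soft_weights(Z, V, tau: float = 1.0) -> np.ndarray:
    """Pre-inflation soft assignments from a Gaussian kernel on distance."""
    Z = np.asarray(Z, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    if V.shape[0] < 2:
        raise ValueError("need at least two centroids")
    d = np.sqrt(np.maximum(
        (Z * Z).sum(1)[:, None] + (V * V).sum(1)[None, :] - 2 * Z @ V.T, 0.0))
    logits = -d
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def inflate(w: np.ndarray, alpha: float = 2.0) -> np.ndarray:
    """Sharpen soft weights: w^alpha renormalized per row."""
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    wa = np.asarray(w, dtype=np.float64) ** alpha
    return wa / wa.sum(axis=1, keepdims=True)


def cluster_loss(Z, V, W, tau: float = 1.0) -> float:
    """Sum_ij w_ij * tau * ||Z_i - V_j|| with W treated as constants."""
    Z = np.asarray(Z, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    d = np.sqrt(np.maximum(
        (Z * Z).sum(1)[:, None] + (V * V).sum(1)[None, :] - 2 * Z @ V.T, 0.0))
    return float(np.sum(np.asarray(W) * tau * d))


def cluster_loss_t(Z: Tensor, V: Tensor, tau: float, alpha: float) -> Tensor:
    """Differentiable soft K-means loss; weights recomputed and detached."""
    d = _dists_t(Z, V)
    W = inflate(soft_weights(Z.data, V.data), alpha).astype(Z.data.dtype)
    n = Z.shape[0]
    return (Tensor(W) * d).sum() * (tau / n)


def total_loss(recon_rna: float, recon_second: float, Lc: float, Lkl: float,
               weights: LossWeights) -> float:
    """L_mRNA + L_second + gamma*L_c + phi*L_kl."""
    parts = np.array([recon_rna, recon_second, Lc, Lkl], dtype=float)
    if not np.all(np.isfinite(parts)):
        raise ValueError("non-finite loss component")
    return float(recon_rna + recon_second
                 + weights.gamma * Lc + weights.phi * Lkl)
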