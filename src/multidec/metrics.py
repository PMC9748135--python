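"""Clustering agreement indices from contingency tables.

ARI is the pair-counting Rand index adjusted for chance; NMI normalizes the
mutual information by max{H(C), H(G)}; AMI additionally subtracts the
expected mutual information under the permutation (hypergeometric) model.
Natural-log entropies are used throughout (the normalized indices are
base-invariant).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def _contingency(c, g):
    c = np.asarray(c)
    g = np.asarray(g)
    if c.shape != g.shape or c.ndim != 1 or c.size == 0:
        raise ValueError("partitions must be equal-length non-empty 1-D vectors")
    _, ci = np.unique(c, return_inverse=True)
    _, gi = np.unique(g, return_inverse=True)
    table = np.zeros((ci.max() + 1, gi.max() + 1), dtype=np.int64)
    np.add.at(table, (ci, gi), 1)
    return table


def _comb2(x):
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1) / 2.0


def ari(c, g) -> float:
    """Adjusted Rand index in [-1, 1]; 1 means identical partitions."""
    t = _contingency(c, g)
    n = t.sum()
    sum_ij = _comb2(t).sum()
    sum_a = _comb2(t.sum(axis=1)).sum()
    sum_b = _comb2(t.sum(axis=0)).sum()
    total = _comb2(n)
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions degenerate -> identical
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _entropy(counts, n):
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def _mutual_info(t):
    n = t.sum()
    a = t.sum(axis=1)
    b = t.sum(axis=0)
    nz = t > 0
    tij = t[nz].astype(np.float64)
    outer = np.outer(a, b)[nz].astype(np.float64)
    return float((tij / n * np.log(n * tij / outer)).sum())


def nmi(c, g) -> float:
    """Normalized mutual information I / max{H(C), H(G)} in [0, 1]."""
    t = _contingency(c, g)
    n = t.sum()
    hc = _entropy(t.sum(axis=1), n)
    hg = _entropy(t.sum(axis=0), n)
    denom = max(hc, hg)
    if denom == 0:
        # zero entropy on both sides: each partition is a single cluster
        return 1.0
    return float(_mutual_info(t) / denom)


def expected_mutual_info(t) -> float:
    """E{I} under the permutation model with fixed marginals (hypergeometric)."""
    t = np.asarray(t, dtype=np.int64)
    n = int(t.sum())
    a = t.sum(axis=1)
    b = t.sum(axis=0)
    lgn = gammaln(np.arange(n + 2) + 1.0)  # log factorials, lgn[k] = log k!

    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            term = nij / n * (np.log(n * nij) - np.log(ai * bj))
            logp = (lgn[ai] + lgn[bj] + lgn[n - ai] + lgn[n - bj]
                    - lgn[n] - lgn[nij] - lgn[ai - nij] - lgn[bj - nij]
                    - lgn[n - ai - bj + nij])
            emi += float((term * np.exp(logp)).sum())
    return emi


def ami(c, g) -> float:
    """Adjusted mutual information: (I - E{I}) / (max{H} - E{I})."""
    t = _contingency(c, g)
    n = t.sum()
    hc = _entropy(t.sum(axis=1), n)
    hg = _entropy(t.sum(axis=0), n)
    denom_h = max(hc, hg)
    mi = _mutual_info(t)
    emi = expected_mutual_info(t)
    denom = denom_h - emi
    if abs(denom) < 1e-15:
        return 1.0 if nmi(c, g) == 1.0 else 0.0
    return float((mi - emi) / denom)


def evaluate(predicted, truth) -> dict:
    """ARI/NMI/AMI report for a predicted partition against truth labels."""
    return {"ari": ari(predicted, truth), "nmi": nmi(predicted, truth),
            "ami": ami(predicted, truth)}
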