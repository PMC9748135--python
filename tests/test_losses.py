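"""Loss oracles: ZINB vs scipy, Q/P/KL vs double loops, soft K-means algebra."""

import numpy as np
import pytest
from scipy import stats

from multidec.losses import (LossWeights, cluster_loss, cluster_loss_t,
                             inflate, kl_loss, kl_selftrain_loss_t, nb_nll,
                             pairwise_q, soft_weights, target_p, total_loss,
                             zinb_nll)
from multidec._autodiff import Tensor


# ---- negative binomial ----------------------------------------------------

def test_nb_nll_matches_scipy_grid():
    xs = np.array([0, 1, 2, 5, 20, 100])
    for mu in (0.1, 1.0, 7.5, 50.0):
        for theta in (0.2, 1.0, 4.0, 30.0):
            ours = nb_nll(xs, np.full_like(xs, mu, dtype=float),
                          np.full_like(xs, theta, dtype=float))
            ref = -stats.nbinom.logpmf(xs, theta, theta / (theta + mu))
            np.testing.assert_allclose(ours, ref, atol=1e-6)


def test_nb_poisson_limit():
    # theta -> infinity: NB converges to Poisson
    mu, x = 3.0, 4
    ours = nb_nll(x, mu, 1e8)
    ref = -stats.poisson.logpmf(x, mu)
    assert abs(ours - ref) < 1e-5


def test_nb_normalizes_over_truncated_support():
    mu, theta = 2.0, 1.5
    xs = np.arange(0, 400)
    total = np.exp(-nb_nll(xs, np.full(400, mu), np.full(400, theta))).sum()
    assert abs(total - 1.0) < 1e-8


def test_nb_rejects_invalid():
    with pytest.raises(ValueError):
        nb_nll(1, -1.0, 1.0)
    with pytest.raises(ValueError):
        nb_nll(1.5, 1.0, 1.0)


# ---- zero-inflated NB -----------------------------------------------------

def test_zinb_hand_value_at_zero():
    # pi=0.5, NB P(0) = (theta/(theta+mu))^theta with theta=1, mu=3 -> 0.25
    # mixture P(0) = 0.5 + 0.5*0.25 = 0.625
    val = zinb_nll(0, 3.0, 1.0, 0.5)
    np.testing.assert_allclose(val, -np.log(0.625), atol=1e-7)


def test_zinb_nonzero_case_is_shifted_nb():
    x, mu, theta, pi = 4, 3.0, 2.0, 0.3
    np.testing.assert_allclose(
        zinb_nll(x, mu, theta, pi), nb_nll(x, mu, theta) - np.log(1 - pi),
        atol=1e-6)


def test_zinb_pi_zero_reduces_to_nb():
    xs = np.array([0, 1, 5])
    mus = np.array([1.0, 2.0, 3.0])
    thetas = np.array([0.5, 1.5, 2.5])
    np.testing.assert_allclose(zinb_nll(xs, mus, thetas, np.zeros(3)),
                               nb_nll(xs, mus, thetas), atol=1e-6)


def test_zinb_normalizes_over_truncated_support():
    mu, theta, pi = 2.0, 1.5, 0.4
    xs = np.arange(0, 400)
    probs = np.exp(-zinb_nll(xs, np.full(400, mu), np.full(400, theta),
                             np.full(400, pi)))
    assert abs(probs.sum() - 1.0) < 1e-9


def test_zinb_rejects_bad_pi():
    with pytest.raises(ValueError, match="pi"):
        zinb_nll(1, 1.0, 1.0, 1.2)


# ---- pairwise similarity / target / KL ------------------------------------

def _q_loops(Z):
    n = Z.shape[0]
    k = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                k[i, j] = 1.0 / (1.0 + np.sum((Z[i] - Z[j]) ** 2))
    return k / k.sum(axis=1, keepdims=True)


def _p_loops(Q):
    n = Q.shape[0]
    f = Q.sum(axis=0)
    num = np.zeros_like(Q)
    for i in range(n):
        for j in range(n):
            if i != j:
                num[i, j] = Q[i, j] ** 2 / f[j]
    return num / num.sum(axis=1, keepdims=True)


def test_q_and_p_match_double_loops(rng):
    Z = rng.normal(size=(9, 4))
    Q = pairwise_q(Z)
    np.testing.assert_allclose(Q, _q_loops(Z), atol=1e-12)
    np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(np.diag(Q) == 0)
    P = target_p(Q)
    np.testing.assert_allclose(P, _p_loops(Q), atol=1e-12)
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


def test_target_p_hand_value():
    # one row (0.8, 0.2) off-diagonal in a 3-cell symmetric toy
    Q = np.array([[0.0, 0.8, 0.2],
                  [0.8, 0.0, 0.2],
                  [0.5, 0.5, 0.0]])
    P = target_p(Q)
    f = Q.sum(axis=0)
    expect0 = np.array([0.0, 0.64 / f[1], 0.04 / f[2]])
    expect0 /= expect0.sum()
    np.testing.assert_allclose(P[0], expect0, atol=1e-12)
    # the textbook two-option case: (0.8, 0.2) with equal frequencies
    num = np.array([0.64, 0.04])
    np.testing.assert_allclose(num / num.sum(), [0.941176, 0.058824], atol=1e-5)


def test_kl_loss_oracle(rng):
    Z = rng.normal(size=(8, 3))
    Q = pairwise_q(Z)
    P = target_p(Q)
    expect = sum(P[i, j] * np.log(P[i, j] / Q[i, j])
                 for i in range(8) for j in range(8) if P[i, j] > 0)
    np.testing.assert_allclose(kl_loss(P, Q), expect, atol=1e-12)
    assert kl_loss(P, Q) >= 0
    assert kl_loss(Q, Q) == pytest.approx(0.0, abs=1e-12)


def test_kl_selftrain_tensor_matches_numpy_chain(rng):
    Z = rng.normal(size=(12, 5))
    t = kl_selftrain_loss_t(Tensor(Z, dtype=np.float64))
    Q = pairwise_q(Z)
    np.testing.assert_allclose(float(t.data), kl_loss(target_p(Q), Q) / 12,
                               rtol=1e-6)


# ---- soft K-means ---------------------------------------------------------

def test_soft_weights_rows_sum_to_one(rng):
    Z = rng.normal(size=(20, 4))
    V = rng.normal(size=(5, 4))
    W = soft_weights(Z, V)
    np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(W > 0)
    # nearest centroid gets the largest weight
    d = np.linalg.norm(Z[:, None] - V[None], axis=2)
    np.testing.assert_array_equal(np.argmax(W, axis=1), np.argmin(d, axis=1))


def test_inflate_identity_and_hand_value():
    w = np.array([[0.6, 0.4]])
    np.testing.assert_allclose(inflate(w, 1.0), w)
    out = inflate(w, 2.0)
    np.testing.assert_allclose(out, [[0.36 / 0.52, 0.16 / 0.52]], atol=1e-12)
    with pytest.raises(ValueError):
        inflate(w, 0.5)


def test_cluster_loss_oracle(rng):
    Z = rng.normal(size=(10, 3))
    V = rng.normal(size=(4, 3))
    W = inflate(soft_weights(Z, V), 2.0)
    tau = 0.7
    expect = sum(W[i, j] * tau * np.linalg.norm(Z[i] - V[j])
                 for i in range(10) for j in range(4))
    np.testing.assert_allclose(cluster_loss(Z, V, W, tau), expect, atol=1e-10)
    t = cluster_loss_t(Tensor(Z, dtype=np.float64), Tensor(V, dtype=np.float64),
                       tau, 2.0)
    np.testing.assert_allclose(float(t.data), expect / 10, rtol=1e-6)


def test_total_loss_is_weighted_sum():
    w = LossWeights(gamma=0.1, phi=0.001, tau=1.0)
    assert total_loss(2.0, 3.0, 10.0, 100.0, w) == pytest.approx(2 + 3 + 1.0 + 0.1)
    with pytest.raises(ValueError, match="non-finite"):
        total_loss(np.nan, 0, 0, 0, w)


def test_loss_weights_validation():
    with pytest.raises(ValueError):
        LossWeights(gamma=-0.1)
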