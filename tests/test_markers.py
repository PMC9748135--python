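"""Marker discovery: confidence function, perturbation search, export."""

import numpy as np
import pytest

from multidec.markers import (MarkerConfig, confidence, direction_vector,
                              find_perturbation, load_rnk, rank_and_export)


def test_marker_config_validation():
    MarkerConfig()
    with pytest.raises(ValueError):
        MarkerConfig(lambda_tradeoff=-1)
    with pytest.raises(ValueError):
        MarkerConfig(beta=0)


# ---- confidence -----------------------------------------------------------

def test_confidence_log_probabilities_sum_to_one(rng):
    z = rng.normal(size=(5, 3))
    V = rng.normal(size=(4, 3))
    m = confidence(z, V, beta=1.3)
    np.testing.assert_allclose(np.exp(m).sum(axis=1), 1.0, atol=1e-12)
    assert np.all(m < 0)


def test_confidence_prefers_nearest_centroid(rng):
    V = rng.normal(size=(4, 3)) * 5
    for k in range(4):
        m = confidence(V[k] + 1e-3, V)
        assert np.argmax(m) == k


def test_confidence_translation_invariance(rng):
    z = rng.normal(size=(3, 2))
    V = rng.normal(size=(3, 2))
    shift = rng.normal(size=(1, 2))
    np.testing.assert_allclose(confidence(z, V), confidence(z + shift, V + shift),
                               atol=1e-9)


def test_confidence_equidistant_is_uniform():
    V = np.array([[1.0, 0.0], [-1.0, 0.0]])
    m = confidence(np.array([0.0, 5.0]), V)
    np.testing.assert_allclose(np.exp(m), [0.5, 0.5], atol=1e-12)


# ---- perturbation search --------------------------------------------------

class _IdentityEncoder:
    """Model stub whose latent space is the input itself."""

    def encode_inputs(self, inputs, batches=None, training=False):
        return inputs[0]


def test_lambda_zero_gives_zero_delta(rng):
    X = rng.normal(size=(6, 2)).astype(np.float32)
    V = np.array([[0.0, 0.0], [5.0, 5.0]])
    cfg = MarkerConfig(lambda_tradeoff=0.0, optimizer_steps=20)
    delta = find_perturbation([X], _IdentityEncoder(), V, 0, 1, cfg)
    np.testing.assert_array_equal(delta, 0.0)


def test_perturbation_moves_toward_target():
    # cells sit at centroid 0; the search should push them toward centroid 1
    X = np.zeros((8, 2), dtype=np.float32)
    V = np.array([[0.0, 0.0], [6.0, 0.0]])
    cfg = MarkerConfig(optimizer_steps=200, step_size=0.05)
    delta = find_perturbation([X], _IdentityEncoder(), V, 0, 1, cfg)
    assert delta[0] > 1.0          # motion along the separating axis
    assert abs(delta[1]) < 0.2     # sparsity keeps the useless axis near zero


def test_perturbation_rest_mode_picks_closest_other():
    X = np.zeros((8, 2), dtype=np.float32)
    V = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 40.0]])
    cfg = MarkerConfig(optimizer_steps=200, step_size=0.05)
    delta = find_perturbation([X], _IdentityEncoder(), V, 0, "rest", cfg)
    assert delta[0] > 0.5 and abs(delta[1]) < 0.2  # flips to cluster 1, not 2


def test_perturbation_input_validation():
    cfg = MarkerConfig()
    with pytest.raises(ValueError, match="differ"):
        find_perturbation([np.zeros((2, 2), np.float32)], _IdentityEncoder(),
                          np.zeros((2, 2)), 0, 0, cfg)
    with pytest.raises(ValueError, match="empty"):
        find_perturbation([np.zeros((0, 2), np.float32)], _IdentityEncoder(),
                          np.zeros((2, 2)), 0, 1, cfg)


# ---- direction and export -------------------------------------------------

def test_direction_vector_signs():
    counts = np.array([[10.0, 0.0], [12.0, 0.0], [1.0, 5.0], [2.0, 6.0]])
    labels = np.array([0, 0, 1, 1])
    d = direction_vector(counts, labels, 0)
    np.testing.assert_array_equal(d, [1, -1])
    np.testing.assert_array_equal(direction_vector(counts, labels, 1), [-1, 1])
    # exact tie maps to +1
    tied = np.ones((4, 1))
    np.testing.assert_array_equal(direction_vector(tied, labels, 0), [1])
    with pytest.raises(ValueError, match="empty"):
        direction_vector(counts, labels, 5)


def test_rank_and_export_round_trip(tmp_path):
    delta = np.array([0.1, -3.0, 0.0, 2.0])
    direction = np.array([1, -1, 1, 1])
    feats = ["a", "b", "c", "d"]
    path = str(tmp_path / "out.rnk")
    table = rank_and_export(delta, direction, feats, path)
    # ordering by |delta| descending: b, d, a, c with rank scores 4,3,2,1
    assert table.feature_ids == ["b", "d", "a", "c"]
    np.testing.assert_allclose(table.delta_magnitude, [3.0, 2.0, 0.1, 0.0])
    np.testing.assert_allclose(table.directed_rank, [-4.0, 3.0, 2.0, 1.0])
    back_feats, back_scores = load_rnk(path)
    # the file is sorted by directed score descending
    assert back_feats == ["d", "a", "c", "b"]
    np.testing.assert_allclose(back_scores, [3.0, 2.0, 1.0, -4.0])
    assert table.error is None
    frame = table.to_frame()
    assert list(frame.columns) == ["feature", "delta_magnitude", "direction",
                                   "directed_rank"]


def test_rank_and_export_all_zero_is_flagged():
    table = rank_and_export(np.zeros(3), np.ones(3, dtype=int), ["a", "b", "c"])
    assert table.error == "no discriminative signal"
    assert table.feature_ids == []


def test_rank_and_export_shape_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        rank_and_export(np.ones(3), np.ones(2), ["a", "b", "c"])


# ---- end-to-end on the trained fixture ------------------------------------

def test_planted_markers_recovered(tiny_fit):
    """On a fitted model the top-ranked perturbation features for a cluster are
    enriched for that cluster's planted exclusive markers."""
    out, fr = tiny_fit
    pre = fr.pre
    res = fr.result
    truth = out.dataset.truth_labels
    planted = out.ground_truth["rna"]["marker_genes"]

    # pick the predicted cluster best matching true group 0
    overlap = [np.sum((res.labels == c) & (truth == 0))
               for c in range(res.centroids.shape[0])]
    c = int(np.argmax(overlap))
    sel = res.labels == c
    assert sel.sum() > 10

    cfg = MarkerConfig(optimizer_steps=300)
    delta = find_perturbation(
        [pre.norm_rna[sel], pre.norm_second[sel]], fr.model, res.centroids,
        c, "rest", cfg, stream=0)
    top10 = np.argsort(-np.abs(delta), kind="stable")[:10]

    # which true group dominates this predicted cluster
    g = int(np.bincount(truth[sel]).argmax())
    marker_set = set(planted[g])
    hits = sum(1 for j in top10 if int(j) in marker_set)
    # 10 planted markers among 150 genes: chance ~0.67 hits in the top 10
    assert hits >= 3
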