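"""Count I/O and preprocessing contracts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from multidec.data import (BatchMatrix, CountMatrix, MultimodalDataset,
                           SizeFactors, compute_size_factors, encode_batches,
                           filter_zero_features, load_counts, normalize,
                           preprocess, save_counts, select_hvg)


def _toy(seed=0, n=12, p=7, modality="RNA"):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(3.0, size=(n, p))
    counts[:, 0] += 1  # avoid an all-zero first column
    return CountMatrix(counts, [f"c{i}" for i in range(n)],
                       [f"f{j}" for j in range(p)], modality)


# ---- containers -----------------------------------------------------------

def test_countmatrix_rejects_bad_input():
    with pytest.raises(ValueError, match="negative"):
        CountMatrix([[1, -1]], ["a"], ["x", "y"])
    with pytest.raises(ValueError, match="non-integral"):
        CountMatrix([[1.5, 2.0]], ["a"], ["x", "y"])
    with pytest.raises(ValueError, match="duplicate cell"):
        CountMatrix([[1], [2]], ["a", "a"], ["x"])
    with pytest.raises(ValueError, match="duplicate feature"):
        CountMatrix([[1, 2]], ["a"], ["x", "x"])
    with pytest.raises(ValueError, match="modality"):
        CountMatrix([[1]], ["a"], ["x"], modality="PROT")


def test_dataset_requires_aligned_cells():
    rna = _toy(0)
    adt = _toy(1, modality="ADT")
    MultimodalDataset(rna, adt)  # same generated ids -> fine
    shuffled = CountMatrix(adt.counts, list(reversed(adt.cell_ids)),
                           adt.feature_ids, "ADT")
    with pytest.raises(ValueError, match="identical cell ids"):
        MultimodalDataset(rna, shuffled)


# ---- round trips ----------------------------------------------------------

@pytest.mark.parametrize("fmt,fname", [
    ("csv", "m.csv"), ("mtx", "m.mtx"), ("h5", "m.h5"),
])
def test_save_load_round_trip(tmp_path, fmt, fname):
    cm = _toy(3)
    path = str(tmp_path / fname)
    save_counts(cm, path, format=fmt)
    back = load_counts(path, modality="RNA")
    np.testing.assert_array_equal(back.counts, cm.counts)
    assert back.cell_ids == cm.cell_ids
    assert back.feature_ids == cm.feature_ids


def test_load_csv_transpose(tmp_path):
    cm = _toy(4, n=5, p=9)
    import pandas as pd
    path = str(tmp_path / "t.csv")
    pd.DataFrame(cm.counts.T, index=cm.feature_ids, columns=cm.cell_ids).to_csv(path)
    back = load_counts(path, transpose=True)
    np.testing.assert_array_equal(back.counts, cm.counts)
    assert back.cell_ids == cm.cell_ids


def test_load_missing_or_unknown(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_counts(str(tmp_path / "nope.csv"))
    bad = tmp_path / "data.xyz"
    bad.write_text("1,2\n")
    with pytest.raises(ValueError, match="cannot infer"):
        load_counts(str(bad))


# ---- preprocessing --------------------------------------------------------

def test_filter_zero_features_drops_only_empty():
    counts = np.array([[1, 0, 2], [0, 0, 3]])
    cm = CountMatrix(counts, ["a", "b"], ["x", "y", "z"])
    out = filter_zero_features(cm)
    assert out.feature_ids == ["x", "z"]
    # idempotent: second pass returns the same object contents
    again = filter_zero_features(out)
    np.testing.assert_array_equal(again.counts, out.counts)


def test_size_factors_median_normalized():
    counts = np.diag([100, 200, 300])
    cm = CountMatrix(counts, ["a", "b", "c"], ["x", "y", "z"])
    np.testing.assert_allclose(compute_size_factors(cm).values, [0.5, 1.0, 1.5])


def test_size_factors_scaling_invariance():
    cm = _toy(5)
    sf1 = compute_size_factors(cm).values
    doubled = CountMatrix(cm.counts * 2, cm.cell_ids, cm.feature_ids)
    np.testing.assert_allclose(compute_size_factors(doubled).values, sf1, rtol=1e-12)


def test_size_factors_reject_empty_cell():
    counts = np.array([[1, 2], [0, 0]])
    cm = CountMatrix(counts, ["a", "b"], ["x", "y"])
    with pytest.raises(ValueError, match="zero library"):
        compute_size_factors(cm)


def test_normalize_zero_mean_unit_variance():
    cm = _toy(6, n=30, p=10)
    out = normalize(cm, compute_size_factors(cm)).values
    np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)
    live = cm.counts.std(axis=0) > 0
    np.testing.assert_allclose(out.std(axis=0)[live], 1.0, atol=1e-10)


def test_normalize_single_count_log_value():
    # equal libraries -> unit size factors -> log1p(counts) then standardize;
    # column [1, 0]: log(2) and 0 -> standardized to +1 / -1
    counts = np.array([[1, 3], [0, 4]])
    cm = CountMatrix(counts, ["a", "b"], ["x", "y"])
    sf = SizeFactors(np.array([1.0, 1.0]))
    out = normalize(cm, sf).values
    np.testing.assert_allclose(out[:, 0], [1.0, -1.0], atol=1e-12)


def test_normalize_constant_feature_is_zero_column():
    counts = np.array([[2, 5], [2, 7], [2, 9]])
    cm = CountMatrix(counts, ["a", "b", "c"], ["x", "y"])
    out = normalize(cm, SizeFactors(np.ones(3))).values
    np.testing.assert_allclose(out[:, 0], 0.0)


def test_select_hvg_picks_most_variable():
    rng = np.random.default_rng(7)
    quiet = rng.poisson(5, size=(50, 8))
    loud = np.concatenate([rng.poisson(1, (25, 2)), rng.poisson(40, (25, 2))])
    cm = CountMatrix(np.hstack([quiet, loud]), [f"c{i}" for i in range(50)],
                     [f"f{j}" for j in range(10)])
    idx = select_hvg(cm, 2, SizeFactors(np.ones(50)))
    assert set(idx) == {8, 9}
    assert list(idx) == sorted(idx)  # returned in ascending feature order
    with pytest.raises(ValueError, match="requested"):
        select_hvg(cm, 11)


def test_encode_batches_first_appearance_order():
    bm = encode_batches(["b", "a", "b", "c"])
    assert bm.batch_names == ["b", "a", "c"]
    np.testing.assert_array_equal(bm.labels, [0, 1, 0, 2])
    np.testing.assert_allclose(bm.onehot.sum(axis=1), 1.0)
    with pytest.raises(ValueError, match="empty"):
        encode_batches([])


@given(st.lists(st.sampled_from("abcd"), min_size=1, max_size=40))
def test_encode_batches_onehot_rows_sum_to_one(labels):
    bm = encode_batches(labels)
    assert bm.onehot.shape == (len(labels), len(set(labels)))
    np.testing.assert_allclose(bm.onehot.sum(axis=1), 1.0)


def test_preprocess_applies_hvg_to_rna_not_adt():
    rna = _toy(8, n=20, p=50)
    adt = _toy(9, n=20, p=10, modality="ADT")
    ds = MultimodalDataset(rna, adt)
    pre = preprocess(ds, n_hvg=15)
    assert pre.norm_rna.shape[1] == 15
    assert pre.norm_second.shape[1] == adt.n_features  # ADT used in full
    assert pre.raw_rna.shape == pre.norm_rna.shape
    assert pre.cell_ids == rna.cell_ids
    # size-factor-normalized counts kept for marker direction calls
    np.testing.assert_allclose(
        pre.sf_normed_second, adt.counts / pre.sf_second[:, None])
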