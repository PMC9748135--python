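"""Count-matrix containers, readers/writers, and preprocessing.

The raw material is a pair of aligned cells x features non-negative integer
count matrices over the same cells: mRNA counts plus either ADT (surface
protein) counts or gene-level ATAC activity counts. Preprocessing follows the
standard deep-count-autoencoder recipe: drop features with no counts, compute
median-of-library-size size factors, divide counts by the cell's size factor,
log1p-transform, and standardize each feature to zero mean / unit variance.
Raw counts are retained because the ZINB reconstruction loss is evaluated on
them, not on the normalized values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

MODALITIES = ("RNA", "ADT", "ATAC")


@dataclass
class CountMatrix:
    """Cells x features non-negative integer counts for one modality."""

    counts: np.ndarray
    cell_ids: list
    feature_ids: list
    modality: str = "RNA"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if sparse.issparse(self.counts):  # pragma: no cover - defensive
            self.counts = self.counts.toarray()
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(self.counts < 0):
            raise ValueError("negative count entries are not allowed")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("non-integral count entries are not allowed")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, p = self.counts.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {p} columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if len(set(self.feature_ids)) != p:
            raise ValueError("duplicate feature ids")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def subset_features(self, idx: Sequence[int]) -> "CountMatrix":
        idx = np.asarray(idx, dtype=int)
        return CountMatrix(self.counts[:, idx], self.cell_ids,
                           [self.feature_ids[i] for i in idx], self.modality)


@dataclass
class SizeFactors:
    """Per-cell library size divided by the median library size."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("size factors must be positive")


@dataclass
class NormalizedMatrix:
    values: np.ndarray
    source_modality: str = "RNA"


@dataclass
class BatchMatrix:
    onehot: np.ndarray
    batch_names: list

    @property
    def n_batches(self) -> int:
        return self.onehot.shape[1]

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.onehot, axis=1)


@dataclass
class MultimodalDataset:
    """Two aligned count matrices plus optional batch and truth labels."""

    rna: CountMatrix
    second: CountMatrix
    batches: Optional[BatchMatrix] = None
    truth_labels: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.rna.cell_ids != self.second.cell_ids:
            raise ValueError("modalities must share identical cell ids in identical order")
        if self.truth_labels is not None:
            self.truth_labels = np.asarray(self.truth_labels)
            if len(self.truth_labels) != self.rna.n_cells:
                raise ValueError("truth labels length mismatch")
        if self.batches is not None and self.batches.onehot.shape[0] != self.rna.n_cells:
            raise ValueError("batch matrix row count mismatch")

    @property
    def n_cells(self) -> int:
        return self.rna.n_cells


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------

def load_counts(path: str, format: str = None, modality: str = "RNA",
                transpose: bool = False) -> CountMatrix:
    """Load a count matrix from mtx (+sidecars), delimited text, or HDF5.

    `transpose=True` declares the file as features x cells and flips it to the
    internal cells x features orientation.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "csv", ".txt": "csv",
                  ".h5": "h5", ".hdf5": "h5"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer format from {path!r}")
    if format == "mtx":
        mat = spio.mmread(path).toarray()
        base = os.path.dirname(path)
        rows = _read_lines(os.path.join(base, "barcodes.tsv"))
        cols = _read_lines(os.path.join(base, "features.tsv"))
        if transpose:
            mat, rows, cols = mat.T, cols, rows
        if mat.shape != (len(rows), len(cols)):
            raise ValueError("matrix shape does not match sidecar id files")
        cm = CountMatrix(mat, rows, cols, modality)
    elif format == "csv":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        if transpose:
            df = df.T
        cm = CountMatrix(df.to_numpy(), list(df.index), list(df.columns), modality)
    elif format == "h5":
        with h5py.File(path, "r") as f:
            g = f["matrix"]
            data = sparse.csc_matrix(
                (g["data"][:], g["indices"][:], g["indptr"][:]),
                shape=tuple(g["shape"][:]),
            ).toarray()
            barcodes = [b.decode() for b in g["barcodes"][:]]
            features = [b.decode() for b in g["features/id"][:]]
        # 10x layout stores features x cells
        mat = data.T if not transpose else data
        cm = CountMatrix(mat, barcodes, features, modality)
    else:
        raise ValueError(f"unknown format {format!r}")
    return cm


def save_counts(cm: CountMatrix, path: str, format: str = "csv") -> None:
    """Write a count matrix in a format `load_counts` can read back."""
    if format == "csv":
        pd.DataFrame(cm.counts, index=cm.cell_ids, columns=cm.feature_ids).to_csv(path)
    elif format == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(cm.counts))
        base = os.path.dirname(path)
        _write_lines(os.path.join(base, "barcodes.tsv"), cm.cell_ids)
        _write_lines(os.path.join(base, "features.tsv"), cm.feature_ids)
    elif format == "h5":
        csc = sparse.csc_matrix(cm.counts.T)  # features x cells, 10x layout
        with h5py.File(path, "w") as f:
            g = f.create_group("matrix")
            g.create_dataset("data", data=csc.data)
            g.create_dataset("indices", data=csc.indices)
            g.create_dataset("indptr", data=csc.indptr)
            g.create_dataset("shape", data=np.asarray(csc.shape))
            g.create_dataset("barcodes", data=np.array(cm.cell_ids, dtype="S"))
            g.create_group("features").create_dataset(
                "id", data=np.array(cm.feature_ids, dtype="S"))
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_lines(path):
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing sidecar file {path}")
    with open(path) as f:
        return [ln.strip().split("\t")[0] for ln in f if ln.strip()]


def _write_lines(path, lines):
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def filter_zero_features(m: CountMatrix) -> CountMatrix:
    """Keep exactly the features with a nonzero total count (order preserved)."""
    keep = np.flatnonzero(m.counts.sum(axis=0) > 0)
    if keep.size == 0:
        raise ValueError("no expressed features after filtering")
    if keep.size == m.n_features:
        return m
    return m.subset_features(keep)


def compute_size_factors(m: CountMatrix) -> SizeFactors:
    lib = m.counts.sum(axis=1).astype(float)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        ids = [m.cell_ids[i] for i in zero[:10]]
        raise ValueError(f"cells with zero library size: {ids}")
    return SizeFactors(lib / np.median(lib))


def normalize(m: CountMatrix, s: SizeFactors) -> NormalizedMatrix:
    """Size-factor scale, log1p, then standardize each feature.

    Features that are constant after scaling are mapped to all-zero columns
    instead of dividing by a zero standard deviation.
    """
    if len(s.values) != m.n_cells:
        raise ValueError("size factor / cell count mismatch")
    x = np.log1p(m.counts / s.values[:, None])
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    out = (x - mu) / sd_safe
    out[:, sd == 0] = 0.0
    return NormalizedMatrix(out, m.modality)


def select_hvg(m: CountMatrix, n: int, size_factors: Optional[SizeFactors] = None) -> np.ndarray:
    """Indices of the `n` most variable features.

    Variability is the variance of log-normalized expression; ADT matrices are
    low-dimensional and are used in full (callers skip selection for them).
    """
    if n > m.n_features:
        raise ValueError(f"requested {n} features but matrix has {m.n_features}")
    s = size_factors if size_factors is not None else compute_size_factors(m)
    x = np.log1p(m.counts / s.values[:, None])
    var = x.var(axis=0)
    order = np.argsort(-var, kind="stable")
    return np.sort(order[:n])


def encode_batches(labels: Sequence[str]) -> BatchMatrix:
    """One-hot encode batch labels; columns ordered by first appearance."""
    labels = [str(x) for x in labels]
    if not labels:
        raise ValueError("empty batch label vector")
    names = list(dict.fromkeys(labels))
    index = {b: j for j, b in enumerate(names)}
    onehot = np.zeros((len(labels), len(names)), dtype=float)
    for i, b in enumerate(labels):
        onehot[i, index[b]] = 1.0
    return BatchMatrix(onehot, names)


@dataclass
class PreprocessedData:
    """Everything the model consumes, for both modalities."""

    raw_rna: np.ndarray
    raw_second: np.ndarray
    norm_rna: np.ndarray
    norm_second: np.ndarray
    sf_rna: np.ndarray
    sf_second: np.ndarray
    rna_feature_ids: list
    second_feature_ids: list
    cell_ids: list
    second_modality: str
    batch_onehot: Optional[np.ndarray] = None
    sf_normed_rna: np.ndarray = field(default=None, repr=False)
    sf_normed_second: np.ndarray = field(default=None, repr=False)


def preprocess(ds: MultimodalDataset, n_hvg: Optional[int] = 2000) -> PreprocessedData:
    """Full preprocessing pipeline for a paired dataset.

    Highly variable feature selection is applied to RNA (and ATAC) but not to
    ADT, which is used in full. Size factors are computed globally over all
    cells; batch structure is handled downstream by the conditional network.
    """
    rna = filter_zero_features(ds.rna)
    second = filter_zero_features(ds.second)
    sf_r = compute_size_factors(rna)
    sf_s = compute_size_factors(second)
    if n_hvg is not None and n_hvg < rna.n_features:
        rna = rna.subset_features(select_hvg(rna, n_hvg, sf_r))
    if ds.second.modality == "ATAC" and n_hvg is not None and n_hvg < second.n_features:
        second = second.subset_features(select_hvg(second, n_hvg, sf_s))
    norm_r = normalize(rna, sf_r)
    norm_s = normalize(second, sf_s)
    return PreprocessedData(
        raw_rna=rna.counts.astype(float),
        raw_second=second.counts.astype(float),
        norm_rna=norm_r.values,
        norm_second=norm_s.values,
        sf_rna=sf_r.values,
        sf_second=sf_s.values,
        rna_feature_ids=rna.feature_ids,
        second_feature_ids=second.feature_ids,
        cell_ids=rna.cell_ids,
        second_modality=second.modality,
        batch_onehot=None if ds.batches is None else ds.batches.onehot,
        sf_normed_rna=rna.counts / sf_r.values[:, None],
        sf_normed_second=second.counts / sf_s.values[:, None],
    )
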