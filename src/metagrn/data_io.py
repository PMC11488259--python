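"""Count-matrix I/O, normalization, PCA embedding and gene selection.

All downstream stages consume two in-memory containers defined here: a
:class:`CountMatrix` of raw UMI counts (genes x cells) and an
:class:`Embedding` of cells in principal-component space.  Raw counts are
kept for the negative-binomial background models and metacell aggregation;
the normalized/log-transformed matrix is used only for the geometric steps
(PCA, sketching) and for regression inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class FormatError(ValueError):
    """Malformed input file (bad header, wrong column count, ...)."""


@dataclass
class CountMatrix:
    """Raw UMI counts, genes x cells, with identifier lists.

    Parameters
    ----------
    values
        Non-negative integer matrix of shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Ordered, unique identifiers matching the matrix dimensions.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("count matrix must be two-dimensional")
        if not np.issubdtype(values.dtype, np.integer):
            frac, _ = np.modf(values)
            bad = np.argwhere(frac != 0)
            if bad.size:
                g, c = bad[0]
                raise ValueError(
                    f"non-integer count at gene {g}, cell {c}: {values[g, c]!r}"
                )
            values = values.astype(np.int64)
        neg = np.argwhere(values < 0)
        if neg.size:
            g, c = neg[0]
            raise ValueError(f"negative count at gene {g}, cell {c}: {values[g, c]}")
        self.values = values
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell identifiers")
        if values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match identifier lists "
                f"({len(self.gene_ids)} genes, {len(self.cell_ids)} cells)"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Total UMI count per cell."""
        return self.values.sum(axis=0)

    def subset_genes(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.values[idx], [self.gene_ids[i] for i in idx], list(self.cell_ids)
        )


@dataclass
class Embedding:
    """Cells projected onto the top principal components.

    ``coords`` rows align with the cell order of the matrix the PCA was
    computed from; ``eigenvalues`` are the component variances, sorted
    non-increasing.
    """

    coords: np.ndarray
    eigenvalues: np.ndarray
    n_pcs: int = field(default=0)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.n_pcs == 0:
            self.n_pcs = self.coords.shape[1]
        if self.coords.shape[1] != self.n_pcs:
            raise ValueError("coords width does not match n_pcs")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be sorted non-increasing")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class GeneSelection:
    """Indices of selected genes and of the candidate regulators among them."""

    gene_indices: np.ndarray
    regulator_indices: np.ndarray  # indices into the *original* gene list
    dispersion: np.ndarray


def _load_csv(path: Path, sep: str) -> CountMatrix:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: header line defines no cell columns")
    return CountMatrix(df.to_numpy(), list(df.index), list(df.columns))


def _load_mtx(path: Path) -> CountMatrix:
    path = Path(path)
    directory = path.parent
    genes_file = directory / "genes.tsv"
    barcodes_file = directory / "barcodes.tsv"
    if not genes_file.exists() or not barcodes_file.exists():
        raise FileNotFoundError(
            f"MTX input requires companion files {genes_file} and {barcodes_file}"
        )
    try:
        mat = spio.mmread(path)
    except Exception as exc:
        raise FormatError(f"cannot parse MatrixMarket file {path}: {exc}") from exc
    genes = pd.read_csv(genes_file, sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(barcodes_file, sep="\t", header=None)[0].astype(str).tolist()
    dense = np.asarray(sparse.coo_matrix(mat).todense())
    return CountMatrix(dense, genes, cells)


def load_counts(path, format: str | None = None) -> CountMatrix:
    """Read a genes x cells UMI count matrix.

    ``format`` is one of ``mtx``, ``csv``, ``tsv``; inferred from the file
    suffix when omitted.  MTX reads 1-based MatrixMarket triplets with
    ``genes.tsv`` / ``barcodes.tsv`` companions in the same directory.
    Genes with all-zero counts are retained (filtering is explicit
    elsewhere).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv"}.get(path.suffix)
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path}")
    if format == "mtx":
        return _load_mtx(path)
    if format == "csv":
        return _load_csv(path, ",")
    if format == "tsv":
        return _load_csv(path, "\t")
    raise ValueError(f"unknown format {format!r}")


def write_counts(counts: CountMatrix, path, format: str = "mtx") -> None:
    """Write a CountMatrix; inverse of :func:`load_counts`."""
    path = Path(path)
    if format == "mtx":
        path.parent.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path, sparse.coo_matrix(counts.values))
        pd.Series(counts.gene_ids).to_csv(
            path.parent / "genes.tsv", sep="\t", header=False, index=False
        )
        pd.Series(counts.cell_ids).to_csv(
            path.parent / "barcodes.tsv", sep="\t", header=False, index=False
        )
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        pd.DataFrame(
            counts.values, index=counts.gene_ids, columns=counts.cell_ids
        ).to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown format {format!r}")


def normalize_counts(counts: CountMatrix, target_size="median") -> np.ndarray:
    """Library-size normalize and log-transform, for PCA/sketching.

    Each cell's counts are scaled to a common library size (the median
    library size by default) and then log-transformed with pseudocount 1.
    All-zero cells are flagged with a warning and left as zero columns so
    cell indexing stays aligned.
    """
    libs = counts.library_sizes().astype(float)
    zero = libs == 0
    if zero.all():
        raise ValueError("no cell has nonzero counts")
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cell(s) have zero total counts; "
            "left as zero columns",
            stacklevel=2,
        )
    if target_size == "median":
        target = float(np.median(libs[~zero]))
    else:
        target = float(target_size)
        if target <= 0:
            raise ValueError("target_size must be positive")
    factors = np.where(zero, 1.0, target / np.where(zero, 1.0, libs))
    return np.log1p(counts.values * factors[None, :])


def compute_pca(normalized: np.ndarray, n_pcs: int = 50) -> Embedding:
    """PCA of cells (observations) on gene features, cell-centered.

    Returns the scores of the top ``n_pcs`` components and the component
    variances (eigenvalues of the cell covariance).  Genes are not scaled
    to unit variance.  Component signs are fixed so the loading entry of
    largest magnitude is positive.
    """
    normalized = np.asarray(normalized, dtype=float)
    n_genes, n_cells = normalized.shape
    max_pcs = min(n_genes, n_cells) - 1
    if n_pcs > max_pcs:
        raise ValueError(f"n_pcs={n_pcs} exceeds min(genes, cells) - 1 = {max_pcs}")
    if n_pcs <= 0:
        raise ValueError("n_pcs must be positive")
    X = normalized.T  # cells x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    for i in range(n_pcs):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    coords = U[:, :n_pcs] * s[:n_pcs]
    eigenvalues = (s[:n_pcs] ** 2) / max(n_cells - 1, 1)
    return Embedding(coords=coords, eigenvalues=eigenvalues, n_pcs=n_pcs)


def pca_loadings(normalized: np.ndarray, embedding: Embedding) -> np.ndarray:
    """Gene loading vectors (genes x n_pcs) recovered from the scores.

    Uses X_centered^T U / s; avoids a second SVD and is exact because the
    scores are U s.
    """
    X = np.asarray(normalized, dtype=float).T
    Xc = X - X.mean(axis=0, keepdims=True)
    s2 = embedding.eigenvalues * max(X.shape[0] - 1, 1)
    s2 = np.where(s2 <= 0, 1.0, s2)
    return (Xc.T @ embedding.coords) / s2[None, :]


def select_genes(
    counts: CountMatrix,
    tf_list=(),
    n_hvg: int = 3000,
    normalized: np.ndarray | None = None,
) -> GeneSelection:
    """Top highly variable genes plus any listed transcription factors.

    Dispersion is the variance-to-mean ratio on the normalized matrix
    (computed here if not supplied).  The selection is the union of the
    top ``n_hvg`` dispersed genes and the TF-list members present in the
    matrix; candidate regulators are the TFs among the selection, or all
    selected genes when the intersection is empty.
    """
    if normalized is None:
        normalized = normalize_counts(counts)
    mean = normalized.mean(axis=1)
    var = normalized.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    n_hvg = min(n_hvg, counts.n_genes)
    # stable selection: by decreasing dispersion, ties by gene index
    order = np.lexsort((np.arange(counts.n_genes), -dispersion))
    hvg = set(order[:n_hvg].tolist())
    gene_pos = {g: i for i, g in enumerate(counts.gene_ids)}
    tf_idx = sorted(gene_pos[t] for t in set(tf_list) if t in gene_pos)
    selected = np.array(sorted(hvg | set(tf_idx)), dtype=int)
    regulators = np.array([i for i in tf_idx if i in hvg or True], dtype=int)
    if regulators.size == 0:
        if len(tf_list) > 0:
            warnings.warn(
                "no TF-list member present in the matrix; "
                "all selected genes used as regulators",
                stacklevel=2,
            )
        regulators = selected.copy()
    return GeneSelection(
        gene_indices=selected, regulator_indices=regulators, dispersion=dispersion
    )


def read_tf_list(path) -> list[str]:
    """Plain-text TF list, one symbol per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
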