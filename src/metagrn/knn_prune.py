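"""Pruned KNN graph construction with local negative-binomial backgrounds.

For every (seed) cell a local NB background distribution is fitted on its
KNN neighborhood: per-gene means after rescaling all members to the
neighborhood median library size, and a gene-independent mean-variance
relation obtained by a quadratic fit of log variance on log mean.  Each
neighbor link receives a probability -- the geometric mean of the three
smallest per-gene two-sided NB tail probabilities of the neighbor's
(depth-rescaled) counts under the seed's background model.  Links below a
probability threshold are pruned: a low probability means the neighbor's
expression is unlikely under the seed's local background, i.e. the
neighborhood is not homogeneous there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import CountMatrix, Embedding

_EPS_VAR = 1e-6  # variance clipped to >= mu * (1 + _EPS_VAR), keeps r finite


@dataclass
class KnnGraph:
    """Exact K nearest neighbors per cell (Euclidean, PC space).

    ``neighbors[j]`` lists cell j's K neighbors sorted by increasing
    distance (ties broken by lower cell index); no self-loops.
    """

    neighbors: np.ndarray  # (m, K) int
    distances: np.ndarray  # (m, K) float

    @property
    def k(self) -> int:
        return self.neighbors.shape[1]

    @property
    def n_cells(self) -> int:
        return self.neighbors.shape[0]


@dataclass
class LocalNbModel:
    """Per-gene NB(mu, r) background for one cell's neighborhood."""

    mu: np.ndarray
    r: np.ndarray
    poly_coeffs: np.ndarray  # quadratic log-var vs log-mean fit
    members: np.ndarray  # {cell} U neighbors
    median_library: float


@dataclass
class LinkProbMatrix:
    """Link probabilities, entry (l, j) = prob of cell ``cells[j]``'s l-th neighbor."""

    probs: np.ndarray  # (K, n_cells_evaluated)
    cells: np.ndarray  # cell indices the columns refer to

    def __post_init__(self) -> None:
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("link probabilities must lie in [0, 1]")


@dataclass
class PrunedKnnGraph:
    """Surviving links per seed cell after probability thresholding."""

    cells: np.ndarray  # seed cells with a (possibly empty) neighbor list
    neighbors: list  # list of int arrays
    probs: list  # list of float arrays, matching neighbors
    p_tr: float

    def links_of(self, cell: int):
        j = int(np.searchsorted(self.cells, cell))
        if j >= len(self.cells) or self.cells[j] != cell:
            raise KeyError(f"cell {cell} has no pruned-neighbor record")
        return self.neighbors[j], self.probs[j]

    def to_edge_list(self):
        """Rows (seed_cell, neighbor_cell, probability)."""
        rows = []
        for c, nb, pr in zip(self.cells, self.neighbors, self.probs):
            rows.extend((int(c), int(n), float(p)) for n, p in zip(nb, pr))
        return rows

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("seed_cell\tneighbor_cell\tprobability\n")
            for c, n, p in self.to_edge_list():
                fh.write(f"{c}\t{n}\t{p:.10g}\n")


def build_knn(embedding: Embedding, K: int) -> KnnGraph:
    """Exact K nearest neighbors under Euclidean distance in PC space.

    Ties are broken by lower cell index for determinism.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    coords = embedding.coords
    m = coords.shape[0]
    if K >= m:
        raise ValueError(f"K={K} must be smaller than the number of cells ({m})")
    neighbors = np.empty((m, K), dtype=int)
    distances = np.empty((m, K), dtype=float)
    idx = np.arange(m)
    chunk = max(1, int(2e7) // max(m, 1))
    sq = (coords**2).sum(axis=1)
    for start in range(0, m, chunk):
        stop = min(m, start + chunk)
        block = coords[start:stop]
        d2 = sq[start:stop, None] - 2.0 * (block @ coords.T) + sq[None, :]
        np.maximum(d2, 0.0, out=d2)
        for i in range(stop - start):
            row = d2[i].copy()
            row[start + i] = np.inf  # no self-loop
            order = np.lexsort((idx, row))[:K]
            neighbors[start + i] = order
            distances[start + i] = np.sqrt(row[order])
    return KnnGraph(neighbors=neighbors, distances=distances)


def _rescaled_neighborhood(counts: CountMatrix, members: np.ndarray):
    """Member columns rescaled to the neighborhood median library size."""
    cols = counts.values[:, members].astype(float)
    libs = cols.sum(axis=0)
    if libs.sum() == 0:
        raise ValueError("neighborhood has zero total counts")
    med = float(np.median(libs[libs > 0]))
    factors = np.where(libs > 0, med / np.where(libs > 0, libs, 1.0), 1.0)
    return cols * factors[None, :], med


def _dispersion_from_fit(mu: np.ndarray, var: np.ndarray):
    """Quadratic log-var/log-mean fit; returns (r, coefficients).

    Genes with zero mean or non-positive variance are excluded from the
    fit; fitted variances are clipped to mu(1+eps) so r stays finite and
    positive.  When fewer than three genes are usable the model degrades
    to (clipped) Poisson.
    """
    valid = (mu > 0) & (var > 0)
    if valid.sum() >= 3 and np.ptp(np.log(mu[valid])) > 0:
        coeffs = np.polyfit(np.log(mu[valid]), np.log(var[valid]), 2)
        with np.errstate(over="ignore"):
            v_fit = np.where(mu > 0, np.exp(np.polyval(coeffs, np.log(np.maximum(mu, 1e-300)))), 0.0)
    else:
        coeffs = np.array([0.0, 1.0, 0.0])  # log v = log mu
        v_fit = mu.copy()
    v_fit = np.maximum(v_fit, mu * (1.0 + _EPS_VAR))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(mu > 0, mu**2 / (v_fit - mu), np.inf)
    return r, coeffs


def fit_local_background(
    counts: CountMatrix, graph: KnnGraph, cell: int
) -> LocalNbModel:
    """Fit the local NB background for one cell's neighborhood."""
    if graph.k < 3:
        raise ValueError("neighborhood needs at least 3 neighbors")
    members = np.concatenate(([cell], graph.neighbors[cell]))
    scaled, med = _rescaled_neighborhood(counts, members)
    mu = scaled.mean(axis=1)
    var = scaled.var(axis=1, ddof=1)
    r, coeffs = _dispersion_from_fit(mu, var)
    return LocalNbModel(
        mu=mu, r=r, poly_coeffs=coeffs, members=members, median_library=med
    )


def _two_sided_tail(mu, r, x):
    """p = min(1, 2 min(F(x), 1 - F(x-1))) under NB(mu, r); F(-1) = 0.

    Vectorized over matching array shapes.  mu = 0 genes are handled as a
    point mass at zero (p = 1 at x = 0, p = 0 otherwise).
    """
    mu = np.asarray(mu, dtype=float)
    r = np.asarray(r, dtype=float)
    x = np.asarray(x)
    r_eff = np.minimum(np.where(np.isfinite(r), r, 1e12), 1e12)
    p_nb = r_eff / (r_eff + mu)
    F = stats.nbinom.cdf(x, r_eff, p_nb)
    Fm1 = np.where(x >= 1, stats.nbinom.cdf(x - 1, r_eff, p_nb), 0.0)
    p = np.minimum(1.0, 2.0 * np.minimum(F, 1.0 - Fm1))
    zero_mu = mu == 0
    if np.any(zero_mu):
        p = np.where(zero_mu, np.where(x == 0, 1.0, 0.0), p)
    return p


def gene_count_probability(model: LocalNbModel, gene: int, count: int) -> float:
    """Two-sided NB tail probability of an observed count for one gene."""
    if count < 0:
        raise ValueError("count must be non-negative")
    return float(_two_sided_tail(model.mu[gene], model.r[gene], count))


def link_probabilities(
    counts: CountMatrix,
    graph: KnnGraph,
    cells: np.ndarray | None = None,
    n_lowest: int = 3,
) -> LinkProbMatrix:
    """Per-link probabilities: geometric mean of the lowest gene tails.

    For each evaluated cell j, its K neighbors' counts (rescaled to j's
    neighborhood median library size, rounded to integers) are scored
    under j's background model; the link probability is the geometric
    mean of the ``n_lowest`` smallest per-gene probabilities.  Restrict
    the computation to ``cells`` (e.g. the seed cells) for speed.
    """
    if cells is None:
        cells = np.arange(graph.n_cells)
    cells = np.asarray(cells, dtype=int)
    if counts.n_genes < n_lowest:
        warnings.warn(
            f"only {counts.n_genes} genes available; using all for the "
            "geometric mean",
            stacklevel=2,
        )
        n_lowest = counts.n_genes
    probs = np.empty((graph.k, len(cells)), dtype=float)
    for j, cell in enumerate(cells):
        model = fit_local_background(counts, graph, int(cell))
        nb = graph.neighbors[cell]
        cols = counts.values[:, nb].astype(float)
        libs = cols.sum(axis=0)
        factors = np.where(libs > 0, model.median_library / np.where(libs > 0, libs, 1.0), 1.0)
        x = np.rint(cols * factors[None, :]).astype(np.int64)
        p = _two_sided_tail(model.mu[:, None], model.r[:, None], x)
        p_sorted = np.sort(p, axis=0)[:n_lowest]
        logp = np.log(np.maximum(p_sorted, 1e-300))
        probs[:, j] = np.exp(logp.mean(axis=0))
    return LinkProbMatrix(probs=probs, cells=cells)


def prune_graph(
    probs: LinkProbMatrix, graph: KnnGraph, p_tr: float = 0.01
) -> PrunedKnnGraph:
    """Remove links with probability below ``p_tr``.

    Cells whose links are all pruned are retained as degree-0 nodes.
    """
    if not (0.0 <= p_tr < 1.0):
        raise ValueError("p_tr must lie in [0, 1)")
    neighbors, kept_probs = [], []
    for j, cell in enumerate(probs.cells):
        keep = probs.probs[:, j] >= p_tr
        neighbors.append(graph.neighbors[cell][keep].copy())
        kept_probs.append(probs.probs[keep, j].copy())
    return PrunedKnnGraph(
        cells=np.asarray(probs.cells, dtype=int),
        neighbors=neighbors,
        probs=kept_probs,
        p_tr=p_tr,
    )
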