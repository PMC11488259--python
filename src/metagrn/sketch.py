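"""Seed-cell sampling, sampling-quality metrics, and the seed-number sweep.

Two samplers are provided: a geometric (covering-box) sketch that places a
near-uniform grid over PC space and keeps one cell per occupied hypercube
-- oversampling rare cell states relative to their abundance -- and plain
uniform random sampling.  Sampling quality is quantified by the directed
Hausdorff distance from the full cell set to the seed set (coverage) and
by the explained expression variance (EEV): the eigenvalue-weighted R^2 of
the top principal-component loading vectors regressed on the sampled
cells' expression profiles.

The seed-number sweep trades off the number of seed cells S against the
average effective metacell size n_s: both are min-max normalized (n_s via
sqrt(n_s - 1)) and the optimum maximizes their product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import CountMatrix, Embedding, pca_loadings


@dataclass
class SeedSet:
    seed_indices: np.ndarray  # strictly increasing cell indices
    method: str
    rng_seed: int

    def __post_init__(self) -> None:
        self.seed_indices = np.asarray(self.seed_indices, dtype=int)
        if len(np.unique(self.seed_indices)) != len(self.seed_indices):
            raise ValueError("seed indices must be unique")
        self.seed_indices = np.sort(self.seed_indices)

    def __len__(self) -> int:
        return len(self.seed_indices)


@dataclass
class EevResult:
    r2: np.ndarray  # per-component R^2, length K_pcs
    weights: np.ndarray  # eigenvalue weights, sum to 1
    eev: float


@dataclass
class SeedSweepResult:
    candidates: np.ndarray
    n_s: np.ndarray
    s_star: np.ndarray
    n_s_star: np.ndarray
    score: np.ndarray
    optimal_S: int

    def to_rows(self):
        return list(zip(self.candidates, self.n_s, self.s_star, self.n_s_star, self.score))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("S\tn_s\tS_star\tn_s_star\tscore\n")
            for S, ns, ss, nss, sc in self.to_rows():
                fh.write(f"{S}\t{ns:.6g}\t{ss:.6g}\t{nss:.6g}\t{sc:.6g}\n")


def _occupied_cubes(unit_coords: np.ndarray, width: float):
    """Map each cell to its hypercube id at the given grid width."""
    grid = np.floor(unit_coords / width).astype(np.int64)
    _, inverse = np.unique(grid, axis=0, return_inverse=True)
    return inverse


def geometric_sketch(embedding: Embedding, S: int, rng_seed: int = 0) -> SeedSet:
    """Covering-box sketch: one cell per occupied PC-space hypercube.

    Each PC axis is min-max rescaled to [0, 1]; a grid side length is
    binary-searched so the number of occupied hypercubes is close to S;
    one uniformly chosen cell per occupied cube is returned, trimmed or
    padded with cells from random occupied cubes to hit S exactly.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    coords = embedding.coords
    m = coords.shape[0]
    if S >= m:
        if S > m:
            warnings.warn(f"S={S} exceeds the number of cells ({m}); returning all")
        return SeedSet(np.arange(m), "geosketch", rng_seed)
    rng = np.random.default_rng(rng_seed)
    span = coords.max(axis=0) - coords.min(axis=0)
    keep_axes = span > 0
    unit = np.zeros_like(coords)
    unit[:, keep_axes] = (coords[:, keep_axes] - coords[:, keep_axes].min(axis=0)) / span[keep_axes]
    # shrink by epsilon so the max point falls in the last cube
    unit = np.minimum(unit, 1.0 - 1e-12)

    lo, hi = 1e-9, 1.0 + 1e-9  # width lo -> m cubes, width hi -> 1 cube
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        n_occ = len(np.unique(_occupied_cubes(unit, mid)))
        if n_occ > S:
            lo = mid
        else:
            hi = mid
    cube_of = _occupied_cubes(unit, hi)
    cube_ids = np.unique(cube_of)
    chosen = []
    order = rng.permutation(len(cube_ids))
    for ci in cube_ids[order]:
        members = np.flatnonzero(cube_of == ci)
        chosen.append(int(rng.choice(members)))
    if len(chosen) > S:
        chosen = chosen[:S]  # trim random cubes (order already random)
    while len(chosen) < S:
        # pad: extra cells from random occupied cubes
        taken = set(chosen)
        ci = cube_ids[rng.integers(len(cube_ids))]
        members = [c for c in np.flatnonzero(cube_of == ci) if c not in taken]
        if members:
            chosen.append(int(rng.choice(members)))
        else:
            remaining = np.setdiff1d(np.arange(m), np.array(sorted(taken)))
            chosen.append(int(rng.choice(remaining)))
    return SeedSet(np.array(chosen), "geosketch", rng_seed)


def random_sample(cells: int, S: int, rng_seed: int = 0) -> SeedSet:
    """Uniform sample of S cells without replacement."""
    if S < 1:
        raise ValueError("S must be >= 1")
    if S >= cells:
        if S > cells:
            warnings.warn(f"S={S} exceeds the number of cells ({cells}); returning all")
        return SeedSet(np.arange(cells), "random", rng_seed)
    rng = np.random.default_rng(rng_seed)
    return SeedSet(rng.choice(cells, size=S, replace=False), "random", rng_seed)


def hausdorff_distance(embedding: Embedding, seeds: SeedSet) -> float:
    """Directed Hausdorff distance from all cells to the seed set.

    max over cells of the distance to the nearest seed; 0 when the seeds
    cover every cell.  Coverage semantics: small values mean no cell state
    is far from a sampled representative.
    """
    if len(seeds) == 0:
        raise ValueError("seed set is empty")
    from scipy.spatial import cKDTree

    coords = embedding.coords
    dist, _ = cKDTree(coords[seeds.seed_indices]).query(coords, k=1)
    return float(dist.max())


def explained_expression_variance(
    normalized: np.ndarray,
    embedding: Embedding,
    seeds: SeedSet,
    K_pcs: int = 10,
) -> EevResult:
    """EEV: eigenvalue-weighted R^2 of PC loadings on seed profiles.

    For each of the top ``K_pcs`` components, the gene-loading vector
    (genes as observations) is regressed on the sampled cells' normalized
    expression profiles with an intercept; EEV is the sum of R^2 values
    weighted by the normalized eigenvalues.
    """
    if K_pcs > embedding.n_pcs:
        raise ValueError("K_pcs exceeds the number of computed PCs")
    normalized = np.asarray(normalized, dtype=float)
    n_genes = normalized.shape[0]
    if len(seeds) >= n_genes:
        warnings.warn("more seeds than genes: R^2 degenerates to 1", stacklevel=2)
    loadings = pca_loadings(normalized, embedding)[:, :K_pcs]
    X = np.column_stack([np.ones(n_genes), normalized[:, seeds.seed_indices]])
    r2 = np.empty(K_pcs)
    for i in range(K_pcs):
        y = loadings[:, i]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2[i] = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    r2 = np.clip(r2, 0.0, 1.0)
    lam = embedding.eigenvalues[:K_pcs]
    weights = lam / lam.sum()
    return EevResult(r2=r2, weights=weights, eev=float((weights * r2).sum()))


def optimal_seed_number(sweep) -> SeedSweepResult:
    """Pick the seed count maximizing S* x n_s*.

    S* is min-max normalized S; n_s* is min-max normalized sqrt(n_s - 1);
    the optimum is the argmax of their product (ties -> smaller S).
    """
    sweep = sorted((int(S), float(ns)) for S, ns in sweep)
    if len(sweep) < 3:
        raise ValueError("need at least 3 sweep candidates")
    S = np.array([s for s, _ in sweep], dtype=float)
    n_s = np.array([ns for _, ns in sweep], dtype=float)
    if np.any(n_s < 1):
        raise ValueError("n_s must be >= 1 for every candidate")
    if S.max() == S.min() or n_s.max() == n_s.min():
        raise ValueError("normalization undefined: constant S or constant n_s")
    s_star = (S - S.min()) / (S.max() - S.min())
    root = np.sqrt(n_s - 1.0)
    if root.max() == root.min():
        raise ValueError("normalization undefined: constant sqrt(n_s - 1)")
    n_s_star = (root - root.min()) / (root.max() - root.min())
    score = s_star * n_s_star
    best = int(np.argmax(score))  # np.argmax takes the first (= smallest S) tie
    return SeedSweepResult(
        candidates=S.astype(int),
        n_s=n_s,
        s_star=s_star,
        n_s_star=n_s_star,
        score=score,
        optimal_S=int(S[best]),
    )


def sweep_seed_numbers(
    counts: CountMatrix,
    embedding: Embedding,
    candidates,
    K: int = 20,
    p_tr: float = 0.01,
    rng_seed: int = 0,
    method: str = "geosketch",
) -> list:
    """Run sampling -> pruning -> partner assignment per candidate S.

    Returns (S, n_s) pairs where n_s is the average effective metacell
    size over all seed cells after disjoint assignment: 1 (the seed) plus
    the mean partner count, so sqrt(n_s - 1) measures the average
    neighborhood that survives pruning.
    """
    from .knn_prune import build_knn, link_probabilities, prune_graph
    from .metacell import assign_partners

    candidates = sorted(int(S) for S in candidates)
    if len(candidates) < 3:
        raise ValueError("need at least 3 candidate sample sizes")
    if candidates[0] < 1 or candidates[-1] > counts.n_cells:
        raise ValueError("candidates must lie in (0, n_cells]")
    graph = build_knn(embedding, K)
    pairs = []
    for S in candidates:
        if method == "geosketch":
            seeds = geometric_sketch(embedding, S, rng_seed)
        else:
            seeds = random_sample(counts.n_cells, S, rng_seed)
        probs = link_probabilities(counts, graph, cells=seeds.seed_indices)
        pruned = prune_graph(probs, graph, p_tr)
        assignment = assign_partners(pruned, seeds)
        n_s = 1.0 + float(
            np.mean([assignment.partner_counts[s] for s in seeds.seed_indices])
        )
        pairs.append((S, n_s))
    return pairs
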