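"""Global GRN inference on metacell profiles and skeleton binarization.

The global network is inferred GENIE3-style: for every target gene a
random-forest regression predicts its (depth-normalized, log-transformed)
metacell profile from the profiles of all other candidate regulators; the
importance of each regulator is its total impurity reduction, normalized
per target to sum to one.  The weighted network is binarized into a
skeleton by thresholding and keeping the top-n targets per regulator, and
can optionally be intersected with a user-supplied prior edge list (e.g.
derived from chromatin accessibility and motif scanning elsewhere).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .metacell import MetacellMatrix


@dataclass
class WeightedGrn:
    """Non-negative importance weights, regulators x targets."""

    weights: np.ndarray
    regulator_ids: list
    target_ids: list

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        for r, reg in enumerate(self.regulator_ids):
            for t, tgt in enumerate(self.target_ids):
                if reg == tgt and self.weights[r, t] != 0:
                    raise ValueError(f"self-edge weight on {reg}")

    def write_tsv(self, path, include_zero: bool = False) -> None:
        with open(path, "w") as fh:
            fh.write("regulator\ttarget\tweight\n")
            for r, reg in enumerate(self.regulator_ids):
                for t, tgt in enumerate(self.target_ids):
                    w = self.weights[r, t]
                    if reg != tgt and (include_zero or w > 0):
                        fh.write(f"{reg}\t{tgt}\t{w:.10g}\n")


@dataclass
class SkeletonNetwork:
    """Binarized regulator -> target adjacency."""

    adjacency: np.ndarray  # bool, regulators x targets
    regulator_ids: list
    target_ids: list
    provenance: str = "genie3"

    def edges(self):
        out = []
        for r, reg in enumerate(self.regulator_ids):
            for t in np.flatnonzero(self.adjacency[r]):
                out.append((reg, self.target_ids[t]))
        return out

    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def targets_of(self, regulator) -> list:
        r = self.regulator_ids.index(regulator)
        return [self.target_ids[t] for t in np.flatnonzero(self.adjacency[r])]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("regulator\ttarget\n")
            for reg, tgt in self.edges():
                fh.write(f"{reg}\t{tgt}\n")


def normalize_profiles(values: np.ndarray) -> np.ndarray:
    """Depth-normalize metacell columns to the median depth, then log1p.

    Aggregated library sizes vary with metacell size, so depth correction
    is required before any cross-metacell regression.
    """
    values = np.asarray(values, dtype=float)
    depth = values.sum(axis=0)
    if np.any(depth == 0):
        raise ValueError("metacell with zero total counts")
    target = float(np.median(depth))
    return np.log1p(values * (target / depth)[None, :])


def infer_global_grn(
    metacells: MetacellMatrix,
    regulators,
    targets=None,
    n_trees: int = 1000,
    rng_seed: int = 0,
    normalize: bool = True,
) -> WeightedGrn:
    """Random-forest importance network over metacell profiles.

    ``regulators`` (and optionally ``targets``) are gene identifiers
    present in the metacell matrix.  A gene never predicts itself.  Rows
    of per-target importances are normalized to sum to one.  Samples are
    put into a canonical order before fitting, so the result does not
    depend on metacell column order for a fixed ``rng_seed``.
    """
    gene_pos = {g: i for i, g in enumerate(metacells.gene_ids)}
    regulators = [g for g in regulators if g in gene_pos]
    if len(regulators) < 2:
        raise ValueError("need at least 2 regulators present in the matrix")
    if targets is None:
        targets = list(metacells.gene_ids)
    if metacells.n_metacells < 10:
        raise ValueError("need at least 10 metacells")
    profiles = (
        normalize_profiles(metacells.values)
        if normalize
        else metacells.values.astype(float)
    )
    # canonical sample order: invariant to input metacell permutation
    order = np.lexsort(profiles)
    profiles = profiles[:, order]
    reg_rows = np.array([gene_pos[g] for g in regulators])
    weights = np.zeros((len(regulators), len(targets)))
    for t_i, tgt in enumerate(targets):
        y = profiles[gene_pos[tgt]]
        if np.ptp(y) == 0:
            warnings.warn(f"constant target profile for {tgt}; zero column")
            continue
        mask = np.array([g != tgt for g in regulators])
        if not mask.any():
            continue
        X = profiles[reg_rows[mask]].T
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=(rng_seed * 100_003 + t_i) % (2**31),
            n_jobs=1,
        )
        rf.fit(X, y)
        imp = rf.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        weights[mask, t_i] = imp
    return WeightedGrn(weights=weights, regulator_ids=list(regulators), target_ids=list(targets))


def binarize_skeleton(
    grn: WeightedGrn, weight_threshold: float = 0.001, top_n: int = 50
) -> SkeletonNetwork:
    """Threshold weights and keep the top-n targets per regulator.

    Ties at the top-n boundary are resolved toward the lower target
    index.
    """
    if weight_threshold <= 0 or top_n <= 0:
        raise ValueError("weight_threshold and top_n must be positive")
    n_reg, n_tgt = grn.weights.shape
    adj = np.zeros((n_reg, n_tgt), dtype=bool)
    tgt_idx = np.arange(n_tgt)
    for r in range(n_reg):
        qualifying = np.flatnonzero(grn.weights[r] >= weight_threshold)
        if qualifying.size == 0:
            continue
        order = np.lexsort((tgt_idx[qualifying], -grn.weights[r, qualifying]))
        adj[r, qualifying[order[:top_n]]] = True
    return SkeletonNetwork(
        adjacency=adj,
        regulator_ids=list(grn.regulator_ids),
        target_ids=list(grn.target_ids),
        provenance="genie3",
    )


def read_prior_edges(path) -> set:
    """Two- or three-column (regulator, target[, weight]) TSV edge list."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("prior network needs at least two columns")
    first = tuple(df.iloc[0, :2])
    if first in {("regulator", "target"), ("Regulator", "Target")}:
        df = df.iloc[1:]
    return set(zip(df[0], df[1]))


def intersect_prior(skeleton: SkeletonNetwork, prior) -> SkeletonNetwork:
    """Keep only skeleton edges that are also in the prior edge set."""
    prior = set(prior)
    adj = skeleton.adjacency.copy()
    for r, reg in enumerate(skeleton.regulator_ids):
        for t in np.flatnonzero(adj[r]):
            if (reg, skeleton.target_ids[t]) not in prior:
                adj[r, t] = False
    if adj.sum() == 0:
        warnings.warn("empty intersection with the prior network", stacklevel=2)
    return SkeletonNetwork(
        adjacency=adj,
        regulator_ids=list(skeleton.regulator_ids),
        target_ids=list(skeleton.target_ids),
        provenance="intersected",
    )
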