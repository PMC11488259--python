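"""Benchmark metrics: early precision rate, AUROC/AUPRC, DEG baseline.

The candidate-edge universe is regulators x (universe genes minus self).
Early precision is the fraction of true edges among the top-k predictions
(k = number of ground-truth edges by default); the early precision rate
(EPR) divides it by the ground-truth edge density, so a random predictor
scores 1 in expectation and a perfect one scores 1/density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

from .grn_core import SkeletonNetwork, WeightedGrn, normalize_profiles


@dataclass
class GroundTruthNetwork:
    """Directed true edges over an explicit gene universe."""

    true_edges: set
    gene_universe: list
    regulators: list | None = None

    def __post_init__(self) -> None:
        self.gene_universe = [str(g) for g in self.gene_universe]
        universe = set(self.gene_universe)
        if self.regulators is None:
            self.regulators = list(self.gene_universe)
        self.regulators = [str(g) for g in self.regulators]
        self.true_edges = {(str(a), str(b)) for a, b in self.true_edges}
        for a, b in self.true_edges:
            if a == b:
                raise ValueError(f"self-loop {a}->{b} in ground truth")
            if a not in universe or b not in universe:
                raise ValueError(f"edge {a}->{b} outside the gene universe")

    @property
    def density(self) -> float:
        denom = len(self.regulators) * (len(self.gene_universe) - 1)
        return len(self.true_edges) / denom

    def candidate_edges(self) -> list:
        return [
            (r, t)
            for r in self.regulators
            for t in self.gene_universe
            if r != t
        ]


@dataclass
class RankedPrediction:
    """Scored directed edges; at most one score per ordered pair."""

    edges: list  # (regulator, target, score)

    def __post_init__(self) -> None:
        pairs = [(a, b) for a, b, _ in self.edges]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate edge in prediction")

    @classmethod
    def from_weighted(cls, grn: WeightedGrn) -> "RankedPrediction":
        edges = []
        for r, reg in enumerate(grn.regulator_ids):
            for t, tgt in enumerate(grn.target_ids):
                if reg != tgt and grn.weights[r, t] > 0:
                    edges.append((reg, tgt, float(grn.weights[r, t])))
        return cls(edges)

    @classmethod
    def from_matrix(cls, weights, regulator_ids, target_ids) -> "RankedPrediction":
        weights = np.asarray(weights, dtype=float)
        edges = []
        for r, reg in enumerate(regulator_ids):
            for t, tgt in enumerate(target_ids):
                if reg != tgt and weights[r, t] > 0:
                    edges.append((reg, tgt, float(weights[r, t])))
        return cls(edges)

    def sorted_edges(self) -> list:
        """Decreasing score; ties by lexicographic (regulator, target)."""
        return sorted(self.edges, key=lambda e: (-e[2], e[0], e[1]))


def early_precision_rate(
    pred: RankedPrediction, truth: GroundTruthNetwork, k: int | None = None
) -> float:
    """EPR = (|top-k predicted edges that are true| / k) / density."""
    if len(truth.true_edges) == 0:
        raise ValueError("ground truth has no edges")
    if k is None:
        k = len(truth.true_edges)
    if k < 1:
        raise ValueError("k must be >= 1")
    universe = set(truth.gene_universe)
    regs = set(truth.regulators)
    ranked = [
        (a, b)
        for a, b, _ in pred.sorted_edges()
        if a in regs and b in universe and a != b
    ]
    top = ranked[:k]
    hits = sum(1 for e in top if e in truth.true_edges)
    early_precision = hits / k
    return early_precision / truth.density


def auroc_auprc(pred: RankedPrediction, truth: GroundTruthNetwork) -> tuple:
    """Trapezoidal AUROC and step-wise AUPRC over all candidate edges.

    Candidate edges missing from the prediction receive score 0.
    """
    candidates = truth.candidate_edges()
    score_of = {(a, b): s for a, b, s in pred.edges}
    y_true = np.array([e in truth.true_edges for e in candidates], dtype=int)
    y_score = np.array([score_of.get(e, 0.0) for e in candidates])
    if y_true.all() or not y_true.any():
        raise ValueError("ground truth is complete or empty over the universe")
    return float(roc_auc_score(y_true, y_score)), float(
        average_precision_score(y_true, y_score)
    )


def deg_lineage_baseline(
    expression: np.ndarray,
    gene_ids: list,
    group_labels,
    grn: SkeletonNetwork | WeightedGrn,
    alpha: float = 0.05,
    normalize: bool = True,
) -> dict:
    """Lineage GRNs as induced subnetworks on up-regulated genes.

    Per terminal-state group, every gene is tested one-sided (group >
    rest) with the Wilcoxon rank-sum test; p-values are Benjamini-
    Hochberg adjusted and genes with adjusted p < alpha are kept.  The
    lineage network is the global network restricted to kept genes.
    """
    group_labels = np.asarray(group_labels)
    groups = sorted(set(group_labels.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    expression = np.asarray(expression, dtype=float)
    if normalize and np.all(expression >= 0) and expression.sum(axis=0).min() > 0:
        expression = normalize_profiles(expression)
    if isinstance(grn, WeightedGrn):
        adjacency = grn.weights > 0
        reg_ids, tgt_ids = grn.regulator_ids, grn.target_ids
    else:
        adjacency = grn.adjacency
        reg_ids, tgt_ids = grn.regulator_ids, grn.target_ids
    out = {}
    for g in groups:
        mask = group_labels == g
        if mask.sum() < 3 or (~mask).sum() < 3:
            raise ValueError(f"group {g!r} or its complement has < 3 members")
        pvals = np.ones(len(gene_ids))
        for i in range(len(gene_ids)):
            a = expression[i, mask]
            b = expression[i, ~mask]
            if np.ptp(np.concatenate([a, b])) == 0:
                pvals[i] = 1.0
                continue
            pvals[i] = stats.mannwhitneyu(a, b, alternative="greater").pvalue
        keep = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
        kept_genes = {gene_ids[i] for i in np.flatnonzero(keep)}
        if not kept_genes:
            warnings.warn(f"no significant genes for group {g!r}", stacklevel=2)
        adj = np.zeros_like(adjacency, dtype=bool)
        for r, reg in enumerate(reg_ids):
            if reg not in kept_genes:
                continue
            for t in np.flatnonzero(adjacency[r]):
                if tgt_ids[t] in kept_genes:
                    adj[r, t] = True
        out[g] = SkeletonNetwork(
            adjacency=adj,
            regulator_ids=list(reg_ids),
            target_ids=list(tgt_ids),
            provenance="deg-baseline",
        )
    return out


def read_ground_truth(path, gene_universe=None, regulators=None) -> GroundTruthNetwork:
    """Edge-list TSV (regulator, target) ground truth."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    first = tuple(df.iloc[0, :2])
    if first in {("regulator", "target"), ("Regulator", "Target")}:
        df = df.iloc[1:]
    edges = set(zip(df[0], df[1]))
    if gene_universe is None:
        gene_universe = sorted({g for e in edges for g in e})
    return GroundTruthNetwork(edges, list(gene_universe), regulators)
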