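"""Regulator ranking, TF-centered module extraction, permutation test.

Regulators are ranked by connectivity (mean absolute outgoing weight by
default; the sum of coefficients is available as an alternative).  Modules
around top regulators are found with spin-glass (Potts model) community
detection on the symmetrized absolute-weight graph, and their modularity
-- the mean regulatory coefficient over internal edges -- is tested by
permuting gene identities, which preserves the topology and the weight
multiset exactly.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass

import igraph as ig
import numpy as np

from .grn_core import WeightedGrn
from .lineage_grn import LineageGrn


@dataclass
class ModuleResult:
    seed_tfs: list
    member_genes: list
    modularity: float
    perm_scores: np.ndarray | None = None
    p_value: float | None = None


def _weight_matrix(grn) -> tuple:
    if isinstance(grn, WeightedGrn):
        return grn.weights, grn.regulator_ids, grn.target_ids
    if isinstance(grn, LineageGrn):
        return grn.G, grn.regulator_ids, grn.target_ids
    weights, regs, tgts = grn
    return np.asarray(weights, dtype=float), list(regs), list(tgts)


def regulator_connectivity(grn, mode: str = "mean_abs") -> list:
    """Rank regulators by outgoing-edge connectivity.

    ``mean_abs``: mean of absolute weights over the regulator's nonzero
    targets (0 for an all-zero row).  ``sum``: plain sum of coefficients.
    Descending, ties by gene name.
    """
    weights, regs, _ = _weight_matrix(grn)
    if weights.size == 0:
        raise ValueError("empty network")
    scores = []
    for r, reg in enumerate(regs):
        row = weights[r]
        if mode == "mean_abs":
            nz = row[row != 0]
            score = float(np.abs(nz).mean()) if nz.size else 0.0
        elif mode == "sum":
            score = float(row.sum())
        else:
            raise ValueError(f"unknown mode {mode!r}")
        scores.append((reg, score))
    return sorted(scores, key=lambda x: (-x[1], x[0]))


def _symmetrized_graph(grn):
    """Undirected igraph on |weight| edges, symmetrized by maximum."""
    weights, regs, tgts = _weight_matrix(grn)
    genes = list(dict.fromkeys(list(regs) + list(tgts)))
    pos = {g: i for i, g in enumerate(genes)}
    W: dict[tuple, float] = {}
    for r, reg in enumerate(regs):
        for t in np.flatnonzero(weights[r]):
            u, v = pos[reg], pos[tgts[t]]
            if u == v:
                continue
            key = (min(u, v), max(u, v))
            W[key] = max(W.get(key, 0.0), abs(float(weights[r, t])))
    g = ig.Graph(n=len(genes), edges=list(W.keys()))
    g.es["weight"] = list(W.values())
    g.vs["name"] = genes
    return g


def _internal_mean_weight(g: ig.Graph, member_idx: set) -> float:
    ws = [
        e["weight"]
        for e in g.es
        if e.source in member_idx and e.target in member_idx
    ]
    return float(np.mean(ws)) if ws else 0.0


def extract_module(grn, seed_tfs, rng_seed: int = 0) -> ModuleResult:
    """Spin-glass community containing each seed TF.

    Communities are detected once per connected component holding seed
    TFs; the module is the union over seeds of the community containing
    that seed.  Modularity = mean absolute weight over internal edges.
    """
    if isinstance(seed_tfs, str):
        seed_tfs = [seed_tfs]
    g = _symmetrized_graph(grn)
    name_pos = {v["name"]: v.index for v in g.vs}
    for tf in seed_tfs:
        if tf not in name_pos:
            raise ValueError(f"seed TF {tf!r} not in the network")
        if g.degree(name_pos[tf]) == 0:
            raise ValueError(f"seed TF {tf!r} is isolated")
    _random.seed(rng_seed)
    ig.set_random_number_generator(_random)
    comps = g.connected_components()
    membership = np.asarray(comps.membership)
    members: set = set()
    for comp_id in sorted({membership[name_pos[tf]] for tf in seed_tfs}):
        sub_nodes = np.flatnonzero(membership == comp_id)
        sub = g.subgraph(sub_nodes.tolist())
        communities = sub.community_spinglass(weights="weight")
        local = {v["name"]: i for i, v in enumerate(sub.vs)}
        comm = np.asarray(communities.membership)
        for tf in seed_tfs:
            if membership[name_pos[tf]] != comp_id:
                continue
            c = comm[local[tf]]
            members |= {sub.vs[i]["name"] for i in np.flatnonzero(comm == c)}
    member_idx = {name_pos[m] for m in members}
    return ModuleResult(
        seed_tfs=list(seed_tfs),
        member_genes=sorted(members),
        modularity=_internal_mean_weight(g, member_idx),
    )


def module_permutation_test(
    grn, module: ModuleResult, n_perm: int = 1000, rng_seed: int = 0
) -> float:
    """Gene-identity permutation p-value for a module's modularity.

    Each permutation relabels all nodes uniformly at random (topology and
    weights untouched) and the modularity of the original member-gene set
    is recomputed under the new labels.  The add-one estimator
    p = (1 + #{perm >= observed}) / (1 + n_perm) never returns exactly 0.
    """
    if len(module.member_genes) < 2:
        raise ValueError("module must contain at least 2 genes")
    g = _symmetrized_graph(grn)
    name_pos = {v["name"]: v.index for v in g.vs}
    member = np.zeros(g.vcount(), dtype=bool)
    for m in module.member_genes:
        member[name_pos[m]] = True
    edges = np.array([(e.source, e.target) for e in g.es], dtype=int)
    w = np.array(g.es["weight"], dtype=float)
    observed = module.modularity
    rng = np.random.default_rng(rng_seed)
    perm_scores = np.empty(n_perm)
    for i in range(n_perm):
        pi = rng.permutation(g.vcount())
        inside = member[pi[edges[:, 0]]] & member[pi[edges[:, 1]]]
        perm_scores[i] = w[inside].mean() if inside.any() else 0.0
    p = (1 + int((perm_scores >= observed - 1e-12).sum())) / (1 + n_perm)
    module.perm_scores = perm_scores
    module.p_value = p
    return p
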