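"""Disjoint metacell construction from pruned seed-cell neighborhoods.

A metacell is a seed cell together with the partner cells assigned to it.
Disjointness -- no cell belongs to two metacells -- is the central design
requirement: sharing cells between aggregated profiles induces spurious
gene-gene correlations downstream.  Shared neighbors are resolved to the
seed with the largest link probability; exact ties go to the seed with the
fewest partners so far, then to the lowest seed index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import CountMatrix
from .knn_prune import PrunedKnnGraph
from .sketch import SeedSet


@dataclass
class MetacellAssignment:
    """Cell -> seed partner relation; -1 marks unassigned cells."""

    seed_of: np.ndarray  # (n_cells,) int, seed index or -1
    seeds: np.ndarray  # seed cell indices
    partner_counts: dict  # seed -> number of partner cells (seed excluded)

    def members_of(self, seed: int) -> np.ndarray:
        """Member cells of a seed's metacell, the seed itself first."""
        partners = np.flatnonzero(self.seed_of == seed)
        partners = partners[partners != seed]
        return np.concatenate(([seed], partners))


@dataclass
class MetacellMatrix:
    """Aggregated expression, genes x metacells."""

    values: np.ndarray
    gene_ids: list
    seed_cells: np.ndarray  # seed cell index per metacell column
    member_lists: list  # list of int arrays, seed first
    min_partners: int

    @property
    def n_metacells(self) -> int:
        return self.values.shape[1]

    def sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.member_lists])

    def write_membership_tsv(self, path, cell_ids=None) -> None:
        with open(path, "w") as fh:
            fh.write("cell_id\tmetacell_id\n")
            for mc, members in enumerate(self.member_lists):
                for c in members:
                    name = cell_ids[c] if cell_ids is not None else str(int(c))
                    fh.write(f"{name}\t{mc}\n")


def assign_partners(pruned: PrunedKnnGraph, seeds: SeedSet) -> MetacellAssignment:
    """Assign each linked non-seed cell to exactly one seed.

    Cells are processed in decreasing order of their best link
    probability (ties by lower cell index) so the outcome is
    deterministic; each is assigned to its max-probability seed, exact
    probability ties to the tied seed with the fewest partners so far,
    remaining ties to the lowest seed index.  Seed cells are always their
    own metacell's member and never partners of other seeds.
    """
    seed_idx = seeds.seed_indices
    seed_set = set(int(s) for s in seed_idx)
    n_cells = int(max(pruned.cells.max(initial=0), max(
        (nb.max() for nb in pruned.neighbors if len(nb)), default=0
    ))) + 1
    # candidate links from seeds only
    cand: dict[int, list] = {}
    for c, nb, pr in zip(pruned.cells, pruned.neighbors, pruned.probs):
        if int(c) not in seed_set:
            continue
        for n, p in zip(nb, pr):
            n = int(n)
            if n in seed_set:
                continue  # seed status wins: never a partner
            cand.setdefault(n, []).append((float(p), int(c)))
    seed_of = np.full(n_cells, -1, dtype=int)
    counts = {int(s): 0 for s in seed_idx}
    for s in seed_idx:
        seed_of[s] = s
    order = sorted(
        cand, key=lambda cell: (-max(p for p, _ in cand[cell]), cell)
    )
    for cell in order:
        best_p = max(p for p, _ in cand[cell])
        tied = [s for p, s in cand[cell] if p == best_p]
        tied.sort(key=lambda s: (counts[s], s))
        chosen = tied[0]
        seed_of[cell] = chosen
        counts[chosen] += 1
    return MetacellAssignment(seed_of=seed_of, seeds=seed_idx.copy(), partner_counts=counts)


def aggregate_metacells(
    counts: CountMatrix,
    assignment: MetacellAssignment,
    min_partners: int = 5,
) -> MetacellMatrix:
    """Sum raw member counts per metacell; drop undersized seeds.

    A seed with fewer than ``min_partners`` partner cells (the seed
    itself not counted) is dropped and its cells become unassigned.
    """
    kept, members = [], []
    for s in assignment.seeds:
        mem = assignment.members_of(int(s))
        if len(mem) - 1 >= min_partners:
            kept.append(int(s))
            members.append(mem)
    if not kept:
        raise ValueError(
            "every seed has fewer than "
            f"{min_partners} partners; use a smaller seed count or larger K"
        )
    if len(kept) < len(assignment.seeds):
        warnings.warn(
            f"dropped {len(assignment.seeds) - len(kept)} seed(s) with fewer "
            f"than {min_partners} partners",
            stacklevel=2,
        )
    values = np.column_stack(
        [counts.values[:, mem].sum(axis=1) for mem in members]
    )
    return MetacellMatrix(
        values=values,
        gene_ids=list(counts.gene_ids),
        seed_cells=np.array(kept),
        member_lists=members,
        min_partners=min_partners,
    )
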