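"""Synthetic scRNA-seq datasets with known global and lineage GRNs.

The generator produces a regulator network (TF backbone plus TF->target
edges, a configurable fraction of which is private to one of two
lineages), then simulates cells along a bifurcating or cyclic trajectory:
each TF follows a smooth bounded activity program of latent pseudotime
(diverging per branch after the bifurcation point), each target's rate is
a softplus of the weighted activities of its ground-truth parents
(lineage-private edges contribute only on their branch), housekeeping
genes have constant rates, and UMI counts are drawn from a negative
binomial around rate x library size with optional Bernoulli dropout.

This is a rate-based generative model, not a kinetic simulation: it is
designed to create recoverable covariation and lineage-specific structure
at desk scale, with ground truth available for every evaluation metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import CountMatrix, load_counts, write_counts
from .evaluation import GroundTruthNetwork
from .lineage_grn import FateMatrix

_LINEAGES = ("CT1", "CT2")


@dataclass
class SimConfig:
    """Default study conditions for the simulator."""

    n_tfs: int = 50
    n_targets: int = 200
    n_hk: int = 50
    n_cells: int = 4000
    edges_per_target: int = 2
    lineage_private_fraction: float = 0.3
    topology: str = "bifurcating"
    nb_dispersion: float = 2.0
    dropout: float = 0.3
    mean_library: float = 1000.0
    fate_noise: float = 0.05
    rng_seed: int = 0


def small_benchmark_config(rng_seed: int = 0, **overrides) -> "SimConfig":
    """Scaled-down benchmark conditions for repeated desk-scale runs.

    Keeps the default per-gene sequencing depth (~2 counts per gene per
    cell before dropout) while shrinking the gene panel and cell count so
    that repeated pipeline runs stay cheap.
    """
    base = dict(
        n_tfs=10,
        n_targets=30,
        n_hk=10,
        n_cells=400,
        mean_library=100.0,
        rng_seed=rng_seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class TruthNetworks:
    """Global truth plus per-lineage edge sets and private-edge tags."""

    global_truth: GroundTruthNetwork
    per_lineage: dict  # lineage label -> GroundTruthNetwork
    edge_lineage: dict  # (reg, tgt) -> None (shared) or lineage label
    tf_ids: list
    target_ids: list
    hk_ids: list
    edge_signs: dict  # (reg, tgt) -> weight used by the rate model


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    truth: TruthNetworks
    fates: FateMatrix
    lineage_of_cell: np.ndarray  # labels, e.g. "CT1"/"CT2"
    pseudotime: np.ndarray
    topology: str
    config: SimConfig


def simulate_grn(
    n_tfs: int = 50,
    n_targets: int = 200,
    n_hk: int = 50,
    edges_per_target: int = 2,
    lineage_private_fraction: float = 0.3,
    rng_seed: int = 0,
) -> TruthNetworks:
    """Build the ground-truth networks.

    TFs form a sparse DAG backbone (each non-root TF regulated by one
    earlier TF); each target receives ``edges_per_target`` TF parents.  A
    ``lineage_private_fraction`` of the TF->target edges is tagged as
    active in only one of the two lineages (split evenly); per-lineage
    truth = shared edges plus that lineage's private edges.  Housekeeping
    genes take part in no edge.
    """
    if min(n_tfs, n_targets, n_hk, edges_per_target) <= 0:
        raise ValueError("all size parameters must be positive")
    if not 0.0 <= lineage_private_fraction <= 1.0:
        raise ValueError("lineage_private_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    tfs = [f"TF{i}" for i in range(n_tfs)]
    targets = [f"T{i}" for i in range(n_targets)]
    hks = [f"HK{i}" for i in range(n_hk)]
    edges = {}
    signs = {}
    for i in range(1, n_tfs):
        parent = int(rng.integers(0, i))
        edges[(tfs[parent], tfs[i])] = None
        signs[(tfs[parent], tfs[i])] = float(rng.uniform(1.0, 3.0) * rng.choice([-1, 1]))
    tf_target_edges = []
    for t in targets:
        parents = rng.choice(n_tfs, size=min(edges_per_target, n_tfs), replace=False)
        for p in parents:
            tf_target_edges.append((tfs[int(p)], t))
    n_private = int(round(lineage_private_fraction * len(tf_target_edges)))
    private_idx = rng.choice(len(tf_target_edges), size=n_private, replace=False)
    lineage_tag = {}
    for rank, e_i in enumerate(sorted(int(i) for i in private_idx)):
        lineage_tag[tf_target_edges[e_i]] = _LINEAGES[rank % 2]
    for e in tf_target_edges:
        edges[e] = lineage_tag.get(e)
        signs[e] = float(rng.uniform(1.0, 3.0) * rng.choice([-1, 1]))
    universe = tfs + targets + hks
    global_truth = GroundTruthNetwork(set(edges), universe, regulators=tfs)
    per_lineage = {}
    for lin in _LINEAGES:
        lin_edges = {e for e, tag in edges.items() if tag is None or tag == lin}
        per_lineage[lin] = GroundTruthNetwork(lin_edges, universe, regulators=tfs)
    return TruthNetworks(
        global_truth=global_truth,
        per_lineage=per_lineage,
        edge_lineage=edges,
        tf_ids=tfs,
        target_ids=targets,
        hk_ids=hks,
        edge_signs=signs,
    )


def _tf_programs(n_tfs: int, rng: np.random.Generator, cyclic: bool):
    """Smooth bounded activity functions of pseudotime, per TF and branch.

    Each TF's activity is a logistic of a low-order random Fourier series
    in s; for bifurcating topologies a branch-specific linear divergence
    term switches on past the bifurcation point s = 0.5.
    """
    amp = rng.uniform(1.0, 3.0, size=(n_tfs, 2))
    freq = rng.integers(1, 3, size=(n_tfs, 2)).astype(float)
    phase = rng.uniform(0, 2 * np.pi, size=(n_tfs, 2))
    diverge = rng.uniform(4.0, 8.0, size=n_tfs) * rng.choice([-1.0, 1.0], size=n_tfs)

    def activity(s: np.ndarray, branch: np.ndarray) -> np.ndarray:
        """(n_tfs, n_cells) activities in (0, 1)."""
        base = np.zeros((n_tfs, len(s)))
        for h in range(2):
            base += amp[:, h, None] * np.sin(
                2 * np.pi * freq[:, h, None] * s[None, :] + phase[:, h, None]
            )
        if not cyclic:
            past = np.maximum(s - 0.5, 0.0) * 2.0  # 0 before, ->1 at s=1
            sign = np.where(branch == 0, 1.0, -1.0)
            base += diverge[:, None] * (past * sign)[None, :]
        return np.clip(1.0 / (1.0 + np.exp(-base)), 1e-9, 1.0 - 1e-9)

    return activity


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def simulate_expression(
    truth: TruthNetworks,
    topology: str = "bifurcating",
    n_cells: int = 4000,
    nb_dispersion: float = 2.0,
    dropout: float = 0.3,
    mean_library: float = 2000.0,
    fate_noise: float = 0.05,
    rng_seed: int = 0,
) -> SimulatedDataset:
    """Simulate UMI counts over the trajectory for a given truth network."""
    if topology not in ("bifurcating", "cyclic"):
        raise ValueError("topology must be 'bifurcating' or 'cyclic'")
    if not (nb_dispersion is None or nb_dispersion > 0):
        raise ValueError("nb_dispersion must be positive or None (Poisson)")
    if not 0.0 <= dropout <= 1.0:
        raise ValueError("dropout must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    cyclic = topology == "cyclic"
    n_tfs = len(truth.tf_ids)
    genes = truth.tf_ids + truth.target_ids + truth.hk_ids
    gene_pos = {g: i for i, g in enumerate(genes)}

    # pseudotime skewed toward 1: terminal attractor states accumulate
    # cells while transitional states are transient
    s = np.sqrt(rng.uniform(0.0, 1.0, size=n_cells))
    branch = rng.integers(0, 2, size=n_cells)  # 0 -> CT1, 1 -> CT2
    if cyclic:
        branch = np.zeros(n_cells, dtype=int)
    program = _tf_programs(n_tfs, rng, cyclic)
    tf_pos = {g: i for i, g in enumerate(truth.tf_ids)}
    backbone = sorted(
        (
            (tf_pos[reg], tf_pos[tgt], truth.edge_signs[(reg, tgt)])
            for (reg, tgt) in truth.edge_lineage
            if reg in tf_pos and tgt in tf_pos
        ),
        key=lambda e: e[1],
    )

    def coupled_activity(s_vec: np.ndarray) -> np.ndarray:
        """TF activities with backbone coupling, in DAG order."""
        act = program(s_vec, branch)
        for p_i, c_i, w in backbone:
            logit = np.log(act[c_i] / (1.0 - act[c_i]))
            logit += w * (act[p_i] - 0.5)
            act[c_i] = np.clip(1.0 / (1.0 + np.exp(-logit)), 1e-9, 1.0 - 1e-9)
        return act

    activity = coupled_activity(s)

    rates = np.zeros((len(genes), n_cells))
    tf_scale = rng.uniform(0.5, 2.0, size=n_tfs)
    rates[:n_tfs] = tf_scale[:, None] * (0.1 + activity)
    # targets respond to their parents' activity with a kinetic delay
    # (transcription/decay timescales), so regulation has the temporal
    # precedence structure that lagged models exploit
    delays = (0.03, 0.05, 0.08, 0.1)
    lagged = {}
    for d in delays:
        s_lag = (s - d) % 1.0 if cyclic else np.maximum(s - d, 0.0)
        lagged[d] = coupled_activity(s_lag)
    target_inputs = {t: [] for t in truth.target_ids}
    for (reg, tgt), tag in truth.edge_lineage.items():
        if tgt in target_inputs:
            delay = float(rng.choice(delays))
            target_inputs[tgt].append((reg, tag, truth.edge_signs[(reg, tgt)], delay))
    for tgt, parents in target_inputs.items():
        z = np.zeros(n_cells)
        for reg, tag, w, delay in parents:
            contrib = w * (lagged[delay][gene_pos[reg]] - 0.5)
            if tag is not None and not cyclic:
                # private regulation acts only in committed cells of its
                # branch; both branches are identical before s = 0.5
                on = (branch == (0 if tag == "CT1" else 1)) & (s > 0.5)
                contrib = contrib * on
            z += contrib
        rates[gene_pos[tgt]] = _softplus(z)
    hk_scale = rng.gamma(2.0, 0.5, size=len(truth.hk_ids)) + 0.1
    rates[n_tfs + len(truth.target_ids):] = hk_scale[:, None]

    fractions = rates / rates.sum(axis=0, keepdims=True)
    library = rng.lognormal(np.log(mean_library), 0.3, size=n_cells)
    mu = fractions * library[None, :]
    if nb_dispersion is None or not np.isfinite(nb_dispersion):
        counts = rng.poisson(mu)
    else:
        p_nb = nb_dispersion / (nb_dispersion + mu)
        counts = rng.negative_binomial(nb_dispersion, p_nb)
    if dropout > 0:
        counts = counts * (rng.random(counts.shape) >= dropout)

    lineages = np.array([_LINEAGES[b] for b in branch])
    if cyclic:
        fate_rows = np.ones((n_cells, 1))
        fates = FateMatrix(fate_rows, ["CT1"])
    else:
        # (1,0)/(0,1) past the bifurcation, interpolating to (0.5,0.5) at
        # the root; commitment is sigmoidal in pseudotime, as in real fate
        # predictors, so probabilities saturate near the plateaus
        commit = 1.0 / (1.0 + np.exp(-(s - 0.45) / 0.12))
        p_own = 0.5 + 0.5 * commit
        p_own = np.clip(p_own + rng.normal(0.0, fate_noise, size=n_cells), 1e-3, 1.0 - 1e-3)
        rows = np.where(
            branch[:, None] == 0,
            np.column_stack([p_own, 1 - p_own]),
            np.column_stack([1 - p_own, p_own]),
        )
        fates = FateMatrix(rows, list(_LINEAGES))

    cell_ids = [f"cell{i}" for i in range(n_cells)]
    cm = CountMatrix(counts.astype(np.int64), genes, cell_ids)
    config = SimConfig(
        n_tfs=n_tfs,
        n_targets=len(truth.target_ids),
        n_hk=len(truth.hk_ids),
        n_cells=n_cells,
        topology=topology,
        nb_dispersion=nb_dispersion if nb_dispersion is not None else float("inf"),
        dropout=dropout,
        mean_library=mean_library,
        fate_noise=fate_noise,
        rng_seed=rng_seed,
    )
    return SimulatedDataset(
        counts=cm,
        truth=truth,
        fates=fates,
        lineage_of_cell=lineages,
        pseudotime=s,
        topology=topology,
        config=config,
    )


def simulate_dataset(config: SimConfig | None = None, **overrides) -> SimulatedDataset:
    """Convenience wrapper: simulate truth and expression in one call."""
    cfg = config or SimConfig()
    if overrides:
        cfg = SimConfig(**{**asdict(cfg), **overrides})
    truth = simulate_grn(
        n_tfs=cfg.n_tfs,
        n_targets=cfg.n_targets,
        n_hk=cfg.n_hk,
        edges_per_target=cfg.edges_per_target,
        lineage_private_fraction=cfg.lineage_private_fraction,
        rng_seed=cfg.rng_seed,
    )
    return simulate_expression(
        truth,
        topology=cfg.topology,
        n_cells=cfg.n_cells,
        nb_dispersion=cfg.nb_dispersion,
        dropout=cfg.dropout,
        mean_library=cfg.mean_library,
        fate_noise=cfg.fate_noise,
        rng_seed=cfg.rng_seed,
    )


def _write_truth_tsv(truth: GroundTruthNetwork, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\n")
        for a, b in sorted(truth.true_edges):
            fh.write(f"{a}\t{b}\n")


def write_fixture(dataset: SimulatedDataset, directory) -> None:
    """Write the dataset as plain-text files; inverse of load_fixture."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_counts(dataset.counts, directory / "counts.mtx", format="mtx")
    _write_truth_tsv(dataset.truth.global_truth, directory / "truth_global.tsv")
    for lin, net in dataset.truth.per_lineage.items():
        _write_truth_tsv(net, directory / f"truth_{lin}.tsv")
    dataset.fates.write_csv(directory / "fates.csv")
    pd.DataFrame(
        {
            "cell_id": dataset.counts.cell_ids,
            "lineage": dataset.lineage_of_cell,
            "pseudotime": dataset.pseudotime,
        }
    ).to_csv(directory / "labels.tsv", sep="\t", index=False)
    with open(directory / "config.json", "w") as fh:
        json.dump(asdict(dataset.config), fh, indent=2)


def load_fixture(directory):
    """Reload counts, truths, fates and labels written by write_fixture."""
    from .evaluation import read_ground_truth
    from .lineage_grn import read_fate_matrix

    directory = Path(directory)
    counts = load_counts(directory / "counts.mtx", format="mtx")
    with open(directory / "config.json") as fh:
        config = SimConfig(**json.load(fh))
    universe = list(counts.gene_ids)
    tfs = [g for g in universe if g.startswith("TF")]
    global_truth = read_ground_truth(
        directory / "truth_global.tsv", gene_universe=universe, regulators=tfs
    )
    per_lineage = {
        lin: read_ground_truth(
            directory / f"truth_{lin}.tsv", gene_universe=universe, regulators=tfs
        )
        for lin in _LINEAGES
        if (directory / f"truth_{lin}.tsv").exists()
    }
    fates = read_fate_matrix(directory / "fates.csv")
    labels = pd.read_csv(directory / "labels.tsv", sep="\t")
    return {
        "counts": counts,
        "truth_global": global_truth,
        "truth_per_lineage": per_lineage,
        "fates": fates,
        "lineage_of_cell": labels["lineage"].to_numpy(),
        "pseudotime": labels["pseudotime"].to_numpy(),
        "config": config,
    }
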