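"""Lineage-specific GRNs from cell-fate probabilities and the skeleton.

Cell-fate probabilities (from any external fate-prediction tool, or the
absorbing-Markov-chain fallback below) are lifted to metacell level,
metacells are clustered on their fate rows with a Gaussian mixture model
(component count by BIC), and each cluster is assigned to the lineage(s)
it is biased toward by at least ``fold_k``.  Per lineage, the member
metacells are ordered by increasing fate probability -- a proxy for travel
time from root to terminal state -- yielding a pseudo time series.  On
that series a lagged ridge (Granger) regression is fitted for every
target with its skeleton parents as regulators; the edge weight is the
absolute sum of lag coefficients, and a per-regulator rank transform
(weight -> 1/rank^2) yields the final lineage network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix, identity
from scipy.sparse.linalg import spsolve
from sklearn.mixture import GaussianMixture

from .grn_core import SkeletonNetwork, normalize_profiles
from .knn_prune import PrunedKnnGraph
from .metacell import MetacellMatrix


@dataclass
class FateMatrix:
    """Rows = cells (or metacells), columns = terminal-state probabilities."""

    probs: np.ndarray
    fate_labels: list

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if np.any(probs < 0) or np.any(probs > 1 + 1e-9):
            raise ValueError("fate probabilities must lie in [0, 1]")
        sums = probs.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("fate row with zero total probability")
        self.probs = probs / sums[:, None]
        self.fate_labels = [str(f) for f in self.fate_labels]

    @property
    def n_fates(self) -> int:
        return self.probs.shape[1]

    def write_csv(self, path, index=None) -> None:
        pd.DataFrame(self.probs, columns=self.fate_labels, index=index).to_csv(
            path, index=index is not None
        )


def read_fate_matrix(path, index_col=None) -> FateMatrix:
    df = pd.read_csv(path, index_col=index_col)
    return FateMatrix(df.to_numpy(), list(df.columns))


@dataclass
class LineageAssignment:
    cluster_of: np.ndarray  # metacell -> GMM component
    cluster_fates: dict  # component -> tuple of fate labels ("" set = uncertain)
    lineage_members: dict  # fate label -> sorted metacell index array
    uncertain: np.ndarray
    fold_k: float
    n_components: int
    bic_trace: np.ndarray


@dataclass
class LineageSeries:
    """One lineage's metacells ordered as a pseudo time series."""

    expression: np.ndarray  # genes x T
    gene_ids: list
    metacell_order: np.ndarray  # original metacell indices, time order
    fate_probability: np.ndarray  # ordering key, increasing
    lineage: str

    @property
    def T(self) -> int:
        return self.expression.shape[1]


@dataclass
class GrangerCoeffs:
    coeffs: np.ndarray  # P regulators x L lags
    regulators: list
    target: str
    lambda_reg: float
    L: int
    intercept: float = 0.0


@dataclass
class LineageGrn:
    """Granger edge-weight matrix G and its rank transform G_tilde."""

    G: np.ndarray  # regulators x targets
    G_tilde: np.ndarray
    regulator_ids: list
    target_ids: list
    lineage: str

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("regulator\ttarget\tgranger_weight\trank_weight\n")
            for r, reg in enumerate(self.regulator_ids):
                for t, tgt in enumerate(self.target_ids):
                    if self.G_tilde[r, t] > 0 or self.G[r, t] > 0:
                        fh.write(
                            f"{reg}\t{tgt}\t{self.G[r, t]:.10g}\t"
                            f"{self.G_tilde[r, t]:.10g}\n"
                        )


def metacell_fate_probabilities(
    fates: FateMatrix, assignment_or_members
) -> FateMatrix:
    """Average member cells' fate rows per metacell, renormalized."""
    if isinstance(assignment_or_members, MetacellMatrix):
        member_lists = assignment_or_members.member_lists
    else:
        member_lists = assignment_or_members
    rows = []
    for mem in member_lists:
        mem = np.asarray(mem, dtype=int)
        if mem.size == 0:
            raise ValueError("metacell with no fate-annotated members")
        rows.append(fates.probs[mem].mean(axis=0))
    return FateMatrix(np.vstack(rows), list(fates.fate_labels))


def _biased_fates(mean_row: np.ndarray, fold_k: float) -> tuple:
    """Fates a cluster is biased toward; empty tuple = uncertain.

    A = fates within factor fold_k of the maximum mean probability.  The
    cluster is assigned to A when A is a strict subset of all fates and
    every fate in A is at least fold_k-fold above every fate outside A;
    otherwise it is uncertain.
    """
    n = len(mean_row)
    top = mean_row.max()
    if top <= 0:
        return ()
    in_a = mean_row * fold_k >= top
    if in_a.all():
        return ()
    out_max = mean_row[~in_a].max()
    if mean_row[in_a].min() >= fold_k * out_max:
        return tuple(int(i) for i in np.flatnonzero(in_a))
    return ()


def cluster_fates(
    fates: FateMatrix,
    fold_k: float = 2.0,
    max_components: int = 10,
    rng_seed: int = 0,
) -> LineageAssignment:
    """GMM-cluster metacell fate rows and assign clusters to lineages.

    Component count is chosen by BIC over 1..max_components (full
    covariance).  A cluster belongs to every fate it is at least
    ``fold_k``-fold biased toward; clusters with comparable probabilities
    toward all fates are uncertain and belong to every lineage.
    """
    if fates.n_fates < 2:
        raise ValueError("need at least 2 fates")
    X = fates.probs
    n = X.shape[0]
    bics, models = [], []
    for k in range(1, min(max_components, n) + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            random_state=rng_seed,
            reg_covar=1e-6,
            n_init=1,
        )
        gm.fit(X)
        bics.append(gm.bic(X))
        models.append(gm)
    best = int(np.argmin(bics))
    gm = models[best]
    labels = gm.predict(X)
    cluster_fate_sets = {}
    for c in range(gm.n_components):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            cluster_fate_sets[c] = ()
            continue
        mean_row = X[members].mean(axis=0)
        cluster_fate_sets[c] = _biased_fates(mean_row, fold_k)
    uncertain = np.array(
        sorted(
            i
            for i in range(n)
            if cluster_fate_sets[labels[i]] == ()
        ),
        dtype=int,
    )
    lineage_members = {}
    for f_i, label in enumerate(fates.fate_labels):
        assigned = [
            i for i in range(n) if f_i in cluster_fate_sets[labels[i]]
        ]
        lineage_members[label] = np.array(
            sorted(set(assigned) | set(uncertain.tolist())), dtype=int
        )
    if all(s == () for s in cluster_fate_sets.values()):
        warnings.warn(
            "no cluster shows fold-k fate dominance; every metacell joins "
            "every lineage",
            stacklevel=2,
        )
    return LineageAssignment(
        cluster_of=labels,
        cluster_fates={c: tuple(fates.fate_labels[i] for i in s) for c, s in cluster_fate_sets.items()},
        lineage_members=lineage_members,
        uncertain=uncertain,
        fold_k=fold_k,
        n_components=gm.n_components,
        bic_trace=np.array(bics),
    )


def order_lineage_metacells(
    metacells: MetacellMatrix,
    fates: FateMatrix,
    assignment: LineageAssignment,
    lineage: str,
    normalize: bool = True,
) -> LineageSeries:
    """Sort a lineage's metacells by increasing fate probability.

    Increasing probability toward the terminal state is the root-to-
    terminal time arrow; ties are broken by metacell index.
    """
    if lineage not in assignment.lineage_members:
        raise KeyError(f"unknown lineage {lineage!r}")
    members = assignment.lineage_members[lineage]
    if members.size == 0:
        raise ValueError(f"lineage {lineage!r} has no metacells")
    f_i = fates.fate_labels.index(lineage)
    key = fates.probs[members, f_i]
    order = np.lexsort((members, key))
    ordered = members[order]
    expr = (
        normalize_profiles(metacells.values)
        if normalize
        else metacells.values.astype(float)
    )
    return LineageSeries(
        expression=expr[:, ordered],
        gene_ids=list(metacells.gene_ids),
        metacell_order=ordered,
        fate_probability=key[order],
        lineage=lineage,
    )


def _effective_lag(T: int, L: int) -> int:
    """Reduce the lag when the series is short; keeps >= ~2/3 of rows."""
    if T > L + 5:
        return L
    return max(1, (T - 1) // 3)


def _group_lasso_fista(X, y, groups, lam, n_iter=600, tol=1e-9):
    """min ½||y - Xa||² + lam·Σ_g ||a_g||₂ via FISTA with group prox."""
    n_feat = X.shape[1]
    a = np.zeros(n_feat)
    z = a.copy()
    t_mom = 1.0
    lip = float(np.linalg.norm(X, 2) ** 2)
    step = 1.0 / max(lip, 1e-12)
    XtX = X.T @ X
    Xty = X.T @ y
    for _ in range(n_iter):
        grad = XtX @ z - Xty
        w = z - step * grad
        a_new = w.copy()
        for g in groups:
            norm = np.linalg.norm(w[g])
            scale = max(0.0, 1.0 - lam * step / norm) if norm > 0 else 0.0
            a_new[g] = w[g] * scale
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        z = a_new + ((t_mom - 1.0) / t_new) * (a_new - a)
        if np.max(np.abs(a_new - a)) < tol:
            a = a_new
            break
        a, t_mom = a_new, t_new
    return a


def fit_granger(
    series: LineageSeries,
    skeleton: SkeletonNetwork,
    target: str,
    L: int = 30,
    lambda_reg: float = 150.0,
    penalty: str = "l2",
) -> GrangerCoeffs:
    """Lagged penalized regression of one target on its skeleton parents.

    The target's expression at time t is predicted from its regulators'
    expression at t-1..t-L.  With ``penalty="l2"`` (default) coefficients
    minimize squared error plus lambda times the squared L2 norm of all
    lag coefficients -- standard ridge with a closed-form solution.  With
    ``penalty="group"`` the penalty is lambda times the sum over
    regulators of the unsquared L2 norm of that regulator's lag-
    coefficient block (group lasso), which can zero out entire regulators
    and so yields a sparser, more lineage-discriminative network; it is
    solved by proximal gradient (FISTA).  The intercept is unpenalized
    (via centering) and all series are standardized per gene before
    fitting so lambda is scale-meaningful.
    """
    regs = [
        skeleton.regulator_ids[r]
        for r in range(len(skeleton.regulator_ids))
        if skeleton.adjacency[r, skeleton.target_ids.index(target)]
        and skeleton.regulator_ids[r] != target
    ]
    if not regs:
        raise ValueError(f"target {target!r} has no skeleton regulators")
    T = series.T
    L_eff = _effective_lag(T, L)
    if T <= L_eff + 5:
        raise ValueError(
            f"lineage {series.lineage!r} too short: T={T} <= L_eff+5={L_eff + 5}"
        )
    gene_pos = {g: i for i, g in enumerate(series.gene_ids)}

    def standardized(g):
        x = series.expression[gene_pos[g]].astype(float)
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else x - x.mean()

    y_full = standardized(target)
    P = len(regs)
    rows = T - L_eff
    X = np.empty((rows, P * L_eff))
    for j, reg in enumerate(regs):
        xj = standardized(reg)
        for l in range(1, L_eff + 1):
            X[:, j * L_eff + (l - 1)] = xj[L_eff - l : T - l]
    y = y_full[L_eff:]
    # unpenalized intercept via centering
    Xm = X.mean(axis=0)
    Xc = X - Xm
    ym = y.mean()
    if penalty == "l2":
        A = Xc.T @ Xc + lambda_reg * np.eye(X.shape[1])
        a = np.linalg.solve(A, Xc.T @ (y - ym))
    elif penalty == "group":
        blocks = [
            np.arange(j * L_eff, (j + 1) * L_eff) for j in range(P)
        ]
        a = _group_lasso_fista(Xc, y - ym, blocks, lambda_reg)
    else:
        raise ValueError(f"unknown penalty {penalty!r}")
    intercept = ym - float(Xm @ a)
    return GrangerCoeffs(
        coeffs=a.reshape(P, L_eff),
        regulators=regs,
        target=target,
        lambda_reg=lambda_reg,
        L=L_eff,
        intercept=intercept,
    )


def granger_edge_weights(coeffs: GrangerCoeffs) -> dict:
    """Edge weight per regulator: |sum over lags of the coefficients|."""
    sums = coeffs.coeffs.sum(axis=1)
    return {reg: float(abs(s)) for reg, s in zip(coeffs.regulators, sums)}


def rank_transform(
    G: np.ndarray, skeleton: SkeletonNetwork | None = None
) -> np.ndarray:
    """Per-regulator rank transform: k-th ranked target -> 1/k^2.

    Interacting targets are the skeleton edges when a skeleton is given,
    otherwise the nonzero entries of G.  Ranking is by decreasing weight,
    ties toward the lower target index; non-interacting entries are zero.
    """
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise ValueError("G must be non-negative")
    out = np.zeros_like(G)
    for r in range(G.shape[0]):
        interacting = (
            np.flatnonzero(skeleton.adjacency[r])
            if skeleton is not None
            else np.flatnonzero(G[r] > 0)
        )
        if interacting.size == 0:
            continue
        order = np.lexsort((interacting, -G[r, interacting]))
        ranked = interacting[order]
        out[r, ranked] = 1.0 / (np.arange(1, len(ranked) + 1) ** 2)
    return out


def infer_lineage_grn(
    metacells: MetacellMatrix,
    fates: FateMatrix,
    assignment: LineageAssignment,
    skeleton: SkeletonNetwork,
    lineage: str,
    L: int = 30,
    lambda_reg: float = 150.0,
    penalty: str = "l2",
) -> LineageGrn:
    """Full per-lineage pipeline: order, fit Granger per target, rank."""
    series = order_lineage_metacells(metacells, fates, assignment, lineage)
    n_reg = len(skeleton.regulator_ids)
    n_tgt = len(skeleton.target_ids)
    G = np.zeros((n_reg, n_tgt))
    reg_pos = {g: i for i, g in enumerate(skeleton.regulator_ids)}
    for t, tgt in enumerate(skeleton.target_ids):
        parents = [
            skeleton.regulator_ids[r]
            for r in np.flatnonzero(skeleton.adjacency[:, t])
            if skeleton.regulator_ids[r] != tgt
        ]
        if not parents:
            continue
        coeffs = fit_granger(
            series, skeleton, tgt, L=L, lambda_reg=lambda_reg, penalty=penalty
        )
        for reg, w in granger_edge_weights(coeffs).items():
            G[reg_pos[reg], t] = w
    G_tilde = rank_transform(G, skeleton)
    return LineageGrn(
        G=G,
        G_tilde=G_tilde,
        regulator_ids=list(skeleton.regulator_ids),
        target_ids=list(skeleton.target_ids),
        lineage=lineage,
    )


def markov_fate_probabilities(
    pruned: PrunedKnnGraph, terminal_cells: dict, n_cells: int | None = None
) -> FateMatrix:
    """Absorption probabilities of a random walk on the pruned graph.

    Transition weights are the link probabilities (symmetrized by
    maximum), rows normalized; the terminal cell sets are absorbing, one
    fate per set.  A plumbing fallback for when no external fate
    prediction is available.
    """
    labels = list(terminal_cells)
    sets = [np.asarray(sorted(terminal_cells[l]), dtype=int) for l in labels]
    flat = np.concatenate(sets) if sets else np.array([], dtype=int)
    if len(labels) == 0 or any(len(s) == 0 for s in sets):
        raise ValueError("terminal sets must be non-empty")
    if len(np.unique(flat)) != len(flat):
        raise ValueError("terminal sets must be disjoint")
    if n_cells is None:
        n_cells = int(
            max(
                pruned.cells.max(initial=0),
                max((nb.max() for nb in pruned.neighbors if len(nb)), default=0),
                flat.max(initial=0),
            )
        ) + 1
    # symmetric weighted adjacency (max of directed link probabilities)
    W: dict[tuple, float] = {}
    for c, nb, pr in zip(pruned.cells, pruned.neighbors, pruned.probs):
        for n, p in zip(nb, pr):
            key = (int(c), int(n))
            W[key] = max(W.get(key, 0.0), float(p))
            rkey = (int(n), int(c))
            W[rkey] = max(W.get(rkey, 0.0), float(p))
    terminal_fate = np.full(n_cells, -1, dtype=int)
    for f_i, s in enumerate(sets):
        terminal_fate[s] = f_i
    transient = np.flatnonzero(terminal_fate < 0)
    t_pos = {c: i for i, c in enumerate(transient)}
    nQ = len(transient)
    k = len(labels)
    rows_q, cols_q, vals_q = [], [], []
    R = np.zeros((nQ, k))
    deg = np.zeros(n_cells)
    for (u, v), w in W.items():
        deg[u] += w
    for (u, v), w in W.items():
        if terminal_fate[u] >= 0:
            continue
        iu = t_pos[u]
        p = w / deg[u]
        if terminal_fate[v] >= 0:
            R[iu, terminal_fate[v]] += p
        else:
            rows_q.append(iu)
            cols_q.append(t_pos[v])
            vals_q.append(p)
    probs = np.zeros((n_cells, k))
    for f_i, s in enumerate(sets):
        probs[s, f_i] = 1.0
    if nQ:
        Q = csr_matrix((vals_q, (rows_q, cols_q)), shape=(nQ, nQ))
        A = identity(nQ, format="csr") - Q
        B = np.column_stack(
            [spsolve(A.tocsc(), R[:, f]) for f in range(k)]
        ) if k > 1 else spsolve(A.tocsc(), R[:, 0])[:, None]
        B = np.asarray(B).reshape(nQ, k)
        sums = B.sum(axis=1)
        stranded = sums < 1e-9
        if np.any(stranded):
            warnings.warn(
                f"{int(stranded.sum())} cell(s) cannot reach any terminal set; "
                "uniform fate rows assigned",
                stacklevel=2,
            )
            B[stranded] = 1.0 / k
        probs[transient] = B
    return FateMatrix(probs, labels)
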