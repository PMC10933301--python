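"""Flow-based reef clustering via the two-level map equation.

A connectivity matrix is read as a directed, weighted graph over reef
groups.  A random walker follows edges in proportion to their weight and,
with a small probability ``tau_tel`` (1% by default), teleports to a
uniformly chosen node; teleportation regularises the stationary
distribution but the teleport jumps themselves are not encoded (unrecorded
teleportation).  The two-level map equation scores a partition M of the
nodes by the description length, in bits per step, of that walk:

    L(M) = q * H(Q) + sum_m p_m * H(P_m)

where q is the total inter-module (exit) flow, H(Q) the entropy of the
per-module exit flows, and H(P_m) the entropy of module m's exit and
within-module visit rates.  Minimising L(M) with a seeded greedy
node-moving + module-merging search yields modules of reefs that tend to
retain larvae.

Clustering *consistency* across a bootstrap ensemble is quantified by
canonicalising module labels per replicate (renumbered by decreasing
module flow), stacking them into a groups x replicates membership matrix,
and running a centred PCA over it: the leading component's score
separation acts as a proxy for how consistently pairs of reefs share a
module — a persistent dispersal barrier shows up as a PC1 gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .connectivity import ConnectivityMatrix

__all__ = [
    "FlowGraph",
    "Partition",
    "MembershipMatrix",
    "ConsistencyPCA",
    "stationary_distribution",
    "map_equation",
    "optimize_partition",
    "canonicalise_labels",
    "consistency_pca",
]

_STATIONARY_TOL = 1e-12
_STATIONARY_MAX_ITER = 100_000


@dataclass
class FlowGraph:
    """Directed weighted graph with uniform teleportation.

    ``weights[i, j]`` >= 0 is the flow weight i -> j; nodes with no
    out-weight (dangling) move by pure teleportation.
    """

    node_labels: np.ndarray
    weights: np.ndarray
    tau_tel: float = 0.01

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.node_labels = np.asarray(self.node_labels)
        n = len(self.node_labels)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix must be square on the node labels")
        if np.any(self.weights < 0):
            raise ValueError("edge weights must be non-negative")
        if not np.any(self.weights > 0):
            raise ValueError("graph needs at least one edge")
        if not (0.0 <= self.tau_tel < 1.0):
            raise ValueError("teleportation probability must lie in [0, 1)")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @classmethod
    def from_connectivity(
        cls, matrix: ConnectivityMatrix, tau_tel: float = 0.01
    ) -> "FlowGraph":
        return cls(matrix.labels.copy(), matrix.values.copy(), tau_tel)


def stationary_distribution(graph: FlowGraph) -> np.ndarray:
    """Visit rates p of the teleportation-adjusted random walk.

    Power iteration on p <- tau/n + (1 - tau) * (p P + p_dangling / n),
    where P row-normalises the weights and dangling rows redistribute
    uniformly; converged when the L1 change drops below 1e-12.  Sums to 1.
    """
    w = graph.weights
    n = graph.n_nodes
    out = w.sum(axis=1)
    dangling = out == 0
    p_mat = np.zeros_like(w)
    p_mat[~dangling] = w[~dangling] / out[~dangling, None]
    tau = graph.tau_tel
    p = np.full(n, 1.0 / n)
    for _ in range(_STATIONARY_MAX_ITER):
        link = p @ p_mat + p[dangling].sum() / n
        p_new = tau / n + (1.0 - tau) * link
        if np.abs(p_new - p).sum() < _STATIONARY_TOL:
            return p_new / p_new.sum()
        p = p_new
    raise RuntimeError(
        f"stationary distribution failed to converge in {_STATIONARY_MAX_ITER} iterations"
    )


@dataclass
class Partition:
    """Module assignment per node (ids contiguous from 1) with codelength."""

    modules: np.ndarray  # (n,) int, 1-based
    codelength: float

    def __post_init__(self):
        self.modules = np.asarray(self.modules, dtype=int)
        ids = np.unique(self.modules)
        if len(ids) == 0 or ids[0] != 1 or not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValueError("module ids must be contiguous from 1")

    @property
    def n_modules(self) -> int:
        return int(self.modules.max())


def _normalise_labels(modules: np.ndarray) -> np.ndarray:
    """Relabel to contiguous 1..K in order of first appearance."""
    out = np.empty_like(modules)
    mapping: dict[int, int] = {}
    for i, m in enumerate(modules):
        if m not in mapping:
            mapping[m] = len(mapping) + 1
        out[i] = mapping[m]
    return out


def _link_flow(graph: FlowGraph, p: np.ndarray) -> np.ndarray:
    """Per-edge walker flow q_ij = (1 - tau) * p_i * W_ij / W_i.

    Teleport jumps are unrecorded: only link transitions carry codelength;
    dangling nodes emit no link flow.
    """
    w = graph.weights
    out = w.sum(axis=1)
    safe = np.where(out == 0, 1.0, out)
    q = (1.0 - graph.tau_tel) * (p / safe)[:, None] * w
    q[out == 0] = 0.0
    return q


def _plogp(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log2(x[pos])
    return out


def _codelength(modules: np.ndarray, p: np.ndarray, q: np.ndarray, n_mod: int) -> float:
    """Two-level map-equation codelength in bits for a 1..n_mod labelling."""
    m = modules - 1
    if np.any(np.bincount(m, minlength=n_mod) == 0):
        raise ValueError("partition contains an empty module")
    p_mod = np.zeros(n_mod)
    np.add.at(p_mod, m, p)
    # exit flow per module: all link flow leaving the module
    same = m[:, None] == m[None, :]
    exit_mod = np.zeros(n_mod)
    np.add.at(exit_mod, m, np.where(same, 0.0, q).sum(axis=1))
    q_tot = exit_mod.sum()
    l = (
        _plogp(np.array([q_tot])).item()
        - 2.0 * _plogp(exit_mod).sum()
        + _plogp(exit_mod + p_mod).sum()
        - _plogp(p).sum()
    )
    return float(l)


def map_equation(graph: FlowGraph, modules: np.ndarray) -> float:
    """Codelength (bits per walk step) of a module assignment.

    ``modules`` is one id per node; ids are made contiguous internally.
    Entropies use base-2 logs with 0*log 0 = 0; with a single module and no
    teleportation this reduces to the entropy of the visit rates.
    """
    modules = np.asarray(modules, dtype=int)
    if len(modules) != graph.n_nodes:
        raise ValueError("one module id per node required")
    ids = np.unique(modules)
    if len(ids) != ids[-1] - ids[0] + 1:
        raise ValueError("partition contains an empty module (gapped module ids)")
    modules = modules - ids[0] + 1
    p = stationary_distribution(graph)
    q = _link_flow(graph, p)
    return _codelength(modules, p, q, int(modules.max()))


def optimize_partition(
    graph: FlowGraph, seed: int = 0, n_restarts: int = 10
) -> Partition:
    """Greedy two-level map-equation minimisation.

    Each restart shuffles the node order, then alternates (a) node-moving
    sweeps — every node is tried in the modules of its in/out neighbours
    and moved to the best strict codelength decrease, ties resolved toward
    the lowest module id — and (b) a module-merging pass over connected
    module pairs, until a local minimum.  The best of ``n_restarts`` seeded
    restarts is returned; its codelength never exceeds the one-module
    codelength.  Deterministic for a given seed.
    """
    p = stationary_distribution(graph)
    q = _link_flow(graph, p)
    n = graph.n_nodes
    neighbours = [
        np.nonzero((graph.weights[i] > 0) | (graph.weights[:, i] > 0))[0]
        for i in range(n)
    ]
    rng = np.random.default_rng(seed)
    one_mod = _codelength(np.ones(n, dtype=int), p, q, 1)
    best_modules = np.ones(n, dtype=int)
    best_l = one_mod

    for _ in range(max(1, n_restarts)):
        order = rng.permutation(n)
        modules = np.arange(1, n + 1)  # start from singletons
        current = _codelength(modules, p, q, n)
        improved = True
        while improved:
            improved = False
            # (a) node moving
            for v in order:
                cand = {int(modules[u]) for u in neighbours[v]} | {int(modules[v])}
                best_move, best_move_l = int(modules[v]), current
                for mod in sorted(cand):
                    if mod == modules[v]:
                        continue
                    trial = modules.copy()
                    trial[v] = mod
                    trial = _normalise_labels(trial)
                    l = _codelength(trial, p, q, int(trial.max()))
                    if l < best_move_l - 1e-13:
                        best_move, best_move_l = mod, l
                if best_move != modules[v]:
                    modules[v] = best_move
                    modules = _normalise_labels(modules)
                    current = best_move_l
                    improved = True
            # (b) module merging
            n_mod = int(modules.max())
            merged = True
            while merged and n_mod > 1:
                merged = False
                best_pair, best_pair_l = None, current
                for a in range(1, n_mod + 1):
                    for b in range(a + 1, n_mod + 1):
                        trial = np.where(modules == b, a, modules)
                        trial = _normalise_labels(trial)
                        l = _codelength(trial, p, q, int(trial.max()))
                        if l < best_pair_l - 1e-13:
                            best_pair, best_pair_l = (a, b), l
                if best_pair is not None:
                    a, b = best_pair
                    modules = _normalise_labels(np.where(modules == b, a, modules))
                    current = best_pair_l
                    n_mod = int(modules.max())
                    merged = True
                    improved = True
        if current < best_l - 1e-13:
            best_modules, best_l = modules.copy(), current

    return Partition(_normalise_labels(best_modules), min(best_l, one_mod))


# ---------------------------------------------------------------------------
# Membership canonicalisation and consistency PCA
# ---------------------------------------------------------------------------


@dataclass
class MembershipMatrix:
    """Canonical module ids, shape (n_groups, n_replicates)."""

    group_labels: np.ndarray
    assignments: np.ndarray

    def __post_init__(self):
        self.assignments = np.asarray(self.assignments, dtype=int)
        if self.assignments.shape[0] != len(self.group_labels):
            raise ValueError("one row per reef group required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.assignments,
            index=self.group_labels,
            columns=[f"rep_{r}" for r in range(self.assignments.shape[1])],
        )


def canonicalise_labels(
    partitions: list[Partition] | list[np.ndarray],
    flows: np.ndarray,
    group_labels: np.ndarray,
) -> MembershipMatrix:
    """Align arbitrary module ids across replicates for comparability.

    Within each replicate, modules are renumbered 1..K in decreasing total
    stationary flow (``flows`` is (n_groups, n_replicates) or a single
    (n_groups,) vector shared by all replicates); ties go to the lowest
    original id.  Co-assignment structure is untouched — only labels move.
    """
    cols = []
    arrs = [p.modules if isinstance(p, Partition) else np.asarray(p) for p in partitions]
    flows = np.asarray(flows, dtype=float)
    if flows.ndim == 1:
        flows = np.repeat(flows[:, None], len(arrs), axis=1)
    for r, modules in enumerate(arrs):
        ids = np.unique(modules)
        totals = {int(m): flows[modules == m, r].sum() for m in ids}
        # decreasing flow, ties -> lowest original id
        ranked = sorted(totals, key=lambda m: (-totals[m], m))
        mapping = {m: k + 1 for k, m in enumerate(ranked)}
        cols.append(np.array([mapping[int(m)] for m in modules]))
    return MembershipMatrix(np.asarray(group_labels), np.column_stack(cols))


@dataclass
class ConsistencyPCA:
    """PCA of the membership matrix: groups are observations, replicates
    variables.  ``scores`` holds per-group PC coordinates."""

    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame
    degenerate: bool = False

    def __post_init__(self):
        evr = self.explained_variance_ratio
        if not self.degenerate:
            if np.any(evr < -1e-12) or np.any(np.diff(evr) > 1e-12) or evr.sum() > 1 + 1e-9:
                raise ValueError("explained variance ratios must be in [0,1], "
                                 "non-increasing, summing to <= 1")


def consistency_pca(membership: MembershipMatrix) -> ConsistencyPCA:
    """Centred (not scaled) PCA of the integer membership matrix.

    PC1 score differences between reef groups proxy how consistently those
    groups share a module across the bootstrap ensemble.  A membership
    matrix with no variance at all (every replicate a single module) is
    flagged degenerate rather than propagating NaNs.
    """
    x = membership.assignments.astype(float)
    if x.shape[1] < 2:
        raise ValueError("at least two replicates are required")
    if np.allclose(x, x.mean(axis=0, keepdims=True)):
        scores = pd.DataFrame(
            np.zeros((x.shape[0], 1)), index=membership.group_labels, columns=["PC1"]
        )
        return ConsistencyPCA(np.array([0.0]), scores, degenerate=True)
    n_comp = min(x.shape[0], x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(x)
    scores = pd.DataFrame(
        coords,
        index=membership.group_labels,
        columns=[f"PC{k + 1}" for k in range(coords.shape[1])],
    )
    return ConsistencyPCA(pca.explained_variance_ratio_, scores)
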