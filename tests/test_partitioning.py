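"""Map-equation clustering against an independently coded oracle.

The oracle computes visit rates by dense linear algebra and the two-level
codelength directly from its entropy definition, and the optimiser is
checked against exhaustive enumeration of all set partitions on small
graphs.
"""

import itertools

import numpy as np
import pytest

import reefconn as rc
from reefconn.partitioning import FlowGraph, MembershipMatrix


# ---------------------------------------------------------------------------
# Independent oracle
# ---------------------------------------------------------------------------


def oracle_stationary(w, tau):
    """Uniform-start limit of the teleportation-adjusted chain, computed by
    dense matrix squaring of the lazy chain (the lazy step removes
    periodicity; disconnected graphs keep each component's uniform share)."""
    n = len(w)
    out = w.sum(axis=1)
    p_mat = np.zeros_like(w, dtype=float)
    for i in range(n):
        if out[i] > 0:
            p_mat[i] = w[i] / out[i]
        else:
            p_mat[i] = 1.0 / n  # dangling: uniform
    t = tau / n + (1 - tau) * p_mat
    lazy = 0.5 * (np.eye(n) + t)
    power = np.linalg.matrix_power(lazy, 2**13)
    p = np.full(n, 1.0 / n) @ power
    return p / p.sum()


def oracle_codelength(w, tau, modules):
    """Two-level map equation, written from its entropy definition."""

    def entropy(probs):
        probs = np.asarray([q for q in probs if q > 0])
        return -(probs * np.log2(probs)).sum() if len(probs) else 0.0

    n = len(w)
    p = oracle_stationary(w, tau)
    out = w.sum(axis=1)
    q = np.zeros((n, n))
    for i in range(n):
        if out[i] > 0:
            q[i] = (1 - tau) * p[i] * w[i] / out[i]
    mods = sorted(set(modules))
    exits = {}
    for m in mods:
        members = [i for i in range(n) if modules[i] == m]
        exits[m] = sum(
            q[i, j] for i in members for j in range(n) if modules[j] != m
        )
    q_tot = sum(exits.values())
    index_term = q_tot * entropy([exits[m] / q_tot for m in mods]) if q_tot > 0 else 0.0
    module_term = 0.0
    for m in mods:
        members = [i for i in range(n) if modules[i] == m]
        p_circ = exits[m] + sum(p[i] for i in members)
        if p_circ > 0:
            probs = [exits[m] / p_circ] + [p[i] / p_circ for i in members]
            module_term += p_circ * entropy(probs)
    return index_term + module_term


def set_partitions(n):
    """All partitions of range(n) as module-label tuples (restricted growth)."""

    def rec(prefix, k):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for m in range(1, k + 2):
            yield from rec(prefix + [m], max(k, m))

    yield from rec([1], 1)


def oracle_best(w, tau):
    best_l, best_m = np.inf, None
    for modules in set_partitions(len(w)):
        l = oracle_codelength(w, tau, modules)
        if l < best_l - 1e-13:
            best_l, best_m = l, modules
    return best_l, best_m


# ---------------------------------------------------------------------------
# Fixture graphs
# ---------------------------------------------------------------------------


def two_cliques(n_half=4, cross=0.0):
    n = 2 * n_half
    w = np.zeros((n, n))
    for blk in (range(n_half), range(n_half, n)):
        for i in blk:
            for j in blk:
                if i != j:
                    w[i, j] = 1.0
    if cross:
        w[0, n_half] = w[n_half, 0] = cross
    return w


def uniform_complete(n):
    return np.ones((n, n)) - np.eye(n)


def directed_cycle(n):
    w = np.zeros((n, n))
    for i in range(n):
        w[i, (i + 1) % n] = 1.0
    return w


def star(n):
    w = np.zeros((n, n))
    w[0, 1:] = 1.0
    w[1:, 0] = 1.0
    return w


def random_digraph(n, seed):
    rng = np.random.default_rng(seed)
    w = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
    np.fill_diagonal(w, 0.0)
    if not w.any():
        w[0, 1] = 1.0
    return w


FIXTURE_GRAPHS = [
    ("two_cliques_separated", two_cliques(4, 0.0), 0.0),
    ("two_cliques_separated_tel", two_cliques(4, 0.0), 0.01),
    ("two_cliques_weak_bridge", two_cliques(3, 0.05), 0.01),
    ("uniform_k4", uniform_complete(4), 0.0),
    ("uniform_k6", uniform_complete(6), 0.01),
    ("directed_cycle5", directed_cycle(5), 0.01),
    ("star6", star(6), 0.01),
    ("random5", random_digraph(5, 1), 0.01),
    ("random6", random_digraph(6, 2), 0.01),
]


# ---------------------------------------------------------------------------
# Stationary distribution
# ---------------------------------------------------------------------------


class TestStationaryDistribution:
    def test_symmetric_two_nodes(self):
        g = FlowGraph(np.arange(2), np.array([[0.0, 1.0], [1.0, 0.0]]), 0.0)
        assert np.allclose(rc.stationary_distribution(g), [0.5, 0.5])

    def test_star_matches_dense_solve(self):
        w = star(6)
        g = FlowGraph(np.arange(6), w, 0.01)
        assert np.allclose(
            rc.stationary_distribution(g), oracle_stationary(w, 0.01), atol=1e-10
        )

    def test_dangling_nodes_get_uniform_share(self):
        # only one edge; the two other nodes are dangling
        w = np.zeros((3, 3))
        w[0, 1] = 1.0
        g = FlowGraph(np.arange(3), w, 0.01)
        p = rc.stationary_distribution(g)
        assert np.allclose(p, oracle_stationary(w, 0.01), atol=1e-10)
        assert p.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Codelength
# ---------------------------------------------------------------------------


class TestMapEquation:
    def test_uniform_cycle_one_module_two_bits(self):
        g = FlowGraph(np.arange(4), directed_cycle(4), 0.0)
        assert rc.map_equation(g, np.ones(4, dtype=int)) == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize("name,w,tau", [(n, w, t) for n, w, t in FIXTURE_GRAPHS])
    def test_matches_independent_implementation(self, name, w, tau):
        g = FlowGraph(np.arange(len(w)), w, tau)
        rng = np.random.default_rng(0)
        partitions = [np.ones(len(w), dtype=int), np.arange(1, len(w) + 1)]
        partitions += [rng.integers(1, 3, len(w)) for _ in range(3)]
        for modules in partitions:
            modules = np.asarray(
                rc.partitioning._normalise_labels(np.asarray(modules))
            )
            assert rc.map_equation(g, modules) == pytest.approx(
                oracle_codelength(w, tau, list(modules)), abs=1e-12
            )

    def test_zero_flow_merge_never_helps(self):
        w = two_cliques(4, 0.0)
        g = FlowGraph(np.arange(8), w, 0.0)
        split = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        assert rc.map_equation(g, split) <= rc.map_equation(g, np.ones(8, dtype=int))

    def test_empty_module_rejected(self):
        g = FlowGraph(np.arange(4), directed_cycle(4), 0.0)
        with pytest.raises(ValueError, match="empty module"):
            rc.map_equation(g, np.array([1, 1, 3, 3]))


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------


class TestOptimizePartition:
    @pytest.mark.parametrize("name,w,tau", [(n, w, t) for n, w, t in FIXTURE_GRAPHS])
    def test_matches_exhaustive_enumeration(self, name, w, tau):
        g = FlowGraph(np.arange(len(w)), w, tau)
        part = rc.optimize_partition(g, seed=0, n_restarts=10)
        best_l, _ = oracle_best(w, tau)
        assert part.codelength == pytest.approx(best_l, abs=1e-12)

    def test_recovers_two_cliques(self):
        g = FlowGraph(np.arange(8), two_cliques(4, 0.0), 0.0)
        part = rc.optimize_partition(g, seed=0)
        assert len(set(part.modules[:4])) == 1
        assert len(set(part.modules[4:])) == 1
        assert part.modules[0] != part.modules[4]

    def test_uniform_complete_graph_stays_one_module(self):
        g = FlowGraph(np.arange(4), uniform_complete(4), 0.0)
        part = rc.optimize_partition(g, seed=0)
        assert part.n_modules == 1

    def test_never_worse_than_one_module(self):
        for name, w, tau in FIXTURE_GRAPHS:
            g = FlowGraph(np.arange(len(w)), w, tau)
            part = rc.optimize_partition(g, seed=3, n_restarts=3)
            one = rc.map_equation(g, np.ones(len(w), dtype=int))
            assert part.codelength <= one + 1e-12

    def test_deterministic_under_seed(self):
        w = random_digraph(6, 5)
        g = FlowGraph(np.arange(6), w, 0.01)
        a = rc.optimize_partition(g, seed=7)
        b = rc.optimize_partition(g, seed=7)
        assert np.array_equal(a.modules, b.modules)
        assert a.codelength == b.codelength


# ---------------------------------------------------------------------------
# Canonicalisation and PCA
# ---------------------------------------------------------------------------


class TestCanonicalise:
    def test_permuted_labels_align(self):
        flows = np.array([0.4, 0.3, 0.2, 0.1])
        reps = [np.array([1, 1, 2, 2]), np.array([2, 2, 1, 1])]
        mm = rc.canonicalise_labels(reps, flows, np.arange(4))
        assert np.array_equal(mm.assignments[:, 0], mm.assignments[:, 1])
        # module holding most flow gets label 1
        assert mm.assignments[0, 0] == 1

    def test_co_assignment_preserved(self):
        rng = np.random.default_rng(0)
        flows = rng.random(6)
        reps = [rng.integers(1, 4, 6) + 0 for _ in range(5)]
        reps = [rc.partitioning._normalise_labels(r) for r in reps]
        mm = rc.canonicalise_labels(reps, flows, np.arange(6))
        for r, orig in enumerate(reps):
            before = orig[:, None] == orig[None, :]
            after = mm.assignments[:, r][:, None] == mm.assignments[:, r][None, :]
            assert np.array_equal(before, after)


class TestConsistencyPCA:
    def test_stable_blocks_give_pc1_everything(self):
        # identical bipartition in every replicate: rank-1 membership matrix
        mm = MembershipMatrix(np.arange(4), np.tile([[1], [1], [2], [2]], 10))
        pca = rc.consistency_pca(mm)
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0)
        scores = pca.scores["PC1"].to_numpy()
        assert len(set(np.round(scores[:2], 9))) == 1
        assert len(set(np.round(scores[2:], 9))) == 1
        assert not np.isclose(scores[0], scores[2])

    def test_noisy_replicate_reduces_but_preserves_ordering(self):
        base = np.tile([[1], [1], [2], [2]], 10)
        base[:, 3] = [1, 2, 2, 1]  # one scrambled replicate
        pca = rc.consistency_pca(MembershipMatrix(np.arange(4), base))
        assert pca.explained_variance_ratio[0] < 1.0
        s = pca.scores["PC1"].to_numpy()
        assert (s[:2].max() < s[2:].min()) or (s[:2].min() > s[2:].max())

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(1)
        m = rng.integers(1, 4, (6, 12))
        perm = rng.permutation(12)
        a = rc.consistency_pca(MembershipMatrix(np.arange(6), m))
        b = rc.consistency_pca(MembershipMatrix(np.arange(6), m[:, perm]))
        assert np.allclose(
            a.explained_variance_ratio, b.explained_variance_ratio, atol=1e-12
        )

    def test_degenerate_matrix_flagged(self):
        mm = MembershipMatrix(np.arange(3), np.ones((3, 5), dtype=int))
        pca = rc.consistency_pca(mm)
        assert pca.degenerate
        assert not np.isnan(pca.scores.to_numpy()).any()
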