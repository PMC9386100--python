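import networkx as nx
import numpy as np
import pytest

from binrefine.edge_binning import scaffold_to_edge_binning, mark_repetitive
from binrefine.graph_io import BinningTable
from binrefine.refine import (
    CORRECTION,
    PROPAGATION,
    RefineConfig,
    SingularSystemError,
    correction_alpha,
    propagation_operator,
    refine_iterate,
    regularization_parameters,
    solve_fixed_point,
)
from tests.conftest import make_graph

TIGHT = RefineConfig(tolerance=1e-10, max_iterations=20000)


def weighted_graph(n, edges):
    H = nx.Graph()
    H.add_nodes_from(range(n))
    for u, v, w in edges:
        H.add_edge(u, v, weight=w)
    return H


def random_instance(rng, n_nodes=30, n_bins=3, alpha_max=0.9):
    H = nx.gnp_random_graph(n_nodes, 0.15, seed=int(rng.integers(2**31)))
    for u, v in H.edges:
        H[u][v]["weight"] = float(rng.uniform(0.1, 5.0))
    S = propagation_operator(H, list(range(n_nodes)))
    Y = np.zeros((n_nodes, n_bins))
    for i in range(n_nodes):
        if rng.random() < 0.5:
            Y[i, rng.integers(n_bins)] = 1.0
    alpha = rng.uniform(0.0, alpha_max, size=n_nodes)
    return S, Y, alpha


class TestRegularizationSchedule:
    def _alpha(self, mode, lengths, binned_scaffolds):
        g = make_graph(
            {f"e{i}": L for i, L in enumerate(lengths)},
            paths={f"s{i}": [f"e{i}"] for i in range(len(lengths))},
        )
        table = BinningTable({f"s{i}": {"A"} for i in binned_scaffolds})
        Y = scaffold_to_edge_binning(g, table)
        cfg = RefineConfig(mode=mode)
        return regularization_parameters(g, Y, mark_repetitive(g), cfg), Y

    def test_correction_long_edge(self):
        alpha, Y = self._alpha(CORRECTION, [5000], [0])
        assert alpha[0] == pytest.approx(0.6)

    def test_correction_length_one(self):
        alpha, _ = self._alpha(CORRECTION, [1], [0])
        assert alpha[0] == pytest.approx(1.0)

    def test_correction_taper_interior(self):
        cfg = RefineConfig(mode=CORRECTION)
        assert correction_alpha(1000, cfg) == pytest.approx(0.6)
        expected = 1.0 - 0.4 * (500 - 1) / 999
        assert correction_alpha(500, cfg) == pytest.approx(expected)
        assert 0.6 < correction_alpha(500, cfg) < 1.0

    def test_propagation_pins_binned_edges(self):
        alpha, _ = self._alpha(PROPAGATION, [5000], [0])
        assert alpha[0] == 0.0

    def test_unbinned_edges_free(self):
        alpha, _ = self._alpha(PROPAGATION, [5000, 5000], [0])
        assert alpha[1] == 1.0

    def test_repetitive_edges_free_in_both_modes(self):
        g = make_graph(
            {"r": 5000, "u": 5000},
            paths={"s1": ["r", "u"], "s2": ["r"]},
        )
        table = BinningTable({"s1": {"A"}, "s2": {"B"}})
        Y = scaffold_to_edge_binning(g, table)
        for mode in (PROPAGATION, CORRECTION):
            alpha = regularization_parameters(g, Y, mark_repetitive(g), RefineConfig(mode=mode))
            assert alpha[Y.index("r")] == 1.0


class TestPropagationOperator:
    def test_single_link(self):
        H = weighted_graph(2, [(0, 1, 1.0)])
        S = propagation_operator(H, [0, 1]).toarray()
        assert S[0, 1] == pytest.approx(1.0)
        assert np.allclose(S, S.T)

    def test_star_center(self):
        H = weighted_graph(5, [(0, i, 1.0) for i in range(1, 5)])
        S = propagation_operator(H, list(range(5))).toarray()
        # center degree 4, leaves degree 1: S = 1/sqrt(4*1) = 1/2
        assert np.allclose(S[0, 1:], 0.5)

    def test_isolated_node_zero_row(self):
        H = weighted_graph(3, [(0, 1, 1.0)])
        S = propagation_operator(H, [0, 1, 2]).toarray()
        assert np.allclose(S[2], 0.0)
        assert np.allclose(S[:, 2], 0.0)

    def test_self_loop_removed(self):
        H = weighted_graph(2, [(0, 1, 1.0)])
        H.add_edge(0, 0, weight=3.0)
        S = propagation_operator(H, [0, 1]).toarray()
        assert S[0, 0] == 0.0
        assert S[0, 1] == pytest.approx(1.0)


class TestRefineIterate:
    def test_all_alpha_zero_returns_y(self):
        H = weighted_graph(2, [(0, 1, 1.0)])
        S = propagation_operator(H, [0, 1])
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        F, report = refine_iterate(S, Y, np.zeros(2), RefineConfig())
        assert np.array_equal(F, Y)
        assert report.converged

    def test_unlabeled_node_adopts_neighbor_label(self):
        H = weighted_graph(2, [(0, 1, 1.0)])
        S = propagation_operator(H, [0, 1])
        Y = np.array([[1.0, 0.0], [0.0, 0.0]])
        alpha = np.array([0.0, 1.0])
        F, _ = refine_iterate(S, Y, alpha, TIGHT)
        assert np.allclose(F[1], [1.0, 0.0], atol=1e-8)

    def test_midpoint_between_two_labels(self):
        # chain a-b-c, ends pinned to opposite bins: b balances symmetrically.
        # Raw fixed point of the symmetric operator is S_ba = S_bc = 1/sqrt(2)
        # per column; after row normalization b reads (1/2, 1/2).
        H = weighted_graph(3, [(0, 1, 1.0), (1, 2, 1.0)])
        S = propagation_operator(H, [0, 1, 2])
        Y = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        alpha = np.array([0.0, 1.0, 0.0])
        F_exact = solve_fixed_point(S, Y, alpha)
        assert np.allclose(F_exact[1], [1 / np.sqrt(2)] * 2)
        assert np.allclose(F_exact[1] / F_exact[1].sum(), [0.5, 0.5])
        F_iter, _ = refine_iterate(S, Y, alpha, TIGHT)
        assert np.allclose(F_iter, F_exact, atol=1e-8)

    def test_matches_dense_solve_on_random_instances(self, rng):
        for _ in range(10):
            S, Y, alpha = random_instance(rng)
            F_iter, report = refine_iterate(S, Y, alpha, TIGHT)
            F_exact = solve_fixed_point(S, Y, alpha)
            assert report.converged
            assert np.max(np.abs(F_iter - F_exact)) < 1e-6

    def test_nonnegativity_preserved(self, rng):
        # the iteration maps nonnegative inputs to nonnegative outputs; raw
        # magnitudes are only meaningful after row normalization (assign stage)
        S, Y, alpha = random_instance(rng)
        F, _ = refine_iterate(S, Y, alpha, TIGHT)
        assert (F >= -1e-12).all()
        assert np.isfinite(F).all()

    def test_permutation_equivariance(self, rng):
        S, Y, alpha = random_instance(rng, n_nodes=20)
        perm = rng.permutation(20)
        F, _ = refine_iterate(S, Y, alpha, TIGHT)
        S_p = S.toarray()[np.ix_(perm, perm)]
        import scipy.sparse as sp

        F_p, _ = refine_iterate(sp.csr_array(S_p), Y[perm], alpha[perm], TIGHT)
        assert np.allclose(F_p, F[perm], atol=1e-8)

    def test_nonconvergence_flagged(self):
        H = weighted_graph(2, [(0, 1, 1.0)])
        S = propagation_operator(H, [0, 1])
        Y = np.array([[1.0], [0.0]])
        alpha = np.array([0.5, 1.0])
        _, report = refine_iterate(S, Y, alpha, RefineConfig(max_iterations=2, tolerance=1e-15))
        assert not report.converged
        assert report.iterations == 2

    def test_singular_system_reported(self):
        # connected all-free component: fixed point not unique
        H = weighted_graph(2, [(0, 1, 1.0)])
        S = propagation_operator(H, [0, 1])
        Y = np.array([[1.0], [0.0]])
        with pytest.raises(SingularSystemError):
            solve_fixed_point(S, Y, np.ones(2))


def test_cross_check_against_sklearn_label_spreading(rng):
    """Uniform-alpha refinement coincides with Zhou-style label spreading as
    implemented independently in scikit-learn."""
    from sklearn.semi_supervised import LabelSpreading

    n = 40
    H = nx.connected_watts_strogatz_graph(n, 4, 0.3, seed=5)
    for u, v in H.edges:
        H[u][v]["weight"] = 1.0
    S = propagation_operator(H, list(range(n)))
    W = nx.to_numpy_array(H, nodelist=range(n))

    labels = np.full(n, -1)
    labels[rng.choice(n, size=12, replace=False)] = rng.integers(0, 3, size=12)
    assert len(set(labels) - {-1}) == 3
    Y = np.zeros((n, 3))
    for i, lab in enumerate(labels):
        if lab >= 0:
            Y[i, lab] = 1.0

    alpha = np.full(n, 0.6)
    F, _ = refine_iterate(S, Y, alpha, TIGHT)
    norm = F / F.sum(axis=1, keepdims=True)

    model = LabelSpreading(kernel=lambda a, b: W, alpha=0.6, max_iter=5000, tol=1e-10)
    model.fit(np.arange(n).reshape(-1, 1), labels)
    assert np.allclose(norm, model.label_distributions_, atol=1e-5)
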