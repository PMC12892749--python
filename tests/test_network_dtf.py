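"""MVAR estimation, DTF against a brute-force oracle, graph metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eznetsi.network_dtf import (AdjacencyMatrix, MVARModel,
                                 auc_over_thresholds, band_network,
                                 compute_dtf, degree_metrics, fit_mvar,
                                 node_metrics, normalize_and_hub,
                                 random_stable_var, sparsity_threshold)
from eznetsi.spectral import BandScheme, default_bands

RATE = 256.0


def _simulate_var(A, n_t, rng, burn=200):
    p, n, _ = A.shape
    x = np.zeros((n, n_t + burn))
    for t in range(p, n_t + burn):
        x[:, t] = sum(A[k] @ x[:, t - k - 1] for k in range(p)) \
            + rng.standard_normal(n)
    return x[:, burn:]


class TestFitMVAR:
    def test_white_noise_null_model(self, rng):
        x = rng.standard_normal((4, 20000))
        m = fit_mvar(x, p=2, ridge=1e-3, rate=RATE)
        assert np.abs(m.A).max() < 0.05

    def test_var2_parameter_recovery(self, rng):
        A = random_stable_var(4, 2, seed=1, scale=0.8)
        x = _simulate_var(A, 60000, rng)
        m = fit_mvar(x, p=2, ridge=1e-4, rate=RATE)
        rmse = np.sqrt(np.mean((m.A - A) ** 2))
        assert rmse < 0.05

    def test_ridge_path_monotone(self, rng):
        x = rng.standard_normal((3, 2000))
        norms = [np.linalg.norm(fit_mvar(x, p=2, ridge=r, rate=RATE).A)
                 for r in (1e-3, 2e-3, 4e-3, 8e-3, 1.0, 2.0)]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_matches_statsmodels_var(self, rng):
        """Independent cross-check: near-zero ridge against statsmodels'
        OLS VAR estimator on a single realization."""
        from statsmodels.tsa.api import VAR

        A = random_stable_var(3, 1, seed=2, scale=0.7)
        x = _simulate_var(A, 5000, rng)
        ours = fit_mvar(x, p=1, ridge=1e-12, rate=RATE)
        sm = VAR(x.T).fit(maxlags=1, trend="n")
        np.testing.assert_allclose(ours.A[0], sm.coefs[0], atol=5e-3)

    def test_auto_order_finds_truth(self, rng):
        A = random_stable_var(3, 2, seed=3, scale=0.85)
        x = _simulate_var(A, 20000, rng)
        m = fit_mvar(x, p="auto", ridge=1e-6, rate=RATE, max_order=6)
        assert m.p == 2


def _dtf_oracle(A, f, rate):
    """Direct complex-matrix evaluation of the normalized DTF."""
    p, n, _ = A.shape
    Af = np.eye(n, dtype=complex)
    for k in range(p):
        Af -= A[k] * np.exp(-2j * np.pi * f * (k + 1) / rate)
    H = np.linalg.inv(Af)
    P = np.abs(H) ** 2
    return P / P.sum(axis=1, keepdims=True)


class TestDTF:
    def test_diagonal_model_no_crossflow(self):
        A = np.zeros((1, 3, 3))
        np.fill_diagonal(A[0], [0.5, -0.3, 0.2])
        m = MVARModel(A=A, rate=RATE, Sigma=np.eye(3), ridge=0.0)
        dtf = compute_dtf(m, np.linspace(0, 128, 33))
        eye = np.eye(3)[:, :, None] * np.ones((1, 1, 33))
        np.testing.assert_allclose(dtf.gamma2, eye, atol=1e-12)

    def test_unidirectional_two_node(self):
        A = np.zeros((1, 2, 2))
        A[0] = [[0.5, 0.0], [0.4, 0.3]]        # node 0 -> node 1 only
        m = MVARModel(A=A, rate=RATE, Sigma=np.eye(2), ridge=0.0)
        dtf = compute_dtf(m, np.linspace(1, 100, 25))
        assert np.all(dtf.gamma2[0, 1, :] < 1e-15)   # no flow 1 -> 0
        assert np.all(dtf.gamma2[1, 0, :] > 0)       # flow 0 -> 1 present

    def test_against_brute_force_oracle(self):
        A = np.zeros((1, 2, 2))
        A[0] = [[0.55, -0.25], [0.35, 0.45]]
        m = MVARModel(A=A, rate=RATE, Sigma=np.eye(2), ridge=0.0)
        dtf = compute_dtf(m, np.array([10.0]))
        np.testing.assert_allclose(dtf.gamma2[:, :, 0],
                                   _dtf_oracle(A, 10.0, RATE), atol=1e-10)

    def test_inflow_normalization_random_models(self):
        for seed in range(25):
            A = random_stable_var(4, 2, seed=seed)
            m = MVARModel(A=A, rate=RATE, Sigma=np.eye(4), ridge=0.0)
            dtf = compute_dtf(m, np.linspace(0, 128, 17))
            sums = dtf.gamma2.sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-8)


class TestBandNetwork:
    def test_frequency_constant_dtf(self):
        A = np.zeros((1, 3, 3))
        m = MVARModel(A=A, rate=RATE, Sigma=np.eye(3), ridge=0.0)
        dtf = compute_dtf(m, np.linspace(1, 10, 5))
        W = band_network(dtf, BandScheme(bands=[("delta", 1.0, 11.0)]),
                         "delta")
        np.testing.assert_array_equal(W.W, 0.0)  # identity H: no cross flow

    def test_row_sums_bounded_after_diagonal_removal(self, rng):
        A = random_stable_var(5, 2, seed=7)
        m = MVARModel(A=A, rate=RATE, Sigma=np.eye(5), ridge=0.0)
        W = band_network(compute_dtf(m, np.linspace(0, 128, 65)),
                         default_bands(), "alpha")
        assert np.all(W.W.sum(axis=0) <= 1.0 + 1e-9)  # inflow per sink

    def test_unidirectional_single_edge(self):
        A = np.zeros((1, 2, 2))
        A[0, 1, 0] = 0.4
        m = MVARModel(A=A, rate=RATE, Sigma=np.eye(2), ridge=0.0)
        W = band_network(compute_dtf(m, np.linspace(1, 4, 4)),
                         default_bands(), "delta")
        assert W.W[0, 1] > 0
        assert np.count_nonzero(W.W) == 1


class TestSparsityThreshold:
    def test_density_one_is_identity(self, rng):
        W = AdjacencyMatrix(W=_offdiag(rng.random((5, 5))), band="delta")
        out = sparsity_threshold(W, 1.0)
        np.testing.assert_array_equal(out.W, W.W)

    def test_four_node_hand_enumeration(self):
        w = np.arange(1.0, 17.0).reshape(4, 4)
        np.fill_diagonal(w, 0.0)
        adj = AdjacencyMatrix(W=w, band="delta")
        out = sparsity_threshold(adj, 0.25)   # ceil(0.25 * 12) = 3 edges
        kept = sorted(w[out.W > 0].tolist())
        assert kept == [13.0, 14.0, 15.0]     # largest off-diagonal weights
        assert np.count_nonzero(out.W) == 3

    def test_tie_break_keeps_lowest_index(self):
        w = np.ones((3, 3))
        np.fill_diagonal(w, 0.0)
        adj = AdjacencyMatrix(W=w, band="delta")
        out = sparsity_threshold(adj, 0.5)    # ceil(3) = 3 of 6 edges
        assert [(i, j) for i, j in zip(*np.nonzero(out.W))] == \
            [(0, 1), (0, 2), (1, 0)]


def _offdiag(w):
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w


class TestDegreeMetrics:
    def test_schematic_toy_graph(self):
        """Three-edge toy network: node 0 receives two unit edges and sends
        one, so DCin 2, DCout 1, DC 3."""
        W = np.zeros((4, 4))
        W[1, 0] = 1.0
        W[2, 0] = 1.0
        W[0, 3] = 1.0
        mets = degree_metrics(AdjacencyMatrix(W=W, band="delta"))
        assert mets["dc_in"][0] == 2.0
        assert mets["dc_out"][0] == 1.0
        assert mets["dc"][0] == 3.0

    def test_empty_graph(self):
        mets = degree_metrics(AdjacencyMatrix(W=np.zeros((3, 3)), band="x"))
        for v in mets.values():
            np.testing.assert_array_equal(v, 0.0)

    def test_weighted_cycle_hand_computed(self):
        W = np.zeros((3, 3))
        W[0, 1], W[1, 2], W[2, 0] = 0.2, 0.3, 0.5
        mets = degree_metrics(AdjacencyMatrix(W=W, band="x"))
        np.testing.assert_allclose(mets["dc_out"], [0.2, 0.3, 0.5])
        np.testing.assert_allclose(mets["dc_in"], [0.5, 0.2, 0.3])
        np.testing.assert_allclose(mets["dc"], [0.7, 0.5, 0.8])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(min_value=0, max_value=10 ** 9))
    def test_dc_decomposition_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        W = _offdiag(rng.random((n, n)))
        mets = degree_metrics(AdjacencyMatrix(W=W, band="x"))
        np.testing.assert_allclose(mets["dc"],
                                   mets["dc_in"] + mets["dc_out"], atol=1e-12)

    def test_permutation_equivariance(self, rng):
        W = _offdiag(rng.random((6, 6)))
        perm = rng.permutation(6)
        Wp = W[np.ix_(perm, perm)]
        a = node_metrics(AdjacencyMatrix(W=W, band="x"))
        b = node_metrics(AdjacencyMatrix(W=Wp, band="x"))
        for key in ("dc", "dc_in", "dc_out"):
            np.testing.assert_allclose(b.auc[key], a.auc[key][perm],
                                       atol=1e-12)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            AdjacencyMatrix(W=np.array([[0.0, -1.0], [0.0, 0.0]]), band="x")


class TestAUC:
    def test_constant_metric_rectangle(self):
        """A metric constant in density integrates to c * span."""
        W = np.zeros((3, 3))
        W[0, 1] = 1.0                          # one edge survives everywhere
        adj = AdjacencyMatrix(W=W, band="x")
        auc = auc_over_thresholds(adj, np.array([0.1, 0.3, 0.5]))
        assert auc["dc_out"][0] == pytest.approx(0.4 * 1.0)

    def test_two_point_trapezoid(self):
        W = _offdiag(np.arange(9.0).reshape(3, 3))
        adj = AdjacencyMatrix(W=W, band="x")
        grid = np.array([0.2, 0.8])
        auc = auc_over_thresholds(adj, grid)
        m1 = degree_metrics(sparsity_threshold(adj, 0.2))["dc"]
        m2 = degree_metrics(sparsity_threshold(adj, 0.8))["dc"]
        np.testing.assert_allclose(auc["dc"], 0.6 * (m1 + m2) / 2)

    def test_against_naive_trapezoid(self, rng):
        W = _offdiag(rng.random((6, 6)))
        adj = AdjacencyMatrix(W=W, band="x")
        grid = np.linspace(0.1, 0.9, 9)
        auc = auc_over_thresholds(adj, grid)
        naive = np.zeros(6)
        for k in range(len(grid) - 1):
            a = degree_metrics(sparsity_threshold(adj, grid[k]))["dc_out"]
            b = degree_metrics(sparsity_threshold(adj, grid[k + 1]))["dc_out"]
            naive += 0.5 * (a + b) * (grid[k + 1] - grid[k])
        np.testing.assert_allclose(auc["dc_out"], naive, atol=1e-12)

    def test_needs_two_densities(self):
        adj = AdjacencyMatrix(W=np.zeros((2, 2)), band="x")
        with pytest.raises(ValueError):
            auc_over_thresholds(adj, np.array([0.5]))


class TestNormalizeAndHub:
    def test_basic(self):
        norm, hubs = normalize_and_hub(np.array([1.0, 2.0, 4.0]))
        np.testing.assert_allclose(norm, [0.25, 0.5, 1.0])
        assert hubs == {2}

    def test_near_tie_both_flagged(self):
        _, hubs = normalize_and_hub(np.array([4.0, 3.9, 1.0]))
        assert hubs == {0, 1}                  # 3.9/4 = 0.975 >= 0.95

    def test_uniform_scores_all_hubs(self):
        _, hubs = normalize_and_hub(np.full(5, 2.0))
        assert hubs == set(range(5))

    def test_all_zero_empty(self, caplog):
        with caplog.at_level("WARNING"):
            _, hubs = normalize_and_hub(np.zeros(4))
        assert hubs == set()
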