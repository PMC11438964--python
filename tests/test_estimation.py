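import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stimarx import estimation, preprocess, synth
from stimarx.estimation import (
    DEFAULT_L_GRID,
    DEFAULT_M_GRID,
    DEFAULT_P_GRID,
    fit_constrained_stim,
    fit_ridge,
    grid_search_orders,
    ridge_solve,
    select_network_lags,
)
from stimarx.model_family import build_features
from stimarx.types import InvalidArgumentError, ModelSpec


def _dataset_from(X, dy, spec=None):
    from stimarx.types import RegressionDataset

    N = X.shape[0]
    spec = spec or ModelSpec(target=0, L=X.shape[1])
    return RegressionDataset(
        X=X, dy=dy, y_t=np.zeros(N), t_index=np.arange(N),
        window_index=np.zeros(N, int), fold=np.zeros(N, int),
        is_train=np.ones(N, bool), spec=spec)


class TestRidge:
    def test_exact_fit_lam0(self):
        ds = _dataset_from(np.array([[1.0], [2.0]]), np.array([2.0, 4.0]),
                           ModelSpec(target=0, L=1))
        m = fit_ridge(ds, lam=0.0, rows="all")
        assert m.theta[0] == pytest.approx(2.0)

    def test_closed_form_with_penalty(self):
        # (X'X + N lam I) theta = X'dy -> (5 + 0.2) theta = 10
        ds = _dataset_from(np.array([[1.0], [2.0]]), np.array([2.0, 4.0]),
                           ModelSpec(target=0, L=1))
        m = fit_ridge(ds, lam=0.1, rows="all")
        assert m.theta[0] == pytest.approx(10.0 / 5.2)

    def test_noiseless_ar1(self):
        """y(t+1) = 0.9 y(t): with lag-1 features y(t-1), the exact least
        squares coefficient is dy(t)/y(t-1) = -0.1 * 0.9 = -0.09."""
        y = 0.9 ** np.arange(60.0)
        ws = preprocess.full_series_window(60, seed=None)
        ds = build_features(y[None, :], np.zeros(60), np.zeros(60), ws,
                            ModelSpec(target=0, L=1))
        m = fit_ridge(ds, lam=0.0, rows="all")
        assert m.theta[0] == pytest.approx(-0.09, abs=1e-12)

    def test_oracle_agreement(self, rng):
        for _ in range(10):
            N, p = int(rng.integers(30, 500)), int(rng.integers(1, 20))
            X = rng.normal(size=(N, p))
            t = rng.normal(size=N)
            lam = float(rng.uniform(0, 1))
            theta = ridge_solve(X, t, lam)
            oracle = np.linalg.solve(X.T @ X + N * lam * np.eye(p), X.T @ t)
            np.testing.assert_allclose(theta, oracle, rtol=1e-8)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_shrinkage(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 5))
        t = rng.normal(size=50)
        norms = [np.linalg.norm(ridge_solve(X, t, lam))
                 for lam in (0.0, 0.01, 0.1, 1.0)]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_singular_lam0_min_norm(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0]])
        t = np.array([1.0, 2.0])
        with pytest.warns(RuntimeWarning, match="minimum-norm"):
            theta = ridge_solve(X, t, 0.0)
        np.testing.assert_allclose(theta, [0.5, 0.5], atol=1e-10)

    def test_negative_lambda_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ridge_solve(np.ones((2, 1)), np.ones(2), -0.1)

    def test_parameter_recovery_switched(self, switched_bundle):
        b = switched_bundle
        system = b["system"]
        ws = preprocess.full_series_window(b["recording"].n_samples, seed=None)
        for k in range(3):
            spec = ModelSpec(target=k, L=4, M=3, gating="switched")
            ds = build_features(b["recording"].signal, b["u"], b["U"], ws,
                                spec)
            m = fit_ridge(ds, lam=1e-6, rows="all")
            assert np.abs(m.theta - system.theta(k, spec)).max() < 0.05


class TestConstrainedFit:
    @pytest.fixture()
    def on_dataset(self, switched_bundle):
        b = switched_bundle
        spec = ModelSpec(target=0, L=4, M=3)
        return build_features(b["recording"].signal, b["u"], b["U"],
                              b["windows"], spec), b["system"]

    def test_true_a_recovers_b(self, switched_bundle):
        b = switched_bundle
        system = b["system"]
        # linear-truth variant: refit b with the true a frozen, OFF-free data
        ws = preprocess.full_series_window(b["recording"].n_samples, seed=None)
        spec = ModelSpec(target=0, L=4, M=3, gating="switched")
        ds = build_features(b["recording"].signal, b["u"], b["U"], ws, spec)
        a_true = system.a[0]
        m = fit_constrained_stim(ds, a_true, lam=1e-6, rows="all")
        np.testing.assert_allclose(m.block("a"), a_true)
        np.testing.assert_allclose(m.block("b"), system.b[0], atol=0.05)

    def test_zero_a_is_input_only_regression(self, on_dataset):
        ds, _ = on_dataset
        m = fit_constrained_stim(ds, np.zeros(4), lam=0.1, rows="train")
        sl = ds.spec.block_slices()
        direct = ridge_solve(ds.X[ds.is_train][:, sl["b"]],
                             ds.dy[ds.is_train], 0.1)
        np.testing.assert_allclose(m.block("b"), direct, rtol=1e-10)
        np.testing.assert_array_equal(m.block("a"), 0)

    def test_m0_returns_frozen_model(self, switched_bundle):
        b = switched_bundle
        ds = build_features(b["recording"].signal, b["u"], b["U"],
                            b["windows"], ModelSpec(target=0, L=4))
        a_fixed = np.array([0.1, -0.2, 0.05, 0.0])
        m = fit_constrained_stim(ds, a_fixed, lam=0.1)
        np.testing.assert_array_equal(m.theta, a_fixed)

    def test_length_mismatch(self, on_dataset):
        ds, _ = on_dataset
        with pytest.raises(InvalidArgumentError):
            fit_constrained_stim(ds, np.zeros(7))


class TestGridSearch:
    def test_printed_grids_are_defaults(self):
        assert DEFAULT_L_GRID == (0, 1, 50, 100, 150, 200, 250, 300, 350,
                                  400, 450, 500)
        assert DEFAULT_M_GRID == (0, 100, 200, 300)
        assert DEFAULT_P_GRID == (1, 11, 21, 31, 41, 51, 61, 71, 81, 91, 100)

    def test_planted_small_order_recovered(self):
        geom = synth.make_electrode_geometry(1, 100, seed=0)
        system = synth.sample_ground_truth_system(
            geom, family="arx", L=2, M=1, noise_sd=0.05, seed=1)
        sched = synth.make_schedule(frequencies=(25.0, 100.0),
                                    amplitudes=(2.0,), reps=8, gap_ms=1500,
                                    seed=2)
        rec = synth.simulate_recording(system, sched, geometry=geom, seed=3)
        ws = preprocess.extract_windows_and_folds(rec, seed=4)
        u, U = preprocess.prepare_inputs(sched, rec.n_samples, "none")
        res = grid_search_orders(rec.signal, u, U, ws, 0,
                                 L_grid=(0, 1, 2, 4, 8), M_grid=(0, 1, 2, 4),
                                 lam=1e-6)
        # autoregression and a nonzero input lag are both required, and the
        # true order's MSE sits at the (numerical-tie) minimum of the table
        L_best, M_best = res.best_mean
        assert L_best >= 1 and M_best >= 1
        t = res.table
        true_mse = float(t[(t.L == 2) & (t.M == 1)].mse.iloc[0])
        assert true_mse <= t.mse.min() * (1 + 1e-4)
        assert t[t.M == 0].mse.min() > true_mse * 1.5  # input needed
        assert t[t.L == 0].mse.min() > true_mse * 1.5  # history needed

    def test_white_noise_target_median_prefers_simplest(self, rng):
        """With useless features, the Wilcoxon criterion keeps the simplest
        model."""
        y = rng.normal(size=(1, 40000))
        sched = synth.make_schedule(frequencies=(25.0,), amplitudes=(2.0,),
                                    reps=12, gap_ms=1500, seed=0)
        from stimarx.types import Recording

        rec = Recording(signal=y, geometry=synth.make_electrode_geometry(
            1, 100, seed=0), schedule=sched)
        ws = preprocess.extract_windows_and_folds(rec, seed=1)
        u, U = preprocess.prepare_inputs(sched, y.shape[1], "none")
        res = grid_search_orders(y, u, U, ws, 0, L_grid=(0, 1, 2),
                                 M_grid=(0, 1), lam=0.1)
        assert res.best_median == (0, 0)

    def test_empty_grid_rejected(self, switched_bundle):
        b = switched_bundle
        with pytest.raises(InvalidArgumentError):
            grid_search_orders(b["recording"].signal, b["u"], b["U"],
                               b["windows"], 0, L_grid=(), M_grid=(0,))
        with pytest.raises(InvalidArgumentError):
            grid_search_orders(b["recording"].signal, b["u"], b["U"],
                               b["windows"], 0, L_grid=(0,), M_grid=(0,))

    def test_table_covers_grid(self, switched_bundle):
        b = switched_bundle
        res = grid_search_orders(b["recording"].signal, b["u"], b["U"],
                                 b["windows"], 0, L_grid=(1, 2),
                                 M_grid=(0, 1), lam=0.1)
        assert len(res.table) == 4
        assert res.best_mean in {(L, M) for L in (1, 2) for M in (0, 1)}


class TestNetworkLagSelection:
    def test_true_p1_selected(self):
        geom = synth.make_electrode_geometry(3, 100, seed=0)
        system = synth.sample_ground_truth_system(
            geom, family="varx", L=3, M=2, P=1, noise_sd=0.05,
            d_range=(0.3, 0.5), seed=1)
        sched = synth.make_schedule(frequencies=(25.0,), amplitudes=(2.0,),
                                    reps=8, gap_ms=1500, seed=2)
        rec = synth.simulate_recording(system, sched, geometry=geom, seed=3)
        ws = preprocess.extract_windows_and_folds(rec, seed=4)
        u, U = preprocess.prepare_inputs(sched, rec.n_samples, "none")
        spec = ModelSpec(target=0, L=3, M=2, P=1, sources=(1, 2))
        best_P, table = select_network_lags(
            rec.signal, u, U, ws, spec, P_grid=(1, 11, 21), lam=1e-4)
        assert best_P == 1
        assert list(table["P"]) == [1, 11, 21]

    def test_no_sources_returns_zero(self, switched_bundle):
        b = switched_bundle
        spec = ModelSpec(target=0, L=4, M=3)
        best_P, table = select_network_lags(
            b["recording"].signal, b["u"], b["U"], b["windows"], spec)
        assert best_P == 0 and table.empty
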