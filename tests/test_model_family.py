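import numpy as np
import pytest

from stimarx import model_family, preprocess
from stimarx.model_family import build_features, predict_one_step, rollout, select_tau
from stimarx.types import (
    DataError,
    FittedModel,
    InvalidArgumentError,
    ModelSpec,
    Window,
)


def _window(start, stop, freq=25.0, onset=None, test_fold=0, fold_len=None):
    return Window(start=start, stop=stop, event_index=0,
                  onset=onset if onset is not None else start,
                  freq_hz=freq, amp_ma=2.0, test_fold=test_fold,
                  fold_len=fold_len or max((stop - start) // 5, 1))


class TestBuildFeatures:
    def test_hand_construction(self):
        y = np.array([[1.0, 2.0, 3.0, 4.0]])
        spec = ModelSpec(target=0, L=2)
        ds = build_features(y, np.zeros(4), np.zeros(4),
                            [_window(0, 4)], spec)
        assert ds.N == 1
        np.testing.assert_array_equal(ds.X[0], [2.0, 1.0])  # y(t-1), y(t-2)
        assert ds.dy[0] == 1.0  # y(4) - y(3) in 1-based terms
        assert ds.y_t[0] == 3.0

    def test_switched_interaction_zero_off_stim(self, switched_bundle):
        b = switched_bundle
        spec = ModelSpec(target=0, L=3, gating="switched")
        ds = build_features(b["recording"].signal, b["u"], b["U"],
                            b["windows"], spec)
        sl = spec.block_slices()
        off = b["U"][ds.t_index] == 0
        assert off.any()
        assert np.all(ds.X[off][:, sl["c"]] == 0)
        on = ~off
        np.testing.assert_array_equal(ds.X[on][:, sl["c"]],
                                      ds.X[on][:, sl["a"]])

    def test_sparse_lags(self):
        y = np.arange(20.0)[None, :]
        spec = ModelSpec(target=0, L=2, sparse=True, tau=3)
        ds = build_features(y, np.zeros(20), np.zeros(20),
                            [_window(0, 20)], spec)
        t = ds.t_index[0]
        np.testing.assert_array_equal(ds.X[0], [y[0, t - 3], y[0, t - 6]])

    def test_reconstruction_lossless(self, switched_bundle):
        b = switched_bundle
        spec = ModelSpec(target=1, L=4, M=3, gating="switched")
        ds = build_features(b["recording"].signal, b["u"], b["U"],
                            b["windows"], spec)
        y = b["recording"].signal[1]
        np.testing.assert_allclose(ds.y_t + ds.dy, y[ds.t_index + 1],
                                   rtol=0, atol=1e-12)

    def test_history_stays_in_window(self, switched_bundle):
        b = switched_bundle
        spec = ModelSpec(target=0, L=10, M=5)
        ds = build_features(b["recording"].signal, b["u"], b["U"],
                            b["windows"], spec)
        for wi, w in enumerate(b["windows"]):
            rows = ds.window_index == wi
            assert ds.t_index[rows].min() >= w.start + 10
            assert ds.t_index[rows].max() <= w.stop - 2

    def test_empty_spec_rejected(self):
        with pytest.raises(DataError):
            build_features(np.zeros((1, 10)), np.zeros(10), np.zeros(10),
                           [_window(0, 10)], ModelSpec(target=0, L=0))

    def test_fold_membership_by_target(self):
        # targets define folds even though history crosses fold boundaries
        y = np.random.default_rng(0).normal(size=(1, 1500))[..., :]
        w = _window(0, 1500, fold_len=300)
        ds = build_features(y, np.zeros(1500), np.zeros(1500), [w],
                            ModelSpec(target=0, L=400))
        np.testing.assert_array_equal(ds.fold, ds.t_index // 300)


class TestPredict:
    def test_zero_theta(self):
        spec = ModelSpec(target=0, L=2)
        m = FittedModel(spec=spec, theta=np.zeros(2), lam=0.0, n_train=0)
        dy, y1 = predict_one_step(m, np.array([1.0, 2.0]), 5.0)
        assert dy[0] == 0.0 and y1 == 5.0

    def test_scalar_arithmetic(self):
        spec = ModelSpec(target=0, L=1)
        m = FittedModel(spec=spec, theta=np.array([0.5]), lam=0.0, n_train=0)
        dy, _ = predict_one_step(m, np.array([2.0]), 0.0)
        assert dy[0] == 1.0

    def test_switched_sum(self):
        # features [y(t-1), U*y(t-1)] with U=1: dy = (a + c) y(t-1) = 3
        spec = ModelSpec(target=0, L=1, gating="switched")
        m = FittedModel(spec=spec, theta=np.array([0.5, 1.0]), lam=0.0,
                        n_train=0)
        dy = m.predict_dy(np.array([2.0, 2.0]))
        assert dy[0] == 3.0

    def test_dimension_mismatch(self):
        spec = ModelSpec(target=0, L=2)
        m = FittedModel(spec=spec, theta=np.zeros(2), lam=0.0, n_train=0)
        with pytest.raises(InvalidArgumentError):
            m.predict_dy(np.zeros((1, 3)))


class TestRollout:
    def test_matches_simulator(self, switched_bundle):
        """Rolling out the true noiseless model reproduces the simulator."""
        from stimarx import synth

        b = switched_bundle
        system = b["system"]
        noiseless = synth.simulate_recording(
            synth.GroundTruthSystem(
                a=system.a, b=system.b, c=system.c, d=system.d,
                gating=system.gating, noise_sd=0.0, margin=system.margin),
            b["schedule"], geometry=b["geometry"], seed=0)
        spec = ModelSpec(target=0, L=system.L, M=system.M, gating="switched")
        model = FittedModel(spec=spec, theta=system.theta(0, spec), lam=0.0,
                            n_train=0)
        t0 = b["schedule"].events[0].onset - 50
        traj = rollout(model, noiseless.signal, b["u"], b["U"], t0, 300)
        np.testing.assert_allclose(
            traj, noiseless.signal[0, t0 + 1 : t0 + 301], atol=1e-9)

    def test_zero_system(self):
        spec = ModelSpec(target=0, L=2)
        m = FittedModel(spec=spec, theta=np.zeros(2), lam=0.0, n_train=0)
        y = np.zeros((1, 100))
        traj = rollout(m, y, np.zeros(100), np.zeros(100), 10, 20)
        np.testing.assert_array_equal(traj, 0)

    def test_k1_equals_one_step(self, switched_bundle):
        b = switched_bundle
        spec = ModelSpec(target=0, L=4, M=3, gating="switched")
        ds = build_features(b["recording"].signal, b["u"], b["U"],
                            b["windows"], spec)
        m = FittedModel(spec=spec, theta=np.linspace(0.1, -0.1, spec.n_params),
                        lam=0.0, n_train=0)
        i = 100
        t = int(ds.t_index[i])
        one = predict_one_step(m, ds.X[i], ds.y_t[i])[1]
        roll = rollout(m, b["recording"].signal, b["u"], b["U"], t, 1)
        assert roll[0] == pytest.approx(float(one[0]), abs=1e-12)

    def test_insufficient_history(self):
        spec = ModelSpec(target=0, L=5)
        m = FittedModel(spec=spec, theta=np.zeros(5), lam=0.0, n_train=0)
        with pytest.raises(DataError):
            rollout(m, np.zeros((1, 100)), np.zeros(100), np.zeros(100), 3, 5)


class TestEquivalences:
    def test_block_nulling(self, switched_bundle):
        """Switched/bilinear models with c = 0 predict like the linear model."""
        b = switched_bundle
        y = b["recording"].signal
        lin_spec = ModelSpec(target=0, L=4, M=3)
        lin_ds = build_features(y, b["u"], b["U"], b["windows"], lin_spec)
        theta_lin = np.linspace(-0.2, 0.2, lin_spec.n_params)
        lin_pred = FittedModel(spec=lin_spec, theta=theta_lin, lam=0, n_train=0
                               ).predict_dy(lin_ds.X)
        for mode in ("switched", "bilinear"):
            U = preprocess.gating_signal(b["u"], b["schedule"], mode)
            spec = ModelSpec(target=0, L=4, M=3, gating=mode)
            ds = build_features(y, b["u"], U, b["windows"], spec)
            theta = np.zeros(spec.n_params)
            sl = spec.block_slices()
            theta[sl["a"]] = theta_lin[:4]
            theta[sl["b"]] = theta_lin[4:]
            pred = FittedModel(spec=spec, theta=theta, lam=0, n_train=0
                               ).predict_dy(ds.X)
            np.testing.assert_allclose(pred, lin_pred, atol=0)

    def test_sparse_tau1_equals_dense(self, switched_bundle):
        b = switched_bundle
        y = b["recording"].signal
        dense = build_features(y, b["u"], b["U"], b["windows"],
                               ModelSpec(target=0, L=4, M=2))
        sparse = build_features(y, b["u"], b["U"], b["windows"],
                                ModelSpec(target=0, L=4, M=2, sparse=True,
                                          tau=1))
        np.testing.assert_array_equal(dense.X, sparse.X)
        np.testing.assert_array_equal(dense.dy, sparse.dy)

    def test_sparse_requires_plain_arx(self):
        with pytest.raises(InvalidArgumentError):
            ModelSpec(target=0, L=4, gating="switched", sparse=True, tau=2)


def _ami_oracle(x, max_lag, bins=16):
    """Independent AMI implementation via sklearn's mutual_info_score."""
    from sklearn.metrics import mutual_info_score

    out = []
    for lag in range(1, max_lag + 1):
        a, b = x[lag:], x[:-lag]
        edges_a = np.histogram_bin_edges(a, bins=bins)
        edges_b = np.histogram_bin_edges(b, bins=bins)
        da = np.clip(np.digitize(a, edges_a), 1, bins)
        db = np.clip(np.digitize(b, edges_b), 1, bins)
        out.append(mutual_info_score(da, db))
    return np.array(out)


class TestSelectTau:
    def test_matches_independent_ami_oracle(self, rng):
        x = rng.normal(size=20000)
        ami = model_family.auto_mutual_information(x, 10)
        oracle = _ami_oracle(x, 10)
        np.testing.assert_allclose(ami, oracle, atol=1e-10)

    def test_white_noise_small_tau(self, rng):
        x = rng.normal(size=50000)
        assert select_tau(x, cap=20) <= 3

    def test_sinusoid_quarter_period(self, rng):
        t = np.arange(50000)
        # 20 ms period in noise: AMI dips where the lagged correlation
        # crosses zero, i.e. at the quarter period
        x = np.sin(2 * np.pi * t / 20.0) + 0.2 * rng.normal(size=t.size)
        assert select_tau(x, cap=20) == pytest.approx(5, abs=1)

    def test_slow_drift_clips_to_cap(self, rng):
        # random-walk drift: AMI decays monotonically, no local minimum
        x = np.cumsum(rng.normal(size=50000))
        assert select_tau(x, cap=20) == 20

    def test_constant_series_error(self):
        with pytest.raises(DataError):
            select_tau(np.ones(1000))
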