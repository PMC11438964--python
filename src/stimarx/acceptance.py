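"""Self-contained property-based verification experiments.

Each ``criterion_*`` function builds its own synthetic ground truth from a
seed, runs the relevant pipeline stage end-to-end, and returns a dict of
measured quantities (including a headline ``value`` and problem size ``n``).
They are consumed by both the acceptance test suite and the standalone
acceptance report script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge

from . import causal, estimation, evaluation, generalize, model_family
from . import network, preprocess, synth
from .types import ModelSpec


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0]) for s in
            np.random.SeedSequence(seed).spawn(n)]


# 1 -------------------------------------------------------------------------


def criterion_01_ridge_oracle(seed: int, n_instances: int = 50) -> dict:
    """fit_ridge vs two independent ridge routes on random instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        N = int(rng.integers(20, 2001))
        p = int(rng.integers(1, 51))
        lam = float(rng.choice([0.0, 1e-3, 0.1, 1.0]))
        X = rng.normal(size=(N, p))
        t = rng.normal(size=N)
        theta = estimation.ridge_solve(X, t, lam)
        direct = np.linalg.solve(X.T @ X + N * lam * np.eye(p), X.T @ t)
        rel = np.linalg.norm(theta - direct) / max(np.linalg.norm(direct), 1e-300)
        worst = max(worst, rel)
        if lam > 0:  # third, fully independent route
            sk = Ridge(alpha=N * lam, fit_intercept=False, solver="svd")
            sk.fit(X, t)
            rel2 = (np.linalg.norm(theta - sk.coef_)
                    / max(np.linalg.norm(sk.coef_), 1e-300))
            worst = max(worst, rel2)
    return {"value": worst, "n": n_instances, "passed": worst < 1e-8}


# 2 -------------------------------------------------------------------------


def criterion_02_parameter_recovery(seed: int, n_reps: int = 10) -> dict:
    """Switched-ARX truth, 60 s of data, lam=1e-6: max |theta_hat - theta|."""
    errs = []
    for s in _spawn(seed, n_reps):
        geom = synth.make_electrode_geometry(4, 120, seed=s)
        system = synth.sample_ground_truth_system(
            geom, family="sl-arx", L=10, M=5, noise_sd=0.1, seed=s + 1)
        sched = synth.make_schedule(
            frequencies=(10.0, 25.0, 50.0, 100.0, 200.0, -1.0),
            amplitudes=(2.0,), reps=5, gap_ms=1500, seed=s + 2)
        rec = synth.simulate_recording(system, sched, geometry=geom, seed=s + 3)
        ws = preprocess.full_series_window(rec.n_samples, seed=s + 4)
        u, U = preprocess.prepare_inputs(sched, rec.n_samples, "switched")
        worst = 0.0
        for k in range(4):
            spec = ModelSpec(target=k, L=10, M=5, gating="switched")
            ds = model_family.build_features(rec.signal, u, U, ws, spec)
            model = estimation.fit_ridge(ds, lam=1e-6, rows="all")
            worst = max(worst, float(
                np.abs(model.theta - system.theta(k, spec)).max()))
        errs.append(worst)
    n_success = int(sum(e < 0.05 for e in errs))
    return {"value": n_success, "n": n_reps, "max_errors": errs,
            "passed": n_success >= 9}


# 3 -------------------------------------------------------------------------


def _family_mses(rec, sched, ws, k, L, M, lam):
    u = preprocess.encode_input(sched, rec.n_samples)
    out = {}
    for label, mode in (("arx", "none"), ("sl-arx", "switched")):
        U = preprocess.gating_signal(u, sched, mode)
        spec = ModelSpec(target=k, L=L, M=M, gating=mode)
        ds = model_family.build_features(rec.signal, u, U, ws, spec)
        model = estimation.fit_ridge(ds, lam=lam, rows="train")
        out[label] = evaluation.evaluate(model, ds, rows="test")["nmse"]
    return out


def criterion_03_family_selection(seed: int, n_channels: int = 20) -> dict:
    """Switched truth: SL-ARX beats ARX on >= 80% of channels; linear truth:
    per-channel NMSE differences stay within a 2% tie margin."""
    s1, s2 = _spawn(seed, 2)
    out = {}
    for label, family, s in (("switched", "sl-arx", s1), ("linear", "arx", s2)):
        geom = synth.make_electrode_geometry(n_channels, 150, seed=s)
        system = synth.sample_ground_truth_system(
            geom, family=family, L=5, M=3, noise_sd=0.1,
            min_regime_gap=0.5, seed=s + 1)
        sched = synth.make_schedule(
            frequencies=(25.0, 100.0), amplitudes=(2.0,), reps=6,
            gap_ms=1500, seed=s + 2)
        rec = preprocess.preprocess_signal(
            synth.simulate_recording(system, sched, geometry=geom, seed=s + 3))
        ws = preprocess.extract_windows_and_folds(rec, seed=s + 4)
        sl_wins, rel_diffs = 0, []
        for k in range(n_channels):
            m = _family_mses(rec, sched, ws, k, L=5, M=3, lam=0.1)
            if m["sl-arx"] < m["arx"]:
                sl_wins += 1
            rel_diffs.append(abs(m["sl-arx"] - m["arx"]) / m["arx"])
        out[label] = {"sl_win_fraction": sl_wins / n_channels,
                      "mean_rel_diff": float(np.mean(rel_diffs))}
    passed = (out["switched"]["sl_win_fraction"] >= 0.8
              and out["linear"]["mean_rel_diff"] < 0.02)
    return {"value": out["switched"]["sl_win_fraction"], "n": n_channels,
            "detail": out, "passed": passed}


# 4 -------------------------------------------------------------------------


def criterion_04_bootstrap_calibration(
    seed: int, n_channels: int = 50, n_boot: int = 100
) -> dict:
    """Type-I rate with b = 0 truth; power with a strong planted b."""
    s1, s2 = _spawn(seed, 2)
    rates = {}
    for label, family, s in (("null", "ar", s1), ("strong", "arx", s2)):
        geom = synth.make_electrode_geometry(n_channels, 150, seed=s)
        system = synth.sample_ground_truth_system(
            geom, family=family, L=5, M=3, noise_sd=0.1, seed=s + 1)
        sched = synth.make_schedule(
            frequencies=(25.0, 100.0), amplitudes=(2.0,), reps=6,
            gap_ms=1500, seed=s + 2)
        rec = preprocess.preprocess_signal(
            synth.simulate_recording(system, sched, geometry=geom, seed=s + 3))
        ws = preprocess.extract_windows_and_folds(rec, seed=s + 4)
        u, U = preprocess.prepare_inputs(sched, rec.n_samples, "none")
        rejects = 0
        for k in range(n_channels):
            spec = ModelSpec(target=k, L=5, M=3, gating="none")
            res = causal.bootstrap_input_test(
                rec.signal, u, U, ws, spec, lam=0.1, n_boot=n_boot,
                alpha=0.05, seed=s + 10 + k)
            rejects += int(res.reject)
        rates[label] = rejects / n_channels
    passed = (0.0 <= rates["null"] <= 0.12) and rates["strong"] >= 0.95
    return {"value": rates["null"], "n": n_channels, "detail": rates,
            "passed": passed}


# 5 -------------------------------------------------------------------------


def criterion_05_order_selection(
    seed: int, n_reps: int = 10, n_channels: int = 3
) -> dict:
    """Recovery of planted orders (L=50, M=100) from the printed grids.

    Fits the raw (unscaled) simulation with a small penalty: the generating
    process is exactly representable by the intercept-free model only in its
    original coordinates (z-scoring a signal whose input drive has nonzero
    mean introduces a constant the model family cannot express).
    """
    recoveries = 0
    err_rows = []
    for rep, s in enumerate(_spawn(seed, n_reps)):
        geom = synth.make_electrode_geometry(n_channels, 120, seed=s)
        system = synth.sample_ground_truth_system(
            geom, family="arx", L=50, M=100, noise_sd=0.1,
            b_range=(0.05, 0.25), seed=s + 1)
        sched = synth.make_schedule(
            frequencies=(10.0, 100.0), amplitudes=(2.0,), reps=6,
            gap_ms=1500, seed=s + 2)
        rec = synth.simulate_recording(system, sched, geometry=geom, seed=s + 3)
        ws = preprocess.extract_windows_and_folds(rec, seed=s + 4)
        u, U = preprocess.prepare_inputs(sched, rec.n_samples, "none")
        picks = []
        for k in range(n_channels):
            res = estimation.grid_search_orders(
                rec.signal, u, U, ws, k, lam=1e-4)
            picks.append(res.best_mean)
            for (L, M), werr in res.window_errors.items():
                if M != 100:
                    continue
                for wi, e in enumerate(werr):
                    err_rows.append({"channel": rep * n_channels + k, "L": L,
                                     "window": wi, "mse": e})
        modal = max(set(picks), key=picks.count)
        if modal == (50, 100) and picks.count(modal) >= 2:
            recoveries += 1
    err_df = pd.DataFrame(err_rows)
    swr = evaluation.statistical_win_rate(err_df)
    return {
        "value": recoveries, "n": n_reps,
        "stat_win_rate": {int(k): float(v) for k, v in swr.items()},
        "passed": recoveries >= 8
        and min(v for k, v in swr.items() if 50 <= k <= 300) >= 0.8
        and max(swr[0], swr[1]) <= 0.5,
    }


# 6 -------------------------------------------------------------------------


def criterion_06_input_encoding(seed: int = 0) -> dict:
    """Nonzero-u counts match brute-force enumeration of the pulse rule."""
    from .types import ALLOWED_FREQS, StimEvent

    expected, got = {}, {}
    for f in ALLOWED_FREQS:
        # independent oracle: enumerate dt in [0, 500] with dt*f/1000 integer
        expected[f] = sum(
            1 for dt in range(501) if (dt * f) % 1000 == 0)
        ev = StimEvent(onset=0, freq_hz=f, amp_ma=1.0)
        u = preprocess.encode_input([ev], 600)
        got[f] = int(np.count_nonzero(u))
    passed = expected == got and got == {10.0: 6, 25.0: 13, 50.0: 26,
                                         100.0: 51, 200.0: 101}
    return {"value": sum(got.values()), "n": len(got),
            "counts": {int(k): v for k, v in got.items()}, "passed": passed}


# 7 -------------------------------------------------------------------------


def criterion_07_planted_band(
    seed: int, n_reps: int = 10, band=(40.0, 80.0), n_channels: int = 24
) -> dict:
    """Smoothed MSE-advantage peak falls inside the planted coupling band."""
    hits, peaks = 0, []
    for s in _spawn(seed, n_reps):
        geom = synth.make_electrode_geometry(n_channels, 170, seed=s)
        system = synth.sample_ground_truth_system(
            geom, family="sl-varx", L=5, M=3, P=1, noise_sd=0.1,
            coupling_band=band, coupling_sources="anode",
            d_range=(0.25, 0.45), seed=s + 1)
        sched = synth.make_schedule(
            frequencies=(25.0, 100.0), amplitudes=(2.0,), reps=6,
            gap_ms=1500, seed=s + 2)
        rec = preprocess.preprocess_signal(
            synth.simulate_recording(system, sched, geometry=geom, seed=s + 3))
        ws = preprocess.extract_windows_and_folds(rec, seed=s + 4)
        u, U = preprocess.prepare_inputs(sched, rec.n_samples, "switched")
        prof = network.mse_advantage_profile(
            rec.signal, u, U, ws, rec.geometry, L=5, M=3, P=1,
            gating="switched", lam=0.1)
        peaks.append(prof.peak_mm)
        if band[0] <= prof.peak_mm <= band[1]:
            hits += 1
    return {"value": hits, "n": n_reps, "peaks_mm": peaks,
            "passed": hits >= 8}


# 8 -------------------------------------------------------------------------


def criterion_08_elimination(seed: int, n_reps: int = 10) -> dict:
    """Remove-all structural identity + zero-coupling bins are unimpacted."""
    from .estimation import fit_ridge
    from .model_family import build_features

    identity_ok = True
    unimpacted_hits, total = 0, 0
    band = (60.0, 100.0)
    for s in _spawn(seed, n_reps):
        geom = synth.make_electrode_geometry(12, 170, seed=s)
        system = synth.sample_ground_truth_system(
            geom, family="sl-varx", L=5, M=3, P=1, noise_sd=0.1,
            coupling_band=band, d_range=(0.15, 0.35), seed=s + 1)
        sched = synth.make_schedule(
            frequencies=(25.0, 100.0), amplitudes=(2.0,), reps=4,
            gap_ms=1500, seed=s + 2)
        rec = preprocess.preprocess_signal(
            synth.simulate_recording(system, sched, geometry=geom, seed=s + 3))
        ws = preprocess.extract_windows_and_folds(rec, seed=s + 4)
        u, U = preprocess.prepare_inputs(sched, rec.n_samples, "switched")
        k = 1  # arbitrary non-anode channel
        table = network.backward_elimination(
            rec.signal, u, U, ws, rec.geometry, k, L=5, M=3, P=1,
            gating="switched", lam=0.1, bin_width_mm=20.0)
        dist_k = rec.geometry.pairwise_dist[k]
        for row in table.itertuples():
            in_bin = [i for i in range(12) if i != k
                      and row.bin_lo_mm <= dist_k[i] < row.bin_hi_mm]
            if np.all(system.d[k, in_bin] == 0):
                total += 1
                unimpacted_hits += int(row.unimpacted)
        # structural identity: drop every network block == scalar model
        full = ModelSpec(target=k, L=5, M=3, P=1, gating="switched",
                         sources=tuple(i for i in range(12) if i != k))
        scalar = ModelSpec(target=k, L=5, M=3, gating="switched")
        ds_s = build_features(rec.signal, u, U, ws, scalar)
        ds_r = build_features(rec.signal, u, U, ws, full.with_sources(()))
        m_s = fit_ridge(ds_s, lam=0.1, rows="train")
        m_r = fit_ridge(ds_r, lam=0.1, rows="train")
        if not np.array_equal(m_s.theta, m_r.theta):
            identity_ok = False
    frac = unimpacted_hits / max(total, 1)
    return {"value": frac, "n": total, "identity_ok": identity_ok,
            "passed": identity_ok and frac >= 0.9}


# 9 -------------------------------------------------------------------------


def criterion_09_noiseless(seed: int, n_steps: int = 200) -> dict:
    """One-step NMSE of the true model on its own noiseless simulation, and
    k-step rollout agreement with the simulator."""
    geom = synth.make_electrode_geometry(2, 100, seed=seed)
    system = synth.sample_ground_truth_system(
        geom, family="sl-arx", L=6, M=4, noise_sd=0.0, seed=seed + 1)
    sched = synth.make_schedule(
        frequencies=(25.0, 100.0), amplitudes=(2.0,), reps=3,
        gap_ms=1500, seed=seed + 2)
    rec = synth.simulate_recording(system, sched, geometry=geom, seed=seed + 3)
    ws = preprocess.full_series_window(rec.n_samples, seed=seed + 4)
    u, U = preprocess.prepare_inputs(sched, rec.n_samples, "switched")
    spec = ModelSpec(target=0, L=6, M=4, gating="switched")
    ds = model_family.build_features(rec.signal, u, U, ws, spec)
    from .types import FittedModel

    true_model = FittedModel(spec=spec, theta=system.theta(0, spec), lam=0.0,
                             n_train=0)
    pred = true_model.predict_dy(ds.X)
    one_step_nmse = evaluation.nmse(pred, ds.dy)
    t0 = sched.events[0].onset - 100
    roll = model_family.rollout(true_model, rec.signal, u, U, t0, n_steps)
    roll_err = float(np.abs(roll - rec.signal[0, t0 + 1 : t0 + 1 + n_steps]).max())
    return {"value": one_step_nmse, "n": ds.N, "rollout_err": roll_err,
            "passed": one_step_nmse < 1e-12 and roll_err < 1e-9}


# 10 ------------------------------------------------------------------------


def criterion_10_frequency_generalization(
    seed: int, n_channels: int = 3, reps: int = 4
) -> dict:
    """NMSE vs number of training frequencies: non-increasing for bilinear
    truth (Spearman rho <= 0), flat for switched truth over k >= 2.

    Fit on the raw simulation with a small penalty so that subset-dependent
    shrinkage bias and filter-induced mismatch cannot masquerade as
    generalization effects (the k = 1 mean includes the STIM OFF-only
    subset, which cannot identify the stimulation blocks; hence flatness is
    judged on k >= 2)."""
    s1, s2 = _spawn(seed, 2)
    curves = {}
    for label, gating, s in (("bilinear", "bilinear", s1),
                             ("switched", "switched", s2)):
        geom = synth.make_electrode_geometry(n_channels, 120, seed=s)
        system = synth.sample_ground_truth_system(
            geom, family="sl-arx", L=5, M=3, gating=gating, noise_sd=0.1,
            seed=s + 1)
        sched = synth.make_schedule(
            frequencies=(10.0, 25.0, 50.0, 100.0, 200.0),
            amplitudes=(2.0,), reps=reps, gap_ms=3500, seed=s + 2)
        rec = synth.simulate_recording(system, sched, geometry=geom, seed=s + 3)
        ws = preprocess.extract_windows_and_folds(rec, seed=s + 4)
        off = generalize.stim_off_windows(sched, rec.n_samples, seed=s + 5)
        all_windows = list(ws) + off
        u, U = preprocess.prepare_inputs(sched, rec.n_samples, "switched")
        sums = []
        for k in range(n_channels):
            _, summary = generalize.frequency_subset_experiment(
                rec.signal, u, U, all_windows, k, L=5, M=3,
                gating="switched", lam=1e-4)
            sums.append(summary)
        curves[label] = pd.concat(sums, axis=1).mean(axis=1)
    bil = curves["bilinear"]
    rho = float(stats.spearmanr(bil.index.to_numpy(), bil.to_numpy())
                .statistic)
    sw = curves["switched"].loc[2:]
    spread = float((sw.max() - sw.min()) / sw.min())
    return {
        "value": rho, "n": int(bil.size),
        "bilinear_curve": {int(k): float(v) for k, v in bil.items()},
        "switched_curve": {int(k): float(v)
                           for k, v in curves["switched"].items()},
        "switched_spread": spread,
        "passed": rho <= 0 and spread < 0.05,
    }


ALL_CRITERIA = {
    "criterion_01_ridge_oracle": criterion_01_ridge_oracle,
    "criterion_02_parameter_recovery": criterion_02_parameter_recovery,
    "criterion_03_family_selection": criterion_03_family_selection,
    "criterion_04_bootstrap_calibration": criterion_04_bootstrap_calibration,
    "criterion_05_order_selection": criterion_05_order_selection,
    "criterion_06_input_encoding": criterion_06_input_encoding,
    "criterion_07_planted_band": criterion_07_planted_band,
    "criterion_08_elimination": criterion_08_elimination,
    "criterion_09_noiseless": criterion_09_noiseless,
    "criterion_10_frequency_generalization": criterion_10_frequency_generalization,
}
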