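"""Frequency-subset and cross-session generalization experiments.

The frequency experiment conditions every regression sample on the
stimulation frequency active in its window: samples inside the stimulation
segment carry the window's pulse frequency, samples in the pre/post
segments carry 0 Hz (STIM OFF).  Models are trained on every nonempty
subset of conditions and tested on one fixed held-out set containing all
conditions.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import DEFAULT_LAMBDA, fit_ridge
from .evaluation import evaluate, nmse
from .model_family import build_features
from .types import (
    DataError,
    ModelSpec,
    RegressionDataset,
    Window,
    WindowSet,
)

FREQ_CONDITIONS = (0.0, 10.0, 25.0, 50.0, 100.0, 200.0)


def sample_conditions(
    ds: RegressionDataset, windows: WindowSet | list[Window]
) -> np.ndarray:
    """Per-row stimulation condition: the window frequency inside the stim
    segment, 0.0 (STIM OFF) in the pre/post segments."""
    win_list = list(windows)
    cond = np.zeros(ds.N)
    for wi, w in enumerate(win_list):
        if w.is_single_pulse:
            continue
        lo, hi = w.stim_span
        sel = (ds.window_index == wi) & (ds.t_index >= lo) & (ds.t_index < hi)
        cond[sel] = w.freq_hz
    return cond


def stim_off_windows(
    schedule, T: int, seed: int | None = 0, margin_ms: int = 250
) -> list[Window]:
    """1500 ms pseudo-windows (condition 0 Hz) cut from stimulation-free gaps.

    A gap qualifies when it leaves ``margin_ms`` clearance after the previous
    event's post-stim window and before the next event's pre-stim window.
    Each pseudo-window gets its own random test fold, like stimulation
    windows.
    """
    from .types import N_FOLDS, PRE_MS, SINGLE_PRE_MS, STIM_DURATION_MS, WINDOW_MS

    rng = np.random.default_rng(seed)
    occupied: list[tuple[int, int]] = []
    for ev in schedule.events:
        pre = SINGLE_PRE_MS if ev.is_single_pulse else PRE_MS
        occupied.append((ev.onset - pre, ev.onset - pre + WINDOW_MS))
    occupied.sort()
    bounds = [(0, occupied[0][0] if occupied else T)]
    for (a0, a1), (b0, b1) in zip(occupied, occupied[1:]):
        bounds.append((a1, b0))
    if occupied:
        bounds.append((occupied[-1][1], T))
    out: list[Window] = []
    for lo, hi in bounds:
        lo, hi = lo + margin_ms, hi - margin_ms
        n_fit = (hi - lo) // WINDOW_MS
        for j in range(max(n_fit, 0)):
            start = lo + j * WINDOW_MS
            out.append(Window(
                start=start, stop=start + WINDOW_MS, event_index=-1,
                onset=start, freq_hz=0.0, amp_ma=0.0,
                test_fold=int(rng.integers(N_FOLDS)),
            ))
    return out


def window_condition(w: Window) -> float:
    """A window's stimulation condition: its pulse frequency, 0 for STIM OFF
    pseudo-windows (single-pulse windows map to -1 and are excluded)."""
    return float(w.freq_hz)


def frequency_subset_experiment(
    y: np.ndarray,
    u: np.ndarray,
    U: np.ndarray,
    windows: WindowSet | list[Window],
    k: int,
    L: int,
    M: int,
    gating: str = "switched",
    lam: float = DEFAULT_LAMBDA,
    frequencies: tuple[float, ...] = FREQ_CONDITIONS,
) -> tuple[pd.DataFrame, pd.Series]:
    """Train on every nonempty frequency subset, test on all conditions.

    Windows are conditioned on their stimulation frequency (0 Hz = STIM OFF
    pseudo-windows, see :func:`stim_off_windows`).  For each subset, training
    uses the train folds of that subset's windows; the held-out set (test
    folds of every conditioned window) is identical across subsets.  Returns
    ``(table, summary)``: one row per subset, and the mean NMSE per subset
    size ``n_freqs``.
    """
    win_list = [w for w in windows if window_condition(w) in frequencies]
    present = {window_condition(w) for w in win_list}
    missing = [f for f in frequencies if f not in present]
    if missing:
        raise DataError(f"missing stimulation conditions: {missing}")
    spec = ModelSpec(target=k, L=L, M=M, gating=gating)
    ds = build_features(y, u, U, win_list, spec)
    cond = np.array([window_condition(w) for w in win_list])
    row_cond = cond[ds.window_index]
    test_rows = ds.rows("test")
    dy_te = ds.dy[test_rows]
    if dy_te.size < 2:
        raise DataError("empty held-out set")
    rows = []
    for nk in range(1, len(frequencies) + 1):
        for subset in combinations(frequencies, nk):
            train_rows = ds.rows("train") & np.isin(row_cond, subset)
            if not train_rows.any():
                raise DataError(f"no training samples for subset {subset}")
            model = fit_ridge(ds, lam=lam, rows=train_rows)
            val = nmse(model.predict_dy(ds.X[test_rows]), dy_te)
            rows.append({"n_freqs": nk, "subset": subset, "nmse": val})
    table = pd.DataFrame(rows)
    summary = table.groupby("n_freqs")["nmse"].mean()
    return table, summary


def session_experiment(
    yA: np.ndarray,
    windowsA: WindowSet | list[Window],
    yB: np.ndarray,
    windowsB: WindowSet | list[Window],
    k: int,
    L: int,
    lam: float = DEFAULT_LAMBDA,
    alpha: float = 0.05,
) -> dict:
    """Compare STIM OFF models trained on session A, session B and A+B.

    All three are autoregressive-only models (stimulation sites differ across
    sessions, so only the un-stimulated dynamics are comparable).  Training
    uses STIM OFF samples in the train folds; testing uses session A's STIM
    OFF test folds.  Also reports a one-sided signed-rank comparison of the
    A-only vs the combined model across test windows.
    """
    spec = ModelSpec(target=k, L=L, M=0, gating="none")
    T_A = np.atleast_2d(yA).shape[1]
    zA = np.zeros(T_A)
    T_B = np.atleast_2d(yB).shape[1]
    zB = np.zeros(T_B)
    dsA = build_features(yA, zA, zA, windowsA, spec)
    dsB = build_features(yB, zB, zB, windowsB, spec)
    condA = sample_conditions(dsA, windowsA) == 0.0
    condB = sample_conditions(dsB, windowsB) == 0.0
    trainA = dsA.rows("train") & condA
    testA = dsA.rows("test") & condA
    trainB = dsB.rows("train") & condB
    if not testA.any():
        raise DataError("session A has no held-out STIM OFF data")
    if not trainB.any():
        raise DataError("session B has no STIM OFF training data")

    model_A = fit_ridge(dsA, lam=lam, rows=trainA)
    model_B = fit_ridge(dsB, lam=lam, rows=trainB)
    X_AB = np.vstack([dsA.X[trainA], dsB.X[trainB]])
    dy_AB = np.concatenate([dsA.dy[trainA], dsB.dy[trainB]])
    from .estimation import ridge_solve
    from .types import FittedModel

    theta_AB = ridge_solve(X_AB, dy_AB, lam)
    model_AB = FittedModel(spec=spec, theta=theta_AB, lam=lam,
                           n_train=X_AB.shape[0])

    res = {name: evaluate(m, dsA, rows=testA)
           for name, m in (("A", model_A), ("B", model_B), ("AB", model_AB))}
    diff = res["A"]["window_errors"] - res["AB"]["window_errors"]
    if np.allclose(diff, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diff, alternative="less").pvalue)
    return {
        "mse_A": res["A"]["mse"],
        "mse_B": res["B"]["mse"],
        "mse_AB": res["AB"]["mse"],
        "p_A_better_than_AB": p,
        "A_better": p < alpha,
    }
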