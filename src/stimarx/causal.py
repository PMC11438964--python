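"""Shuffle-based causal-effect tests and the indirect linearity test.

The bootstrap tests refit the channel model after permuting either the input
series or the other channels' past (jointly, with one time permutation per
replicate), and compare the observed test MSE against the null distribution
of shuffled-model test MSEs.  The p-value uses the add-one rule
``p = (1 + #{null <= observed}) / (1 + n_boot)`` so it is never exactly zero.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .estimation import DEFAULT_LAMBDA, fit_constrained_stim, fit_ridge
from .evaluation import evaluate
from .model_family import build_features
from .types import (
    CausalTestResult,
    DataError,
    InvalidArgumentError,
    ModelSpec,
    Window,
    WindowSet,
)


def _fit_and_test_mse(y, u, U, windows, spec, lam) -> float:
    ds = build_features(y, u, U, windows, spec)
    model = fit_ridge(ds, lam=lam, rows="train")
    return evaluate(model, ds, rows="test")["mse"]


def bootstrap_input_test(
    y: np.ndarray,
    u: np.ndarray,
    U: np.ndarray,
    windows: WindowSet | list[Window],
    spec: ModelSpec,
    lam: float = DEFAULT_LAMBDA,
    n_boot: int = 100,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> CausalTestResult:
    """Test for a direct causal effect of the stimulation input.

    Each replicate permutes the raw ``u`` series across time, rebuilds the
    lagged input features and refits; the observed model uses the intact
    ``u``.  Rejection (a direct effect) is declared when the observed test
    MSE beats the null distribution, i.e. ``p < alpha``.
    """
    if spec.M <= 0:
        raise InvalidArgumentError("input test requires a spec with M > 0")
    u = np.asarray(u, dtype=float)
    if not np.any(u != 0):
        return CausalTestResult(
            observed_mse=np.nan, null_mse=np.zeros(0), p_value=1.0,
            n_boot=n_boot, alpha=alpha, reject=False, seed=seed, degenerate=True,
        )
    rng = np.random.default_rng(seed)
    observed = _fit_and_test_mse(y, u, U, windows, spec, lam)
    null = np.empty(n_boot)
    T = u.shape[0]
    for r in range(n_boot):
        u_tilde = u[rng.permutation(T)]
        null[r] = _fit_and_test_mse(y, u_tilde, U, windows, spec, lam)
    p = (1 + int(np.sum(null <= observed))) / (1 + n_boot)
    return CausalTestResult(
        observed_mse=observed, null_mse=null, p_value=p, n_boot=n_boot,
        alpha=alpha, reject=p < alpha, seed=seed,
    )


def bootstrap_network_test(
    y: np.ndarray,
    u: np.ndarray,
    U: np.ndarray,
    windows: WindowSet | list[Window],
    spec: ModelSpec,
    lam: float = DEFAULT_LAMBDA,
    n_boot: int = 100,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> CausalTestResult:
    """Test for causal network effects from the other channels.

    Each replicate applies one random time permutation jointly to every
    source channel's series before rebuilding the network features.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if spec.P <= 0 or not spec.sources:
        raise InvalidArgumentError("network test requires P > 0 and sources")
    if y.shape[0] < 2:
        raise DataError("network test requires at least 2 channels")
    rng = np.random.default_rng(seed)
    observed = _fit_and_test_mse(y, u, U, windows, spec, lam)
    null = np.empty(n_boot)
    T = y.shape[1]
    others = list(spec.sources)
    for r in range(n_boot):
        perm = rng.permutation(T)
        y_tilde = y.copy()
        y_tilde[others] = y[others][:, perm]
        null[r] = _fit_and_test_mse(y_tilde, u, U, windows, spec, lam)
    p = (1 + int(np.sum(null <= observed))) / (1 + n_boot)
    return CausalTestResult(
        observed_mse=observed, null_mse=null, p_value=p, n_boot=n_boot,
        alpha=alpha, reject=p < alpha, seed=seed,
    )


def linearity_test(
    y: np.ndarray,
    u: np.ndarray,
    U: np.ndarray,
    windows: WindowSet | list[Window],
    k: int,
    L: int,
    M: int,
    lam: float = DEFAULT_LAMBDA,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> dict:
    """Indirect test of stimulation-induced nonlinearity for channel ``k``.

    Three sub-datasets: (1) STIM OFF samples, used to fit autoregressive
    weights ``a1``; (2) half the STIM ON windows, used to fit a full ARX
    ``{a2, b2}`` and a constrained ARX ``{a1, b3}`` (autoregressive block
    frozen at ``a1``); (3) the held-out STIM ON windows, on which both are
    tested.  A significantly better Stim model (one-sided signed-rank across
    windows) indicates that a single linear model cannot capture both
    regimes.
    """
    win_list = list(windows)
    spec = ModelSpec(target=k, L=L, M=M, gating="none")
    ds = build_features(y, u, U, win_list, spec)

    on = np.zeros(ds.N, dtype=bool)
    for wi, w in enumerate(win_list):
        lo, hi = w.stim_span
        on |= (ds.window_index == wi) & (ds.t_index >= lo) & (ds.t_index < hi)
    if not on.any() or on.all():
        raise DataError("linearity test needs both STIM ON and STIM OFF samples")

    on_windows = np.unique(ds.window_index[on])
    if on_windows.size < 2:
        raise DataError("need at least 2 STIM ON windows to split train/test")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(on_windows)
    train_w = set(shuffled[: on_windows.size // 2].tolist())
    rows_off = ~on
    rows_on_train = on & np.isin(ds.window_index, list(train_w))
    rows_on_test = on & ~np.isin(ds.window_index, list(train_w))

    ar_spec = ModelSpec(target=k, L=L, M=0, gating="none")
    ds_ar = build_features(y, u, U, win_list, ar_spec)
    a1 = fit_ridge(ds_ar, lam=lam, rows=rows_off).theta

    stim_model = fit_ridge(ds, lam=lam, rows=rows_on_train)
    rs_model = fit_constrained_stim(ds, a1, lam=lam, rows=rows_on_train)

    res_stim = evaluate(stim_model, ds, rows=rows_on_test)
    res_rs = evaluate(rs_model, ds, rows=rows_on_test)
    diff = res_stim["window_errors"] - res_rs["window_errors"]
    if np.allclose(diff, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diff, alternative="less").pvalue)
    return {
        "mse_rs": res_rs["mse"],
        "mse_stim": res_stim["mse"],
        "delta": res_rs["mse"] - res_stim["mse"],
        "p_value": p,
        "nonlinear": p < alpha,
        "window_errors_rs": res_rs["window_errors"],
        "window_errors_stim": res_stim["window_errors"],
    }
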