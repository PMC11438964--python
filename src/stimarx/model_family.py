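"""Feature construction and prediction for the one-step model family.

The one-step model predicts the increment ``dy_k(t) = y_k(t+1) - y_k(t)`` as

    dy_k(t) = (a_k + U(t) c_k)' y_k^L(t) + b_k' u^M(t) + sum_i d_{k,i}' y_i^P(t)

with lag vectors starting at ``t - 1`` (``y_k^L(t) = [y_k(t-1), ..., y_k(t-L)]``),
or at delay-embedded lags ``t - tau, ..., t - L tau`` for sparse specs (the
input block stays dense).  Which blocks are free is determined by the
:class:`~stimarx.types.ModelSpec` family.
"""

from __future__ import annotations

import numpy as np

from .types import (
    DataError,
    FittedModel,
    InvalidArgumentError,
    ModelSpec,
    RegressionDataset,
    Window,
    WindowSet,
)


def _lag_matrix(series: np.ndarray, ts: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Rows ``[series[t - lag] for lag in lags]`` for each t in ``ts``."""
    if lags.size == 0:
        return np.zeros((ts.size, 0))
    return series[ts[:, None] - lags[None, :]]


def build_features(
    y: np.ndarray,
    u: np.ndarray,
    U: np.ndarray,
    windows: WindowSet | list[Window],
    spec: ModelSpec,
) -> RegressionDataset:
    """Extract the regression dataset for ``spec`` from windowed data.

    Rows are all samples ``t`` whose full lag history and target ``t + 1`` lie
    inside their own window (history never crosses window boundaries; it may
    cross fold boundaries).  Fold membership is defined by the target sample.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    u = np.asarray(u, dtype=float)
    U = np.asarray(U, dtype=float)
    if spec.n_params == 0:
        raise DataError("spec has no free features (L = M = P = 0)")
    if spec.target >= y.shape[0]:
        raise InvalidArgumentError("target channel out of range")
    for i in spec.sources:
        if i >= y.shape[0]:
            raise InvalidArgumentError(f"source channel {i} out of range")

    k = spec.target
    maxlag = max(spec.max_lag, 1)
    ar_lags = (np.arange(1, spec.L + 1) * (spec.tau if spec.sparse else 1)).astype(int)
    in_lags = np.arange(1, spec.M + 1)
    net_lags = np.arange(1, spec.P + 1)

    X_parts, dy_parts, yt_parts, t_parts, w_parts, f_parts, train_parts = (
        [], [], [], [], [], [], [])
    win_list = list(windows)
    for wi, w in enumerate(win_list):
        lo = w.start + maxlag
        hi = w.stop - 2  # need t+1 <= stop-1
        if hi < lo:
            continue
        ts = np.arange(lo, hi + 1)
        cols = []
        ar = _lag_matrix(y[k], ts, ar_lags)
        cols.append(ar)
        if spec.gated:
            cols.append(U[ts][:, None] * ar)
        cols.append(_lag_matrix(u, ts, in_lags))
        for i in spec.sources:
            cols.append(_lag_matrix(y[i], ts, net_lags))
        X_parts.append(np.hstack(cols))
        dy_parts.append(y[k, ts + 1] - y[k, ts])
        yt_parts.append(y[k, ts])
        t_parts.append(ts)
        w_parts.append(np.full(ts.size, wi))
        folds = w.fold_of(ts)
        f_parts.append(folds)
        train_parts.append(folds != w.test_fold)

    if not X_parts:
        raise DataError("no usable samples: windows shorter than the lag span")
    return RegressionDataset(
        X=np.vstack(X_parts),
        dy=np.concatenate(dy_parts),
        y_t=np.concatenate(yt_parts),
        t_index=np.concatenate(t_parts),
        window_index=np.concatenate(w_parts),
        fold=np.concatenate(f_parts),
        is_train=np.concatenate(train_parts),
        spec=spec,
    )


def predict_one_step(
    model: FittedModel, x: np.ndarray, y_t: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """``(dy_hat, y_hat(t+1))`` for one or more feature rows."""
    dy = model.predict_dy(x)
    return dy, np.asarray(y_t, dtype=float) + dy


def rollout(
    model: FittedModel,
    y_context: np.ndarray,
    u: np.ndarray,
    U: np.ndarray,
    t0: int,
    n_steps: int,
) -> np.ndarray:
    """Iterated one-step prediction for the target channel.

    Starting from true history up to and including sample ``t0``, feeds
    predictions back as the target channel's history for ``n_steps`` steps.
    Other channels (network sources) and the input series are taken as given.
    Returns the predicted ``y_k(t0 + 1 .. t0 + n_steps)``; ``n_steps == 1``
    coincides with :func:`predict_one_step`.
    """
    y = np.atleast_2d(np.asarray(y_context, dtype=float)).copy()
    u = np.asarray(u, dtype=float)
    U = np.asarray(U, dtype=float)
    spec = model.spec
    k = spec.target
    maxlag = max(spec.max_lag, 1)
    if t0 - maxlag < 0:
        raise DataError(f"insufficient history: need {maxlag} samples before t0")
    if t0 + n_steps >= y.shape[1]:
        raise DataError("context arrays too short for the requested rollout")
    ar_lags = (np.arange(1, spec.L + 1) * (spec.tau if spec.sparse else 1)).astype(int)
    in_lags = np.arange(1, spec.M + 1)
    net_lags = np.arange(1, spec.P + 1)
    out = np.empty(n_steps)
    for s in range(n_steps):
        t = t0 + s
        parts = []
        ar = y[k, t - ar_lags] if ar_lags.size else np.zeros(0)
        parts.append(ar)
        if spec.gated:
            parts.append(U[t] * ar)
        parts.append(u[t - in_lags] if in_lags.size else np.zeros(0))
        for i in spec.sources:
            parts.append(y[i, t - net_lags])
        x = np.concatenate(parts)
        y[k, t + 1] = y[k, t] + float(model.predict_dy(x)[0])
        out[s] = y[k, t + 1]
    return out


def auto_mutual_information(
    series: np.ndarray, max_lag: int, bins: int = 16
) -> np.ndarray:
    """Histogram-estimated mutual information of ``(y(t), y(t-lag))`` per lag.

    Returns an array of length ``max_lag`` for lags ``1..max_lag``.
    """
    x = np.asarray(series, dtype=float)
    out = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        a, b = x[lag:], x[:-lag]
        joint, _, _ = np.histogram2d(a, b, bins=bins)
        pxy = joint / joint.sum()
        px = pxy.sum(axis=1, keepdims=True)
        py = pxy.sum(axis=0, keepdims=True)
        nz = pxy > 0
        out[lag - 1] = float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))
    return out


def select_tau(
    series: np.ndarray, cap: int = 20, bins: int = 16, rtol: float = 0.02
) -> int:
    """Delay time as the first local minimum of the lagged auto mutual information.

    Scans lags ``1..cap``; the first lag at which the AMI stops decreasing
    (within ``rtol`` of the AMI dynamic range) is returned, clipped to
    ``[1, cap]``.  Monotone-decaying AMI (slow drift) returns ``cap``.
    """
    x = np.asarray(series, dtype=float)
    if cap < 1:
        raise InvalidArgumentError("cap must be >= 1")
    if x.std() == 0:
        raise DataError("constant series: delay time undefined")
    if cap == 1:
        return 1
    ami = auto_mutual_information(x, cap, bins=bins)
    eps = rtol * (ami.max() - ami.min() + 1e-12)
    for lag in range(1, cap):
        if ami[lag - 1] <= ami[lag] + eps:
            return lag
    return cap
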