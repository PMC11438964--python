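"""Ridge estimation and hierarchical model-structure search.

The fit criterion is the per-sample mean squared error of the one-step
increment plus an l2 penalty::

    cost(theta) = (1/N) sum_t (dy(t) - theta' x(t))^2 + lam * ||theta||^2

whose minimizer solves ``(X'X + N lam I) theta = X' dy``.  Note the explicit
``N`` factor in front of ``lam``: the penalty multiplies the *mean* squared
error, not the sum.  No intercept is fit (signals are z-scored upstream).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .model_family import build_features
from .types import (
    DataError,
    FittedModel,
    InvalidArgumentError,
    ModelSpec,
    RegressionDataset,
    Window,
    WindowSet,
)
from . import evaluation

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = 0.1
# printed order grids: L in {0, 1, 50, 100, ..., 500}, M in {0, 100, 200, 300}
DEFAULT_L_GRID = (0, 1) + tuple(range(50, 501, 50))
DEFAULT_M_GRID = (0, 100, 200, 300)
# network lags swept from 1 to 100 in steps of 10
DEFAULT_P_GRID = tuple(range(1, 100, 10)) + (100,)


def ridge_solve(X: np.ndarray, t: np.ndarray, lam: float) -> np.ndarray:
    """Solve ``(X'X + N lam I) theta = X' t`` deterministically.

    Uses a Cholesky factorization of the (symmetric PD for ``lam > 0``) normal
    matrix; for a singular system at ``lam == 0`` falls back to the
    minimum-norm least-squares solution with a warning.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float)
    if X.shape[0] == 0:
        raise DataError("cannot fit on an empty sample set")
    if lam < 0:
        raise InvalidArgumentError("lambda must be nonnegative")
    if X.shape[1] == 0:
        return np.zeros(0)
    N = X.shape[0]
    A = X.T @ X + N * lam * np.eye(X.shape[1])
    b = X.T @ t
    try:
        c, low = sla.cho_factor(A)
        return sla.cho_solve((c, low), b)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular normal equations; using minimum-norm least squares",
            RuntimeWarning,
        )
        return np.linalg.lstsq(X, t, rcond=None)[0]


def fit_ridge(
    dataset: RegressionDataset,
    lam: float = DEFAULT_LAMBDA,
    rows: str | np.ndarray = "train",
) -> FittedModel:
    """Ridge-fit all free parameters of the dataset's spec."""
    mask = dataset.rows(rows) if isinstance(rows, str) else np.asarray(rows, bool)
    theta = ridge_solve(dataset.X[mask], dataset.dy[mask], lam)
    return FittedModel(
        spec=dataset.spec,
        theta=theta,
        lam=lam,
        n_train=int(mask.sum()),
    )


def fit_constrained_stim(
    dataset: RegressionDataset,
    a_fixed: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    rows: str | np.ndarray = "train",
) -> FittedModel:
    """Ridge-fit with the autoregressive block frozen at ``a_fixed``.

    The remaining blocks are fit against the residual target
    ``dy - a_fixed' y^L``.  With no remaining free blocks the frozen model is
    returned unchanged.
    """
    a_fixed = np.asarray(a_fixed, dtype=float).ravel()
    spec = dataset.spec
    sl = spec.block_slices()["a"]
    if a_fixed.size != sl.stop - sl.start:
        raise InvalidArgumentError(
            f"a_fixed length {a_fixed.size} != L = {sl.stop - sl.start}"
        )
    mask = dataset.rows(rows) if isinstance(rows, str) else np.asarray(rows, bool)
    rest = np.ones(dataset.n_features, dtype=bool)
    rest[sl] = False
    theta = np.zeros(dataset.n_features)
    theta[sl] = a_fixed
    if rest.any():
        resid = dataset.dy[mask] - dataset.X[mask][:, sl] @ a_fixed
        theta[rest] = ridge_solve(dataset.X[mask][:, rest], resid, lam)
    return FittedModel(
        spec=spec,
        theta=theta,
        lam=lam,
        n_train=int(mask.sum()),
        meta={"constrained": "a"},
    )


@dataclass
class OrderSearchResult:
    best_mean: tuple[int, int]
    best_median: tuple[int, int]
    table: pd.DataFrame  # columns L, M, mse, nmse
    window_errors: dict[tuple[int, int], np.ndarray]


def grid_search_orders(
    y: np.ndarray,
    u: np.ndarray,
    U: np.ndarray,
    windows: WindowSet | list[Window],
    k: int,
    L_grid=DEFAULT_L_GRID,
    M_grid=DEFAULT_M_GRID,
    lam: float = DEFAULT_LAMBDA,
    alpha: float = 0.05,
) -> OrderSearchResult:
    """Sweep ARX orders ``(L, M)`` and return both selection criteria.

    All orders are evaluated on the identical sample set defined by the
    largest lags in the grid, so test errors are directly comparable; the
    Gram matrix of the largest model is computed once and submodels are
    solved on its sub-blocks.  The mean criterion returns the argmin of the
    test MSE; the median criterion applies pairwise one-sided Wilcoxon
    signed-rank tests across per-window test errors with Bonferroni
    correction.  Ties break toward smaller ``L`` then smaller ``M``.
    """
    L_grid = sorted(set(int(v) for v in L_grid))
    M_grid = sorted(set(int(v) for v in M_grid))
    if not L_grid or not M_grid:
        raise InvalidArgumentError("empty order grid")
    Lmax, Mmax = max(L_grid), max(M_grid)
    if Lmax == 0 and Mmax == 0:
        raise InvalidArgumentError("grid contains only the empty model")

    big = ModelSpec(target=k, L=Lmax, M=Mmax, gating="none")
    ds = build_features(y, u, U, windows, big)
    tr, te = ds.rows("train"), ds.rows("test")
    Xtr, Xte = ds.X[tr], ds.X[te]
    dytr, dyte = ds.dy[tr], ds.dy[te]
    wte = ds.window_index[te]
    Ntr = Xtr.shape[0]
    G = Xtr.T @ Xtr
    g = Xtr.T @ dytr
    var_te = float(np.var(dyte))

    rows = []
    window_errors: dict[tuple[int, int], np.ndarray] = {}
    uniq_w = np.unique(wte)
    for L in L_grid:
        for M in M_grid:
            ix = np.r_[np.arange(L), Lmax + np.arange(M)]
            if ix.size == 0:
                pred = np.zeros(dyte.size)
            else:
                A = G[np.ix_(ix, ix)] + Ntr * lam * np.eye(ix.size)
                try:
                    c, low = sla.cho_factor(A)
                    theta = sla.cho_solve((c, low), g[ix])
                except np.linalg.LinAlgError:
                    theta = np.linalg.lstsq(Xtr[:, ix], dytr, rcond=None)[0]
                pred = Xte[:, ix] @ theta
            err = (dyte - pred) ** 2
            mse = float(err.mean())
            rows.append({"L": L, "M": M, "mse": mse,
                         "nmse": mse / var_te if var_te > 0 else np.nan})
            window_errors[(L, M)] = np.array(
                [err[wte == w].mean() for w in uniq_w]
            )
    table = pd.DataFrame(rows)

    best_mean = None
    best_val = np.inf
    for r in rows:  # grid iterated in (L, M) order -> strict < keeps smallest
        if r["mse"] < best_val:
            best_val = r["mse"]
            best_mean = (r["L"], r["M"])

    n_params = {(L, M): L + M for L in L_grid for M in M_grid}
    labels = {f"{L},{M}": (L, M) for (L, M) in window_errors}
    winner, _ = evaluation.median_best(
        {lbl: window_errors[lm] for lbl, lm in labels.items()},
        n_params={lbl: n_params[lm] for lbl, lm in labels.items()},
        alpha=alpha,
    )
    best_median = labels[winner]
    return OrderSearchResult(
        best_mean=best_mean,
        best_median=best_median,
        table=table,
        window_errors=window_errors,
    )


def select_network_lags(
    y: np.ndarray,
    u: np.ndarray,
    U: np.ndarray,
    windows: WindowSet | list[Window],
    spec: ModelSpec,
    P_grid=DEFAULT_P_GRID,
    lam: float = DEFAULT_LAMBDA,
) -> tuple[int, pd.DataFrame]:
    """Refine the network lag ``P`` by validation MSE over the printed grid.

    ``spec`` carries the already-chosen family, ``(L, M)`` and source set.
    Returns ``(best_P, table)``; with no network sources returns ``P = 0``.
    """
    if not spec.sources:
        logger.info("no network sources: returning P = 0")
        return 0, pd.DataFrame(columns=["P", "mse"])
    rows = []
    best_P, best_val = None, np.inf
    for P in sorted(set(int(p) for p in P_grid)):
        ds = build_features(y, u, U, windows, spec.with_sources(spec.sources, P=P))
        model = fit_ridge(ds, lam=lam, rows="train")
        mse = evaluation.mse(model.predict_dy(ds.X[ds.rows("test")]),
                             ds.dy[ds.rows("test")])
        rows.append({"P": P, "mse": mse})
        if mse < best_val:
            best_val, best_P = mse, P
    return best_P, pd.DataFrame(rows)
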