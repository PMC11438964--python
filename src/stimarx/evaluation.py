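"""Test-set metrics and model-comparison statistics.

NMSE is test MSE divided by the variance of the test targets, so a perfect
predictor scores 0 and the constant-zero predictor scores 1 on zero-mean
targets.  "Win rate" is the fraction of channels on which a model attains
the strictly smallest cross-validated error, with exact ties credited to the
model with fewer parameters.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import DataError, FittedModel, InvalidArgumentError, RegressionDataset


def mse(predictions: np.ndarray, targets: np.ndarray) -> float:
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predictions.shape != targets.shape:
        raise InvalidArgumentError("predictions and targets must have equal length")
    return float(np.mean((predictions - targets) ** 2))


def nmse(predictions: np.ndarray, targets: np.ndarray) -> float:
    """MSE normalized by the variance of the targets over the same samples."""
    targets = np.asarray(targets, dtype=float)
    if targets.size < 2:
        raise InvalidArgumentError("need at least 2 samples")
    var = float(np.var(targets))
    if var == 0:
        raise DataError("zero target variance: NMSE undefined")
    return mse(predictions, targets) / var


def evaluate(
    model: FittedModel, dataset: RegressionDataset, rows: str | np.ndarray = "test"
) -> dict:
    """Test metrics plus per-window squared-error means for paired tests."""
    mask = dataset.rows(rows) if isinstance(rows, str) else np.asarray(rows, bool)
    pred = model.predict_dy(dataset.X[mask])
    targ = dataset.dy[mask]
    err = (pred - targ) ** 2
    wi = dataset.window_index[mask]
    uniq = np.unique(wi)
    var = float(np.var(targ))
    out = {
        "mse": float(err.mean()),
        "nmse": float(err.mean()) / var if var > 0 else np.nan,
        "n": int(mask.sum()),
        "window_errors": np.array([err[wi == w].mean() for w in uniq]),
        "windows": uniq,
    }
    return out


def win_rate(
    mse_table: pd.DataFrame, n_params: Mapping[str, int] | None = None
) -> pd.Series:
    """Per-model fraction of channels with the smallest error.

    ``mse_table`` is channels x models.  Exact ties are credited to the model
    with the fewest parameters (falling back to column order).
    """
    if mse_table.empty:
        raise InvalidArgumentError("empty MSE table")
    if mse_table.shape[1] < 2:
        raise InvalidArgumentError("need at least 2 models")
    models = list(mse_table.columns)
    order = {m: ((n_params.get(m, np.inf) if n_params else np.inf), str(m))
             for m in models}
    counts = {m: 0 for m in models}
    for _, row in mse_table.iterrows():
        best = row.min()
        tied = [m for m in models if row[m] == best]
        winner = min(tied, key=lambda m: order[m])
        counts[winner] += 1
    return pd.Series(counts, dtype=float) / len(mse_table)


def median_best(
    errors: Mapping[str, np.ndarray],
    n_params: Mapping[str, int] | None = None,
    alpha: float = 0.05,
) -> tuple[str, pd.DataFrame]:
    """Wilcoxon-based winner among models with paired per-fold/window errors.

    All ordered pairs are tested one-sided ("first model has smaller error")
    at level ``alpha`` divided by the number of tested pairs (Bonferroni).
    The winner is a model never found significantly worse than any other;
    among such candidates the one with fewest parameters wins.  With fewer
    than 6 paired samples the test is underpowered and the mean criterion is
    used instead (with a warning).
    """
    models = list(errors.keys())
    if len(models) < 2:
        raise InvalidArgumentError("need at least 2 models")
    lengths = {len(np.asarray(v)) for v in errors.values()}
    if len(lengths) != 1:
        raise InvalidArgumentError("error vectors must be paired (equal length)")
    n = lengths.pop()
    order = {m: ((n_params.get(m, np.inf) if n_params else np.inf), str(m))
             for m in models}
    if n < 6:
        warnings.warn(
            "fewer than 6 paired samples: falling back to the mean criterion",
            RuntimeWarning,
        )
        means = {m: float(np.mean(errors[m])) for m in models}
        best = min(means.values())
        tied = [m for m in models if means[m] == best]
        winner = min(tied, key=lambda m: order[m])
        return winner, pd.DataFrame()

    n_pairs = len(models) * (len(models) - 1) // 2
    corrected = alpha / n_pairs
    decisions = []
    worse = {m: False for m in models}
    for i, a in enumerate(models):
        for b in models[i + 1 :]:
            diff = np.asarray(errors[a], float) - np.asarray(errors[b], float)
            if np.allclose(diff, 0):
                p_ab = p_ba = 1.0
            else:
                p_ab = stats.wilcoxon(diff, alternative="less").pvalue
                p_ba = stats.wilcoxon(-diff, alternative="less").pvalue
            if p_ab < corrected:
                worse[b] = True
            if p_ba < corrected:
                worse[a] = True
            decisions.append(
                {"first": a, "second": b, "p_first_less": float(p_ab),
                 "p_second_less": float(p_ba), "alpha_corrected": corrected}
            )
    candidates = [m for m in models if not worse[m]]
    if not candidates:  # circular rejections; fall back to all models
        candidates = models
    winner = min(candidates, key=lambda m: order[m])
    return winner, pd.DataFrame(decisions)


def statistical_win_rate(
    errors: pd.DataFrame,
    value_col: str = "mse",
) -> pd.Series:
    """Fraction of channels for which each candidate ``L`` is sufficient.

    ``errors`` has columns ``channel``, ``L``, ``window`` and ``value_col``
    (per-window test errors).  For each channel the best ``L`` is the argmin
    of the mean error; a candidate ``L`` "suffices" if its mean error is
    within ``2 * SEM`` of the best model's mean, where the SEM is computed
    across the best model's per-window errors.
    """
    required = {"channel", "L", "window", value_col}
    if not required.issubset(errors.columns):
        raise InvalidArgumentError(f"errors must have columns {sorted(required)}")
    counts: dict[int, int] = {}
    channels = errors["channel"].unique()
    Ls = np.sort(errors["L"].unique())
    for L in Ls:
        counts[int(L)] = 0
    for ch in channels:
        sub = errors[errors["channel"] == ch]
        means = sub.groupby("L")[value_col].mean()
        best_L = means.idxmin()
        best_err = sub.loc[sub["L"] == best_L, value_col].to_numpy()
        if best_err.size < 2:
            raise DataError("SEM undefined with a single window per model")
        sem = best_err.std(ddof=1) / np.sqrt(best_err.size)
        cutoff = means[best_L] + 2 * sem
        for L in Ls:
            if means[L] <= cutoff:
                counts[int(L)] += 1
    return pd.Series(counts, dtype=float) / len(channels)
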