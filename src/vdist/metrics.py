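"""Fold-error evaluation statistics and method-comparison reports.

A prediction method is summarised by the percentage of compounds predicted
within 2-, 3- and 10-fold of observed, the squared Pearson correlation of
log10 predictions vs log10 observations, and the absolute average fold
error

    AAFE = 10 ** ( mean |log10(pred_i / obs_i)| ),

which equals 1 only for perfect predictions and is symmetric under
over/under-prediction.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InputError, VdistWarning

__all__ = [
    "fold_error",
    "pct_within",
    "aafe",
    "log_r2",
    "evaluate_methods",
]

_FOLDS = (2, 3, 10)


def _as_positive(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InputError(f"{name} is empty")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError(f"{name} must be finite and > 0")
    return arr


def fold_error(pred: float, obs: float) -> float:
    """Symmetric fold error ``max(pred/obs, obs/pred) >= 1``."""
    if pred <= 0 or obs <= 0:
        raise DomainError("fold error requires positive values")
    return max(pred / obs, obs / pred)


def pct_within(preds, obs, k: float) -> float:
    """Percentage of pairs with fold error <= k (boundary inclusive)."""
    if k <= 1:
        raise DomainError(f"fold threshold k = {k} must be > 1")
    p = _as_positive(preds, "preds")
    o = _as_positive(obs, "obs")
    if p.shape != o.shape:
        raise InputError("preds and obs must have equal length")
    fe = np.maximum(p / o, o / p)
    return 100.0 * float(np.mean(fe <= k))


def aafe(preds, obs) -> float:
    """Absolute average fold error (1.0 = perfect)."""
    p = _as_positive(preds, "preds")
    o = _as_positive(obs, "obs")
    if p.shape != o.shape:
        raise InputError("preds and obs must have equal length")
    return float(10.0 ** np.mean(np.abs(np.log10(p / o))))


def log_r2(preds, obs) -> float | None:
    """Squared Pearson correlation of log10(pred) vs log10(obs).

    Returns None (with a warning) when either vector has zero variance.
    """
    p = _as_positive(preds, "preds")
    o = _as_positive(obs, "obs")
    if p.shape != o.shape:
        raise InputError("preds and obs must have equal length")
    if p.size < 3:
        raise InputError(f"log_r2 requires n >= 3, got n = {p.size}")
    lp, lo = np.log10(p), np.log10(o)
    if np.ptp(lp) == 0 or np.ptp(lo) == 0:
        warnings.warn(
            "log_r2 undefined: zero variance in predictions or observations",
            VdistWarning,
            stacklevel=2,
        )
        return None
    r, _ = stats.pearsonr(lp, lo)
    return float(r * r)


def linear_r2(preds, obs) -> float | None:
    """Squared Pearson correlation on the linear scale (config alternative)."""
    p = _as_positive(preds, "preds")
    o = _as_positive(obs, "obs")
    if p.size < 3:
        raise InputError(f"linear_r2 requires n >= 3, got n = {p.size}")
    if np.ptp(p) == 0 or np.ptp(o) == 0:
        warnings.warn("linear_r2 undefined: zero variance", VdistWarning, stacklevel=2)
        return None
    r, _ = stats.pearsonr(p, o)
    return float(r * r)


def evaluate_methods(
    predictions: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    observed: Mapping[str, float],
    r2_scale: str = "log",
) -> pd.DataFrame:
    """Per-method summary table.

    Parameters
    ----------
    predictions
        Either ``{method_label: {compound_id: vdss}}`` or a DataFrame with
        columns (compound_id, method_label, vdss_L_per_kg).
    observed
        ``{compound_id: observed vdss}``.  Compounds missing either value
        are excluded per method.
    r2_scale
        "log" (default) or "linear".

    Returns
    -------
    DataFrame with columns method_label, n, pct_within_2fold,
    pct_within_3fold, pct_within_10fold, r2, aafe — one row per method,
    mirroring the usual method-comparison table layout.
    """
    if isinstance(predictions, pd.DataFrame):
        grouped: dict[str, dict[str, float]] = {}
        for row in predictions.itertuples(index=False):
            grouped.setdefault(row.method_label, {})[row.compound_id] = (
                row.vdss_L_per_kg
            )
        predictions = grouped
    r2_fn = log_r2 if r2_scale == "log" else linear_r2

    rows = []
    for method, preds in predictions.items():
        # sorted so the report is invariant to input row order
        ids = sorted(
            c for c, v in preds.items()
            if c in observed and v is not None and v > 0 and observed[c] > 0
        )
        if not ids:
            continue
        p = np.array([preds[c] for c in ids], dtype=float)
        o = np.array([observed[c] for c in ids], dtype=float)
        row = {"method_label": method, "n": len(ids)}
        for k in _FOLDS:
            row[f"pct_within_{k}fold"] = pct_within(p, o, k)
        row["r2"] = r2_fn(p, o) if len(ids) >= 3 else None
        row["aafe"] = aafe(p, o)
        rows.append(row)
    if not rows:
        raise InputError("no method had predictions overlapping the observations")
    return pd.DataFrame(rows)
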