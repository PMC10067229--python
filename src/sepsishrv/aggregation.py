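"""Admission-aligned 3-hour summaries of per-window HRV features.

Every retained 5-minute window is assigned to the 3-hour bin containing its
start (bin k covers [3k, 3k+3) hours from ED admission; a 48-hour stay spans
16 bins). Within a bin each feature is summarised by its arithmetic mean over
non-missing windows and by the ordinary-least-squares slope of feature value
against window midpoint time in hours. Means require at least one window,
slopes at least two; otherwise the summary is missing. The bin-0 means form
the design matrix of the deterioration model — only the first three hours
after admission are used for prediction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

__all__ = [
    "BIN_LENGTH_S",
    "bin_windows",
    "summarize_bin",
    "aggregate_features",
    "first_interval_matrix",
]

BIN_LENGTH_S = 3 * 3600.0


def bin_windows(features: pd.DataFrame, bin_length_s: float = BIN_LENGTH_S) -> pd.DataFrame:
    """Attach a ``bin_index`` column: floor(window_start / 3 h).

    ``features`` holds one row per retained window with a ``window_start``
    column in seconds from admission. Negative window times are rejected.
    """
    if (features["window_start"] < 0).any():
        raise ValueError("window_start must be nonnegative (admission-aligned)")
    out = features.copy()
    out["bin_index"] = (out["window_start"] // bin_length_s).astype(int)
    return out


def summarize_bin(
    times_h: np.ndarray, values: np.ndarray
) -> tuple[float, float]:
    """(mean, slope) of one feature within one bin.

    ``times_h`` are window midpoints in hours. Missing values are dropped;
    the slope is the OLS fit of value against time and needs >= 2 points at
    distinct times.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    t, v = t[ok], v[ok]
    if len(v) == 0:
        return (np.nan, np.nan)
    mean = float(np.mean(v))
    if len(v) < 2 or np.ptp(t) == 0:
        return (mean, np.nan)
    slope = float(np.polyfit(t, v, 1)[0])
    return (mean, slope)


def aggregate_features(
    features: pd.DataFrame,
    feature_names: list[str] | None = None,
    bin_length_s: float = BIN_LENGTH_S,
) -> pd.DataFrame:
    """Per-patient-per-bin mean and slope of every feature.

    Input: one row per retained window with ``patient_id``, ``window_start``
    and feature columns. Output: one row per (patient_id, bin_index) with
    ``mean_<f>``, ``slope_<f>`` and ``n_windows`` columns.
    """
    feature_names = feature_names or [f for f in FEATURE_NAMES if f in features.columns]
    binned = bin_windows(features, bin_length_s)
    binned["midpoint_h"] = (binned["window_start"] + 150.0) / 3600.0
    rows = []
    for (pid, b), grp in binned.groupby(["patient_id", "bin_index"], sort=True):
        row: dict[str, object] = {
            "patient_id": pid,
            "bin_index": int(b),
            "n_windows": len(grp),
        }
        for f in feature_names:
            mean, slope = summarize_bin(grp["midpoint_h"].to_numpy(), grp[f].to_numpy())
            row[f"mean_{f}"] = mean
            row[f"slope_{f}"] = slope
        rows.append(row)
    return pd.DataFrame(rows)


def first_interval_matrix(
    summaries: pd.DataFrame,
    feature_names: list[str] | None = None,
    include_slopes: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Design matrix of bin-0 feature means (one row per patient).

    Patients without any retained bin-0 window are excluded and listed in the
    second return value. Column order follows ``feature_names`` exactly.
    """
    feature_names = feature_names or [
        c.removeprefix("mean_") for c in summaries.columns if c.startswith("mean_")
    ]
    all_patients = list(pd.unique(summaries["patient_id"]))
    bin0 = summaries[summaries["bin_index"] == 0].set_index("patient_id")
    cols = [f"mean_{f}" for f in feature_names]
    if include_slopes:
        cols += [f"slope_{f}" for f in feature_names]
    excluded = [p for p in all_patients if p not in bin0.index]
    design = bin0.loc[[p for p in all_patients if p in bin0.index], cols]
    if design.empty:
        raise ValueError("no patient has retained bin-0 windows: empty design matrix")
    return design, excluded
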