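"""Tumor-burden metrics: caliper volume, relative series, percent change.

Subcutaneous tumor volume uses the ellipsoid approximation
V = pi * L * W^2 / 6 with L the larger and W the smaller caliper axis.
Burden series (volume or bioluminescent radiance) are normalized per
subject to a baseline day, and regression is summarized as a percent
change between two days.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd


def tumor_volume(length_mm, width_mm):
    """Ellipsoid caliper volume V = pi * L * W^2 / 6 (mm^3).

    If width exceeds length the axes are swapped with a warning (the
    formula squares the smaller axis).  Non-positive dimensions are an
    error.  Accepts scalars or arrays.
    """
    L = np.asarray(length_mm, dtype=float)
    W = np.asarray(width_mm, dtype=float)
    if np.any(L <= 0) or np.any(W <= 0):
        raise ValueError("caliper dimensions must be positive")
    if np.any(W > L):
        warnings.warn("width > length; axes swapped (L=max, W=min)", stacklevel=2)
        L, W = np.maximum(L, W), np.minimum(L, W)
    vol = math.pi * L * W**2 / 6.0
    return float(vol) if np.ndim(vol) == 0 else vol


def add_volumes(df: pd.DataFrame) -> pd.DataFrame:
    """Attach ``volume_mm3`` computed from length_mm/width_mm columns."""
    out = df.copy()
    out["volume_mm3"] = tumor_volume(
        out["length_mm"].to_numpy(), out["width_mm"].to_numpy()
    )
    return out


def _burden_column(df: pd.DataFrame, value_col: str | None) -> str:
    if value_col is not None:
        return value_col
    for c in ("radiance", "volume_mm3"):
        if c in df.columns:
            return c
    raise KeyError("no burden column found (expected 'radiance' or 'volume_mm3')")


def relative_series(
    df: pd.DataFrame,
    baseline_day: float,
    value_col: str | None = None,
    subject_key: str = "subject",
    day_key: str = "day",
) -> pd.DataFrame:
    """Normalize each subject's burden series to its baseline-day value.

    The baseline day maps to exactly 1.  Subjects without a measurement at
    ``baseline_day`` are excluded with a warning.  Adds a ``relative``
    column; invariant to rescaling a subject's whole series.
    """
    col = _burden_column(df, value_col)
    pieces = []
    for subject, sub in df.groupby(subject_key, sort=True):
        base = sub.loc[sub[day_key] == baseline_day, col]
        if len(base) == 0:
            warnings.warn(
                f"subject {subject!r} has no day {baseline_day} baseline; excluded",
                stacklevel=2,
            )
            continue
        b = float(base.iloc[0])
        if b == 0:
            raise ValueError(f"subject {subject!r} baseline value is zero")
        out = sub.copy()
        out["relative"] = out[col] / b
        pieces.append(out)
    if not pieces:
        return df.iloc[0:0].assign(relative=pd.Series(dtype=float))
    return pd.concat(pieces, ignore_index=True)


def percent_change(
    df: pd.DataFrame,
    from_day: float,
    to_day: float,
    value_col: str | None = None,
    subject_key: str = "subject",
    day_key: str = "day",
) -> pd.Series:
    """Per-subject percent change 100 * (v_to - v_from) / v_from.

    Negative values indicate regression (e.g. 100 -> 1 gives -99%).
    Subjects missing either day, or with a zero starting value, are an
    error.
    """
    col = _burden_column(df, value_col)
    result = {}
    for subject, sub in df.groupby(subject_key, sort=True):
        v_from = sub.loc[sub[day_key] == from_day, col]
        v_to = sub.loc[sub[day_key] == to_day, col]
        if len(v_from) == 0 or len(v_to) == 0:
            raise ValueError(
                f"subject {subject!r} missing day {from_day} or {to_day}"
            )
        v0 = float(v_from.iloc[0])
        if v0 == 0:
            raise ValueError(f"subject {subject!r} has zero value at day {from_day}")
        result[subject] = 100.0 * (float(v_to.iloc[0]) - v0) / v0
    return pd.Series(result, name="percent_change")


def summarize_groups(
    df: pd.DataFrame,
    value_col: str | None = None,
    group_key: str = "group",
    day_key: str = "day",
) -> pd.DataFrame:
    """Mean and SD of the burden per group and day."""
    col = _burden_column(df, value_col)
    out = (
        df.groupby([group_key, day_key], sort=True)[col]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    return out
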