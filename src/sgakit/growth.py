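"""Exponential growth-curve fitting and population doubling time.

OD600 time series are fitted in their exponential ("linear on the log
scale") phase with the model ``y = Y * exp(B * x)`` by ordinary least
squares of ln(OD) on time; the population doubling time is then
``PD = 0.6931 / B * 60`` minutes.  The constant 0.6931 is the rounded
natural log of 2 used in the downstream reporting convention; pass
``exact_ln2=True`` for full-precision ln 2.

Window policy: among all runs of >= 4 consecutive readings with OD
inside the exponential band (default [0.05, 0.5]), every sub-window is
scored by OLS; the longest window with r^2 >= 0.99 wins, ties broken by
higher r^2.  If no window reaches the r^2 threshold the best-r^2
candidate is used and the fit is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, ValidationError

__all__ = [
    "LN2_PRINTED",
    "GrowthCurve",
    "GrowthFit",
    "fit_exponential",
    "doubling_time",
    "read_growth_table",
    "write_growth_table",
    "fit_growth_table",
]

#: rounded ln 2 of the doubling-time reporting convention
LN2_PRINTED = 0.6931


@dataclass
class GrowthCurve:
    """One sample's OD600 time series (times in hours, strictly increasing)."""

    sample_id: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.od = np.asarray(self.od, float)
        if self.times.size != self.od.size:
            raise ValidationError(f"{self.sample_id!r}: times and od differ in length")
        if self.times.size < 4:
            raise ValidationError(f"{self.sample_id!r}: need >= 4 readings")
        if (np.diff(self.times) <= 0).any():
            raise ValidationError(f"{self.sample_id!r}: times must strictly increase")
        if (self.od < 0).any():
            raise ValidationError(f"{self.sample_id!r}: negative OD reading")


@dataclass
class GrowthFit:
    """Result of the exponential fit for one curve."""

    sample_id: str
    Y: float  # OD600 intercept
    B: float  # growth rate per hour
    window: tuple[int, int]  # [start, end] indices, inclusive
    r_squared: float
    pd_minutes: float  # NaN when B <= 0
    pd_defined: bool
    window_ok: bool  # True when the window met the r^2 threshold


def doubling_time(B: float, exact_ln2: bool = False) -> float:
    """Population doubling time in minutes, PD = ln2 / B * 60."""
    if B <= 0:
        raise ComputationError(f"doubling time undefined for B = {B}")
    ln2 = float(np.log(2.0)) if exact_ln2 else LN2_PRINTED
    return ln2 / B * 60.0


def _ols_log(times: np.ndarray, od: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and r^2 of ln(od) on time (od must be positive)."""
    y = np.log(od)
    if np.ptp(y) == 0.0:  # flat on the log scale: perfect fit, slope 0
        return 0.0, float(y[0]), 1.0
    slope, intercept, r, _, _ = stats.linregress(times, y)
    return float(slope), float(intercept), float(r) ** 2


def fit_exponential(
    curve: GrowthCurve,
    od_band: tuple[float, float] = (0.05, 0.5),
    min_points: int = 4,
    r2_threshold: float = 0.99,
    exact_ln2: bool = False,
) -> GrowthFit:
    """Fit ``y = Y exp(Bx)`` over the best exponential-phase window."""
    lo, hi = od_band
    eligible = (curve.od > 0) & (curve.od >= lo) & (curve.od <= hi)
    candidates: list[tuple[int, int, float, float, float]] = []
    i = 0
    n = curve.times.size
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and eligible[j + 1]:
            j += 1
        for a in range(i, j - min_points + 2):
            for b in range(a + min_points - 1, j + 1):
                slope, intercept, r2 = _ols_log(
                    curve.times[a : b + 1], curve.od[a : b + 1]
                )
                candidates.append((a, b, slope, intercept, r2))
        i = j + 1
    if not candidates:
        raise ComputationError(
            f"{curve.sample_id!r}: no window of >= {min_points} readings inside "
            f"the OD band [{lo}, {hi}]"
        )
    good = [c for c in candidates if c[4] >= r2_threshold]
    window_ok = bool(good)
    pool = good if good else candidates
    # longest window first, then higher r^2
    a, b, slope, intercept, r2 = max(pool, key=lambda c: (c[1] - c[0], c[4]))
    pd_defined = slope > 0
    pd_min = doubling_time(slope, exact_ln2) if pd_defined else float("nan")
    return GrowthFit(
        sample_id=curve.sample_id,
        Y=float(np.exp(intercept)),
        B=slope,
        window=(a, b),
        r_squared=r2,
        pd_minutes=pd_min,
        pd_defined=pd_defined,
        window_ok=window_ok,
    )


def read_growth_table(path: str | Path) -> list[GrowthCurve]:
    """Read a curve TSV (sample, time_h, od600), one row per reading."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    missing = [c for c in ("sample", "time_h", "od600") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    curves = []
    for sample, grp in df.groupby("sample", sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(str(sample), grp["time_h"].to_numpy(), grp["od600"].to_numpy())
        )
    return curves


def write_growth_table(curves: Sequence[GrowthCurve], path: str | Path) -> None:
    pd.concat(
        [
            pd.DataFrame({"sample": c.sample_id, "time_h": c.times, "od600": c.od})
            for c in curves
        ],
        ignore_index=True,
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def fit_growth_table(
    curves: Sequence[GrowthCurve], **fit_kwargs
) -> pd.DataFrame:
    """Fit every curve and return the flat results table."""
    rows = []
    for c in curves:
        f = fit_exponential(c, **fit_kwargs)
        rows.append(
            {
                "sample": f.sample_id,
                "B_per_h": f.B,
                "Y": f.Y,
                "r2": f.r_squared,
                "window_start": f.window[0],
                "window_end": f.window[1],
                "PD_min": f.pd_minutes,
            }
        )
    return pd.DataFrame(rows)
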