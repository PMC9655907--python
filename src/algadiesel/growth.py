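"""Growth-curve handling: OD→dry-weight calibration, µ, productivities.

Batch microalgal growth is tracked as optical density at 680 nm and/or dry
weight (g/L). Dry weight is recovered from OD through a linear calibration
fitted by ordinary least squares. The specific growth rate over a window of
the exponential phase is

    µ = (ln DW_t − ln DW_0) / t      (day⁻¹)

and biomass / lipid productivities are concentration differences between
the early and late exponential phase divided by the elapsed time. Printed
productivities in this field are positive magnitudes, so the default report
is |late − early|/Δt with the window recorded; pass ``signed=True`` to keep
the sign of the difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthSeries",
    "OdDwCalibration",
    "ProductivityResult",
    "fit_calibration",
    "growth_rate",
    "productivity",
    "fold_change",
    "read_growth_csv",
    "estimate_mu",
    "best_log_window",
]


@dataclass(frozen=True)
class OdDwCalibration:
    """Linear OD₆₈₀ → dry-weight calibration, dw = slope·od + intercept."""

    slope: float  # (g/L) per absorbance unit
    intercept: float  # g/L
    r2: float

    def od_to_dw(self, od: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(od) + self.intercept


@dataclass
class GrowthSeries:
    """Timestamped OD/dry-weight measurements for one strain.

    Either measurement may be missing per sample (NaN); times must be
    strictly increasing.
    """

    strain_id: str
    time_days: Sequence[float]
    od680: Sequence[float] | None = None
    dw_gL: Sequence[float] | None = None
    phases: Sequence[str] | None = None  # optional lag/log/stationary labels

    def __post_init__(self) -> None:
        t = np.asarray(self.time_days, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.strain_id}: times must be strictly increasing")
        for name in ("od680", "dw_gL"):
            vals = getattr(self, name)
            if vals is not None and np.nanmin(np.asarray(vals, dtype=float)) < 0:
                raise ValueError(f"{self.strain_id}: negative {name} value")

    def dw(self, calibration: OdDwCalibration | None = None) -> np.ndarray:
        """Dry weight per sample, preferring measured DW over converted OD."""
        n = len(self.time_days)
        out = np.full(n, np.nan)
        if self.od680 is not None and calibration is not None:
            od = np.asarray(self.od680, dtype=float)
            out = np.where(np.isnan(od), out, calibration.od_to_dw(od))
        if self.dw_gL is not None:
            dw = np.asarray(self.dw_gL, dtype=float)
            out = np.where(np.isnan(dw), out, dw)
        return out


@dataclass(frozen=True)
class ProductivityResult:
    """Biomass (g/L/day) and lipid (mg/L/day) productivities over a window."""

    bp: float | None
    lp: float | None
    window: tuple[float, float]

    def as_dict(self) -> dict:
        return {"bp_gL_day": self.bp, "lp_mgL_day": self.lp, "window_days": list(self.window)}


def fit_calibration(points: Iterable[tuple[float, float]]) -> OdDwCalibration:
    """Least-squares OD₆₈₀ → dry weight line from (od, dw) pairs.

    Requires at least three points with non-degenerate OD spread.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("calibration needs at least 3 (od, dw) points")
    od, dw = pts[:, 0], pts[:, 1]
    if np.ptp(od) == 0:
        raise ValueError("degenerate calibration: all OD values equal")
    res = stats.linregress(od, dw)
    return OdDwCalibration(slope=res.slope, intercept=res.intercept, r2=res.rvalue**2)


def growth_rate(dw0: float, dwt: float, t: float) -> float:
    """Specific growth rate µ = (ln dwt − ln dw0)/t, day⁻¹."""
    if dw0 <= 0 or dwt <= 0:
        raise ValueError("dry weights must be positive for a log growth rate")
    if t <= 0:
        raise ValueError("elapsed time must be positive")
    return (math.log(dwt) - math.log(dw0)) / t


def productivity(
    dw_window: tuple[float, float, float, float] | None = None,
    lipid_window: tuple[float, float, float, float] | None = None,
    signed: bool = False,
) -> ProductivityResult:
    """Biomass and lipid productivity over early→late exponential windows.

    Each window is ``(t_early, value_early, t_late, value_late)`` — dry
    weight in g/L, lipid concentration in mg/L. By default the positive
    magnitude |late − early|/Δt is reported with the window recorded;
    ``signed=True`` keeps the sign of late − early.
    """

    def _rate(win: tuple[float, float, float, float]) -> tuple[float, tuple[float, float]]:
        t0, v0, t1, v1 = win
        dt = t1 - t0
        if dt <= 0:
            raise ValueError(f"window must have positive Δt, got {dt}")
        rate = (v1 - v0) / dt
        return (rate if signed else abs(rate)), (t0, t1)

    if dw_window is None and lipid_window is None:
        raise ValueError("need at least one of dw_window, lipid_window")
    bp = lp = None
    window = None
    if dw_window is not None:
        bp, window = _rate(dw_window)
    if lipid_window is not None:
        lp, lwin = _rate(lipid_window)
        window = window or lwin
    return ProductivityResult(bp=bp, lp=lp, window=window)


def fold_change(mutant_value: float, wild_value: float) -> tuple[float, float]:
    """(fold, percent increase) of a mutant trait over the wild strain.

    fold = mutant/wild; percent = (fold − 1) × 100.
    """
    if wild_value <= 0:
        raise ValueError("wild-strain value must be positive")
    fold = mutant_value / wild_value
    return fold, (fold - 1.0) * 100.0


def read_growth_csv(source: str | Path) -> list[GrowthSeries]:
    """Read growth series from CSV (strain, time_days, od680, dw_gL)."""
    df = pd.read_csv(source)
    required = {"strain", "time_days"}
    if not required <= set(df.columns):
        raise ValueError(f"growth CSV needs columns {sorted(required)}")
    out = []
    for strain, grp in df.groupby("strain", sort=False):
        grp = grp.sort_values("time_days")
        out.append(
            GrowthSeries(
                strain_id=str(strain),
                time_days=grp["time_days"].to_numpy(float),
                od680=grp["od680"].to_numpy(float) if "od680" in grp else None,
                dw_gL=grp["dw_gL"].to_numpy(float) if "dw_gL" in grp else None,
            )
        )
    return out


def estimate_mu(
    series: GrowthSeries,
    window: tuple[float, float] = (2.0, 16.0),
    calibration: OdDwCalibration | None = None,
) -> float:
    """µ from the first/last dry weights inside a time window (days)."""
    t = np.asarray(series.time_days, dtype=float)
    dw = series.dw(calibration)
    mask = (t >= window[0]) & (t <= window[1]) & ~np.isnan(dw) & (dw > 0)
    if mask.sum() < 2:
        raise ValueError(
            f"{series.strain_id}: fewer than 2 usable samples in window {window}"
        )
    tt, vv = t[mask], dw[mask]
    return growth_rate(vv[0], vv[-1], tt[-1] - tt[0])


def best_log_window(
    series: GrowthSeries,
    min_points: int = 4,
    calibration: OdDwCalibration | None = None,
) -> tuple[float, float]:
    """Window (t_start, t_end) maximizing R² of the ln(DW) regression.

    Automatic alternative to a user-specified exponential window: scans all
    contiguous sample windows of at least ``min_points`` with positive mean
    slope and returns the best-fitting one.
    """
    t = np.asarray(series.time_days, dtype=float)
    dw = series.dw(calibration)
    ok = ~np.isnan(dw) & (dw > 0)
    t, dw = t[ok], dw[ok]
    if len(t) < min_points:
        raise ValueError("too few usable samples for window selection")
    logdw = np.log(dw)
    best, best_r2 = None, -np.inf
    for i in range(len(t) - min_points + 1):
        for j in range(i + min_points, len(t) + 1):
            res = stats.linregress(t[i:j], logdw[i:j])
            if res.slope > 0 and res.rvalue**2 > best_r2:
                best_r2, best = res.rvalue**2, (t[i], t[j - 1])
    if best is None:
        raise ValueError("no growing window found")
    return best
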