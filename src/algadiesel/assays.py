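"""Spectrophotometric assays: pigment equations and standard-curve calibration.

Pigments are quantified from methanol-extract absorbances at 663, 644 and
452 nm with the classic chlorophyll equations

    Chl a       = 10.3·A663 − 0.913·A644          (µg/mL extract)
    Chl b       = 19.07·A644 − 3.87·A663
    carotenoids = 4.2·A452 − (0.0264·Chl a + 0.426·Chl b)

and converted to µg per mg dry weight through the extract volume and the
biomass in the aliquot. Small negative values — blank-subtraction noise —
are floored at zero with a warning rather than rejected.

Lipid (sulfo-phospho-vanillin), carbohydrate, protein and Nile-red TAG
readings are quantified against empirical linear standard curves; inversion
outside the calibrated concentration range is flagged as extrapolation,
never silent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .growth import fold_change

__all__ = [
    "PigmentReading",
    "PigmentResult",
    "StandardCurve",
    "InvertResult",
    "pigments",
    "fit_standard_curve",
    "invert",
    "composition_table",
    "CHL_B_COEFF",
]

#: Default Chl b coefficient on A644 (µg/mL per absorbance unit).
CHL_B_COEFF = 19.07

ANALYTES = ("lipid_SPV", "carbohydrate", "protein", "tag_nile_red")


@dataclass(frozen=True)
class PigmentReading:
    """Absorbances of one methanol extract plus the biomass it came from."""

    a663: float
    a644: float
    a452: float
    biomass_mg: float = 1.0
    extract_volume_mL: float = 1.0

    def __post_init__(self) -> None:
        if min(self.a663, self.a644, self.a452) < 0:
            raise ValueError("absorbances must be non-negative")
        if self.biomass_mg <= 0:
            raise ValueError("biomass must be positive for per-DW normalization")
        if self.extract_volume_mL <= 0:
            raise ValueError("extract volume must be positive")


@dataclass(frozen=True)
class PigmentResult:
    """Pigment contents in µg/mgDW (floored at 0; see ``floored``)."""

    chl_a: float
    chl_b: float
    carotenoids: float
    floored: tuple[str, ...] = ()

    @property
    def total(self) -> float:
        return self.chl_a + self.chl_b + self.carotenoids


def pigments(
    reading: PigmentReading,
    chl_b_coeff: float = CHL_B_COEFF,
    floor: bool = True,
) -> PigmentResult:
    """Pigment contents (µg/mgDW) from a three-wavelength reading.

    ``chl_b_coeff`` overrides the default 19.07 coefficient on A644.
    With ``floor=False`` raw (possibly negative) values are returned, which
    the linearity property tests rely on.
    """
    chl_a = 10.3 * reading.a663 - 0.913 * reading.a644
    chl_b = chl_b_coeff * reading.a644 - 3.87 * reading.a663
    caro = 4.2 * reading.a452 - (0.0264 * chl_a + 0.426 * chl_b)
    per_dw = reading.extract_volume_mL / reading.biomass_mg
    vals = {"chl_a": chl_a * per_dw, "chl_b": chl_b * per_dw, "carotenoids": caro * per_dw}
    floored: list[str] = []
    if floor:
        for key, v in vals.items():
            if v < 0:
                warnings.warn(
                    f"negative {key} ({v:.4g} µg/mgDW) floored to 0", stacklevel=2
                )
                vals[key] = 0.0
                floored.append(key)
    return PigmentResult(**vals, floored=tuple(floored))


@dataclass(frozen=True)
class StandardCurve:
    """Fitted line signal = slope·concentration + intercept."""

    analyte: str
    slope: float
    intercept: float
    r2: float
    conc_range: tuple[float, float]


@dataclass(frozen=True)
class InvertResult:
    concentration: float
    extrapolated: bool


def fit_standard_curve(
    points: Iterable[tuple[float, float]], analyte: str = "lipid_SPV"
) -> StandardCurve:
    """Least-squares standard curve from (concentration, signal) points.

    Needs at least three points spanning a nonzero concentration range.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("standard curve needs at least 3 points")
    conc, sig = pts[:, 0], pts[:, 1]
    if np.ptp(conc) == 0:
        raise ValueError("standards must span a nonzero concentration range")
    res = stats.linregress(conc, sig)
    if res.slope == 0:
        raise ValueError("degenerate standard curve: zero slope")
    return StandardCurve(
        analyte=analyte,
        slope=res.slope,
        intercept=res.intercept,
        r2=res.rvalue**2,
        conc_range=(float(conc.min()), float(conc.max())),
    )


def invert(curve: StandardCurve, signal: float) -> InvertResult:
    """Concentration for a signal; flags readings outside the calibrated range."""
    conc = (signal - curve.intercept) / curve.slope
    lo, hi = curve.conc_range
    return InvertResult(concentration=conc, extrapolated=not lo <= conc <= hi)


def composition_table(
    concentrations: pd.DataFrame,
    dw_gL: dict[str, float] | None = None,
    wild: str = "WS",
) -> pd.DataFrame:
    """Tidy composition table (mg/gDW, %DW, fold vs wild) per strain × analyte.

    ``concentrations`` has columns (strain, analyte, value). When ``dw_gL``
    is given, values are culture concentrations in mg/L and are divided by
    the strain's dry weight (g/L) to get mg/gDW; otherwise values are taken
    as mg/gDW already. %DW = mg/gDW / 10. Folds are relative to the wild
    strain's value for the same analyte.
    """
    need = {"strain", "analyte", "value"}
    if not need <= set(concentrations.columns):
        raise ValueError(f"concentration table needs columns {sorted(need)}")
    if wild not in set(concentrations["strain"]):
        raise ValueError(f"wild strain {wild!r} missing from table")

    df = concentrations.copy()
    if dw_gL is not None:
        missing = set(df["strain"]) - set(dw_gL)
        if missing:
            raise ValueError(f"no dry weight for strains: {sorted(missing)}")
        df["mg_per_gDW"] = [
            v / dw_gL[s] for s, v in zip(df["strain"], df["value"])
        ]
    else:
        df["mg_per_gDW"] = df["value"]
    df["pct_dw"] = df["mg_per_gDW"] / 10.0

    wild_vals = (
        df[df["strain"] == wild].set_index("analyte")["mg_per_gDW"].to_dict()
    )
    folds, pcts = [], []
    for _, row in df.iterrows():
        ref = wild_vals.get(row["analyte"])
        if ref is None or ref <= 0:
            folds.append(np.nan)
            pcts.append(np.nan)
        else:
            f, p = fold_change(row["mg_per_gDW"], ref)
            folds.append(f)
            pcts.append(p)
    df["fold_vs_wild"] = folds
    df["pct_change_vs_wild"] = pcts
    return df[
        ["strain", "analyte", "mg_per_gDW", "pct_dw", "fold_vs_wild", "pct_change_vs_wild"]
    ]
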