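"""Plasma-mutagenesis screening arithmetic.

Atmospheric and room temperature plasma (ARTP) mutagenesis exposes cells to
a helium plasma jet for increasing times; the dose is chosen from the
mortality curve and the surviving mutants are screened against the wild
strain. Three pieces of arithmetic live here:

* mortality per exposure, (1 − T/C) × 100, from treated (T) and control (C)
  colony counts;
* optimal-dose selection — the shortest exposure whose mortality reaches a
  threshold (≥95% maximizes the positive mutation rate) while leaving at
  least one survivor to screen;
* ranking mutants that beat the wild strain on both growth and lipid
  content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ScreeningTable",
    "MutantScreenRecord",
    "mortality_rate",
    "survival_rate",
    "select_exposure",
    "rank_mutants",
]


def mortality_rate(treated: int, control: int) -> float:
    """Mortality percentage (1 − T/C) × 100 from colony counts.

    Clamped to [0, 100]; a treated count above the control (T > C) warns
    and clamps to 0 rather than going negative.
    """
    if control <= 0:
        raise ValueError("control colony count must be positive")
    if treated < 0:
        raise ValueError("treated colony count must be non-negative")
    if treated > control:
        warnings.warn(
            f"treated colonies ({treated}) exceed control ({control}); "
            "mortality clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return (1.0 - treated / control) * 100.0


def survival_rate(treated: int, control: int) -> float:
    """Survival percentage, the complement of :func:`mortality_rate`."""
    return 100.0 - mortality_rate(treated, control)


@dataclass
class ScreeningTable:
    """Colony counts per exposure time with derived mortality rates."""

    exposures_s: Sequence[float]
    treated: Sequence[int]
    control: Sequence[int]

    def __post_init__(self) -> None:
        n = len(self.exposures_s)
        if not (len(self.treated) == len(self.control) == n):
            raise ValueError("exposure, treated and control must align")
        if len(set(self.exposures_s)) != n:
            raise ValueError("exposure times must be unique")

    @classmethod
    def from_csv(cls, source: str | Path) -> "ScreeningTable":
        df = pd.read_csv(source)
        need = {"exposure_s", "treated_colonies", "control_colonies"}
        if not need <= set(df.columns):
            raise ValueError(f"screening CSV needs columns {sorted(need)}")
        return cls(
            exposures_s=df["exposure_s"].tolist(),
            treated=df["treated_colonies"].tolist(),
            control=df["control_colonies"].tolist(),
        )

    def mortality(self) -> pd.DataFrame:
        """Per-row mortality percentages, sorted by exposure."""
        rows = [
            {
                "exposure_s": e,
                "treated": t,
                "control": c,
                "mortality_pct": mortality_rate(t, c),
            }
            for e, t, c in zip(self.exposures_s, self.treated, self.control)
        ]
        return pd.DataFrame(rows).sort_values("exposure_s", ignore_index=True)


def select_exposure(table: ScreeningTable, threshold: float = 95.0) -> float | None:
    """Smallest exposure with mortality ≥ threshold and ≥1 surviving colony.

    Fully lethal doses (no survivors) leave nothing to screen and are
    excluded. Returns None when no exposure qualifies ("no viable dose").
    Invariant under row permutation.
    """
    if not 0 < threshold < 100:
        raise ValueError("threshold must be in (0, 100)")
    df = table.mortality()
    ok = (df["mortality_pct"] >= threshold) & (df["treated"] > 0)
    if not ok.any():
        return None
    return float(df.loc[ok, "exposure_s"].iloc[0])


@dataclass(frozen=True)
class MutantScreenRecord:
    """One strain's screen measurements after 10 days of growth."""

    strain_id: str
    od_day10: float
    growth_rate: float  # day⁻¹
    lipid_gL: float


def rank_mutants(
    records: Iterable[MutantScreenRecord],
    wild: MutantScreenRecord,
    k: int,
    primary: str = "lipid",
) -> list[tuple[MutantScreenRecord, float, float]]:
    """Top-k mutants beating the wild strain on both growth rate and lipid.

    Filters to records with fold_growth > 1 AND fold_lipid > 1, then orders
    by the primary fold descending ("lipid" by default, "growth"
    alternatively), ties by the other fold descending, then strain id.
    Returns (record, fold_growth, fold_lipid) triples.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if wild.growth_rate <= 0 or wild.lipid_gL <= 0:
        raise ValueError("wild-strain values must be positive")
    if primary not in ("lipid", "growth"):
        raise ValueError("primary must be 'lipid' or 'growth'")
    scored = []
    for rec in records:
        fg = rec.growth_rate / wild.growth_rate
        fl = rec.lipid_gL / wild.lipid_gL
        if fg > 1 and fl > 1:
            scored.append((rec, fg, fl))
    if primary == "lipid":
        scored.sort(key=lambda r: (-r[2], -r[1], r[0].strain_id))
    else:
        scored.sort(key=lambda r: (-r[1], -r[2], r[0].strain_id))
    return scored[:k]
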