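"""Fatty-acid methyl ester (FAME) profiles: parsing, validation, class summaries.

GC-MS lipidomics of microalgae is routinely reported as a table of relative
percentages: rows are FAME species labelled like ``C16:0`` or ``C18:1 (ω9)``,
columns are strains, and a dash marks species below the detection limit.
This module parses such tables into :class:`FameProfile` objects and reduces
them to the class totals used in biodiesel feedstock assessment:

* SFA / MUFA / PUFA — percentages of species with 0, 1, and ≥2 C=C bonds;
* Db≥4 — percentage with four or more double bonds (EN 14214 caps it at 10%);
* the average degree of unsaturation ADU = Σ N·Mf, where N is the number of
  C=C bonds and Mf the mass fraction (percentage/100) of each species.

ADU is the single predictor in the linear fuel-property regressions of
:mod:`algadiesel.biodiesel`.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FattyAcid",
    "FameProfile",
    "FaClassSummary",
    "FaParseError",
    "ProfileValidationError",
    "parse_fa_name",
    "load_profiles",
    "class_summary",
    "summaries_frame",
    "ND_MARKERS",
]

#: Cell values interpreted as "not detected" (treated as 0.0, not missing).
ND_MARKERS = ("–", "—", "-", "", "ND", "nd", "n.d.")

#: Shortest FAME chain accepted (butyrate, the shortest species in C4–C24
#: calibration mixes).
MIN_CARBONS = 4

#: Per-strain totals outside this band fail validation on load.
TOTAL_GATE = (95.0, 105.0)

_FA_PATTERN = re.compile(
    r"^\s*C\s*(?P<carbons>\d+)\s*:\s*(?P<db>\d+)"
    r"(?:\s*\(\s*[ωw]\s*(?P<omega>\d+)\s*\))?\s*$"
)


class FaParseError(ValueError):
    """A fatty-acid label could not be parsed."""


class ProfileValidationError(ValueError):
    """A profile table violated a structural or numeric constraint."""


@dataclass(frozen=True, order=True)
class FattyAcid:
    """Identity of one FAME species.

    Two species with equal chain length and unsaturation but different ω
    position (e.g. C18:1 (ω7) vs C18:1 (ω9)) are distinct profile keys, as
    are annotated and unannotated isomers of the same formula.
    """

    carbons: int
    double_bonds: int
    omega: int | None = None

    def __post_init__(self) -> None:
        if self.carbons < MIN_CARBONS:
            raise FaParseError(
                f"carbons below minimum ({self.carbons} < {MIN_CARBONS})"
            )
        if self.double_bonds < 0:
            raise FaParseError(f"negative double-bond count: {self.double_bonds}")
        if self.carbons % 2:
            warnings.warn(
                f"odd carbon number in {self.label!r}; unusual for algal FAMEs",
                stacklevel=2,
            )

    @property
    def label(self) -> str:
        """Canonical label, e.g. ``'C18:1 (ω9)'``."""
        base = f"C{self.carbons}:{self.double_bonds}"
        return base if self.omega is None else f"{base} (ω{self.omega})"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_fa_name(label: str) -> FattyAcid:
    """Parse a fatty-acid label like ``'C18:1 (ω9)'`` into a :class:`FattyAcid`.

    Accepts flexible whitespace and a spelled-out ``w`` in place of the ω
    glyph. The canonical :attr:`FattyAcid.label` round-trips through this
    parser.

    Raises
    ------
    FaParseError
        If the label does not match ``C<carbons>:<double_bonds>`` with an
        optional ``(ω<position>)`` suffix, or the carbon count is below the
        minimum chain length.
    """
    m = _FA_PATTERN.match(label)
    if m is None:
        raise FaParseError(f"malformed fatty-acid label: {label!r}")
    omega = m.group("omega")
    return FattyAcid(
        carbons=int(m.group("carbons")),
        double_bonds=int(m.group("db")),
        omega=int(omega) if omega is not None else None,
    )


@dataclass(frozen=True)
class FameProfile:
    """A strain's compositional vector of relative FAME percentages."""

    strain_id: str
    fractions: Mapping[FattyAcid, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fractions", dict(self.fractions))
        for fa, pct in self.fractions.items():
            if pct < 0:
                raise ProfileValidationError(
                    f"{self.strain_id}: negative fraction {pct} for {fa.label}"
                )

    @property
    def total(self) -> float:
        """Sum of all fractions (percent of total FAMEs)."""
        return float(sum(self.fractions.values()))

    def __getitem__(self, key: FattyAcid | str) -> float:
        if isinstance(key, str):
            key = parse_fa_name(key)
        return self.fractions.get(key, 0.0)

    def normalize(self) -> "FameProfile":
        """Return a copy rescaled so the fractions sum to exactly 100.

        The original profile is unchanged. Idempotent up to floating point.
        """
        total = self.total
        if total <= 0:
            raise ProfileValidationError(
                f"{self.strain_id}: cannot normalize a zero-total profile"
            )
        scale = 100.0 / total
        return FameProfile(
            self.strain_id, {fa: pct * scale for fa, pct in self.fractions.items()}
        )


@dataclass(frozen=True)
class FaClassSummary:
    """Class totals and average degree of unsaturation for one profile."""

    strain_id: str
    sfa_pct: float  # species with no C=C bond
    mufa_pct: float  # exactly one C=C bond
    pufa_pct: float  # two or more
    db4plus_pct: float  # four or more (EN 14214 limit ≤ 10%)
    c18_3_pct: float  # all C18:3 isomers (standards limit ≤ 12%)
    c16_c18_pct: float  # chain length 16–18, the diesel-range fraction
    adu: float  # Σ N·Mf with Mf on the 0–1 scale

    @property
    def total(self) -> float:
        return self.sfa_pct + self.mufa_pct + self.pufa_pct


def class_summary(profile: FameProfile, renormalize: bool = False) -> FaClassSummary:
    """Summarize a profile into SFA/MUFA/PUFA classes and the ADU.

    Parameters
    ----------
    profile
        The FAME profile to summarize.
    renormalize
        When True, fractions are first rescaled to a 100% total; by default
        the raw percentages are used, so a column summing to 99.2 yields
        class totals summing to 99.2.

    Notes
    -----
    ADU uses mass fractions on the 0–1 scale (Mf = percentage/100), so a
    pure C18:1 profile has ADU exactly 1. Db≥4 counts species with four or
    more double bonds literally; the C18:3 total is reported separately for
    the standards limit on linolenate.
    """
    p = profile.normalize() if renormalize else profile
    sfa = mufa = pufa = db4 = c18_3 = c16_18 = adu = 0.0
    for fa, pct in p.fractions.items():
        n = fa.double_bonds
        if n == 0:
            sfa += pct
        elif n == 1:
            mufa += pct
        else:
            pufa += pct
        if n >= 4:
            db4 += pct
        if fa.carbons == 18 and n == 3:
            c18_3 += pct
        if 16 <= fa.carbons <= 18:
            c16_18 += pct
        adu += n * pct / 100.0
    return FaClassSummary(
        strain_id=p.strain_id,
        sfa_pct=sfa,
        mufa_pct=mufa,
        pufa_pct=pufa,
        db4plus_pct=db4,
        c18_3_pct=c18_3,
        c16_c18_pct=c16_18,
        adu=adu,
    )


def load_profiles(
    source: str | Path | io.IOBase,
    sep: str | None = None,
    nd_markers: Sequence[str] = ND_MARKERS,
    total_gate: tuple[float, float] | None = TOTAL_GATE,
) -> list[FameProfile]:
    """Load FAME profiles from a delimited table (first column = FA labels).

    The delimiter is auto-detected unless ``sep`` is given. Not-detected
    markers (``–``, ``-``, empty, ``ND``) map to 0.0. Each strain column
    becomes one :class:`FameProfile`.

    Raises
    ------
    ProfileValidationError
        On duplicate fatty-acid labels, negative cells, or a per-strain
        total outside ``total_gate`` (pass ``None`` to skip the gate).
    """
    df = pd.read_csv(source, sep=sep, engine="python", dtype=str)
    if df.shape[1] < 2:
        raise ProfileValidationError("profile table needs an FA column and ≥1 strain")
    fa_labels = df.iloc[:, 0].tolist()
    fas = [parse_fa_name(lbl) for lbl in fa_labels]
    seen: set[FattyAcid] = set()
    for fa in fas:
        if fa in seen:
            raise ProfileValidationError(f"duplicate fatty-acid label: {fa.label}")
        seen.add(fa)

    nd = {m.strip().lower() for m in nd_markers}
    profiles: list[FameProfile] = []
    for strain in df.columns[1:]:
        fractions: dict[FattyAcid, float] = {}
        for fa, raw in zip(fas, df[strain]):
            cell = "" if pd.isna(raw) else str(raw).strip()
            if cell.lower() in nd:
                value = 0.0
            else:
                try:
                    value = float(cell)
                except ValueError as exc:
                    raise ProfileValidationError(
                        f"{strain}/{fa.label}: unreadable cell {cell!r}"
                    ) from exc
            if value < 0:
                raise ProfileValidationError(
                    f"{strain}/{fa.label}: negative percentage {value}"
                )
            if value != 0.0:
                fractions[fa] = value
        prof = FameProfile(strain_id=str(strain), fractions=fractions)
        if total_gate is not None:
            lo, hi = total_gate
            if not lo <= prof.total <= hi:
                raise ProfileValidationError(
                    f"strain {strain}: total {prof.total:.2f} outside [{lo}, {hi}]"
                )
        profiles.append(prof)
    return profiles


def summaries_frame(
    profiles: Iterable[FameProfile], renormalize: bool = False
) -> pd.DataFrame:
    """Tidy per-strain summary table (strain, sfa, mufa, pufa, db4plus, adu...)."""
    rows = []
    for prof in profiles:
        s = class_summary(prof, renormalize=renormalize)
        rows.append(
            {
                "strain": s.strain_id,
                "sfa_pct": s.sfa_pct,
                "mufa_pct": s.mufa_pct,
                "pufa_pct": s.pufa_pct,
                "db4plus_pct": s.db4plus_pct,
                "c18_3_pct": s.c18_3_pct,
                "c16_c18_pct": s.c16_c18_pct,
                "adu": s.adu,
                "total_pct": prof.total,
            }
        )
    return pd.DataFrame(rows)
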