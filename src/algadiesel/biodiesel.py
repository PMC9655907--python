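"""Biodiesel fuel-property estimation from FAME composition.

Fuel properties of a microalgal biodiesel are estimated from two descriptors
of the FAME profile:

* ADU, the average degree of unsaturation (Σ double-bonds × mass fraction),
  which drives the empirical linear regressions

  .. math::

     KV  = -0.6313\\,ADU + 5.2065 \\qquad (mm^2/s)\\\\
     ρ   =  0.0055\\,ADU + 0.8726 \\qquad (g/cm^3)\\\\
     CP  = -3.356\\,ADU + 19.994 \\qquad (°C)\\\\
     CN  = -6.6684\\,ADU + 62.876\\\\
     IV  =  74.373\\,ADU + 12.71  \\qquad (g\\,I_2/100\\,g)\\\\
     HHV =  1.7601\\,ADU + 38.534 \\qquad (MJ/kg)

* LCSF, the long-chain saturated factor — a weighted sum of the C16–C24
  saturated FA percentages — which predicts the cold filter plugging point,
  CFPP = 3.1417·LCSF − 16.477 (°C).

Estimates are screened against the ASTM D6751 and EN 14214 biodiesel
standards shipped with the package (``data/standards.json``).

Caveats surfaced as structured flags on every report: the cloud-point
regression is not validated against measured cloud points for this strain
panel, and an ADU recomputed from a profile can disagree with a published
ADU for the same strain; both situations are flagged, never silently
reconciled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from .fa_profile import FaClassSummary, FameProfile, parse_fa_name

__all__ = [
    "BiodieselProperties",
    "StandardsSpec",
    "Limit",
    "ComplianceReport",
    "estimate_properties",
    "compute_lcsf",
    "check_compliance",
    "load_standards",
    "available_standards",
    "CP_NOT_VALIDATED_FLAG",
    "ADU_MISMATCH_FLAG",
]

# Linear regression coefficients (slope, intercept) on ADU.
REGRESSIONS: Mapping[str, tuple[float, float]] = {
    "kv": (-0.6313, 5.2065),
    "density": (0.0055, 0.8726),
    "cp": (-3.356, 19.994),
    "cn": (-6.6684, 62.876),
    "iv": (74.373, 12.71),
    "hhv": (1.7601, 38.534),
}

# CFPP on LCSF.
CFPP_SLOPE, CFPP_INTERCEPT = 3.1417, -16.477

# LCSF weights per saturated species: {carbons: weight}. The five-term form
# (including 1.5×C22:0) is the default; the four-term variant drops C22:0.
LCSF_WEIGHTS_FIVE: Mapping[int, float] = {16: 0.1, 18: 0.5, 20: 1.0, 22: 1.5, 24: 2.0}
LCSF_WEIGHTS_FOUR: Mapping[int, float] = {16: 0.1, 18: 0.5, 20: 1.0, 24: 2.0}

CP_NOT_VALIDATED_FLAG = (
    "cloud_point_regression_not_validated: CP from the ADU regression is not "
    "reconciled with measured cloud points; interpret with caution"
)
ADU_MISMATCH_FLAG = (
    "adu_source_mismatch: supplied ADU differs from the profile-derived ADU "
    "by more than 0.05; supplied value used"
)


@dataclass(frozen=True)
class BiodieselProperties:
    """Estimated fuel properties for one strain's FAME profile."""

    strain_id: str
    adu: float
    kv: float  # kinematic viscosity at 40 °C, mm²/s
    density: float  # g/cm³
    cp: float  # cloud point, °C
    cn: float  # cetane number
    iv: float  # iodine value, g I₂/100 g oil
    hhv: float  # higher heating value, MJ/kg
    lcsf: float  # long-chain saturated factor, wt%
    cfpp: float  # cold filter plugging point, °C
    db4plus_pct: float = 0.0
    c18_3_pct: float = 0.0
    adu_source: str = "supplied"  # "supplied" or "profile"
    flags: tuple[str, ...] = ()

    def as_dict(self, ndigits: int | None = 2) -> dict:
        """Serializable mapping; values rounded to ``ndigits`` (None = full)."""
        num = {
            k: getattr(self, k)
            for k in (
                "adu", "kv", "density", "cp", "cn", "iv", "hhv",
                "lcsf", "cfpp", "db4plus_pct", "c18_3_pct",
            )
        }
        if ndigits is not None:
            num = {k: round(v, ndigits) for k, v in num.items()}
        return {
            "strain": self.strain_id,
            **num,
            "adu_source": self.adu_source,
            "flags": list(self.flags),
        }


def estimate_properties(
    adu: float,
    lcsf: float,
    extras: FaClassSummary | None = None,
    strain_id: str | None = None,
    adu_source: str = "supplied",
) -> BiodieselProperties:
    """Apply the property regressions at the given ADU and LCSF.

    ``extras`` (a class summary) supplies the Db≥4 and C18:3 percentages
    carried through for standards compliance, and triggers an
    ``adu_source_mismatch`` flag when its profile-derived ADU disagrees with
    the supplied one by more than 0.05. Full precision is retained; rounding
    happens only at serialization.
    """
    if adu < 0:
        raise ValueError(f"ADU must be non-negative, got {adu}")
    if lcsf < 0:
        raise ValueError(f"LCSF must be non-negative, got {lcsf}")
    vals = {k: m * adu + b for k, (m, b) in REGRESSIONS.items()}
    flags = [CP_NOT_VALIDATED_FLAG]
    db4 = c18_3 = 0.0
    if extras is not None:
        db4, c18_3 = extras.db4plus_pct, extras.c18_3_pct
        if adu_source == "supplied" and abs(extras.adu - adu) > 0.05:
            flags.append(ADU_MISMATCH_FLAG)
    return BiodieselProperties(
        strain_id=strain_id or (extras.strain_id if extras else ""),
        adu=adu,
        lcsf=lcsf,
        cfpp=CFPP_SLOPE * lcsf + CFPP_INTERCEPT,
        db4plus_pct=db4,
        c18_3_pct=c18_3,
        adu_source=adu_source,
        flags=tuple(flags),
        **vals,
    )


def compute_lcsf(profile: FameProfile, five_term: bool = True) -> float:
    """Long-chain saturated factor (wt%) from a profile.

    LCSF = 0.1·C16:0 + 0.5·C18:0 + 1.0·C20:0 + 1.5·C22:0 + 2.0·C24:0, with
    missing species contributing 0. ``five_term=False`` drops the C22:0
    term.
    """
    weights = LCSF_WEIGHTS_FIVE if five_term else LCSF_WEIGHTS_FOUR
    return sum(
        w * profile[f"C{c}:0"] for c, w in weights.items()
    )


@dataclass(frozen=True)
class Limit:
    """One standard's interval for a property; an absent bound is unbounded."""

    lower: float | None = None
    upper: float | None = None
    lower_open: bool = False
    upper_open: bool = False

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise ValueError("a limit needs at least one finite bound")

    def contains(self, value: float) -> bool:
        if self.lower is not None:
            if value < self.lower or (self.lower_open and value == self.lower):
                return False
        if self.upper is not None:
            if value > self.upper or (self.upper_open and value == self.upper):
                return False
        return True

    def __str__(self) -> str:
        if self.lower is not None and self.upper is not None:
            return f"{self.lower}–{self.upper}"
        if self.lower is not None:
            return (">" if self.lower_open else "≥") + f" {self.lower}"
        return ("<" if self.upper_open else "≤") + f" {self.upper}"


@dataclass(frozen=True)
class StandardsSpec:
    """A named biodiesel standard: property → interval."""

    name: str
    limits: Mapping[str, Limit] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "limits", dict(self.limits))


@dataclass(frozen=True)
class ComplianceReport:
    """Per-property verdicts of one property set against one standard."""

    strain_id: str
    standard: str
    verdicts: Mapping[str, str]  # property → "pass" | "fail" | "not-limited"

    @property
    def overall(self) -> str:
        """"pass" iff every limited property passes."""
        return (
            "pass"
            if all(v != "fail" for v in self.verdicts.values())
            else "fail"
        )

    def as_dict(self) -> dict:
        return {
            "strain": self.strain_id,
            "standard": self.standard,
            "verdicts": dict(self.verdicts),
            "overall": self.overall,
        }


_CHECKABLE = (
    "kv", "cn", "iv", "cp", "density", "hhv", "cfpp", "db4plus_pct", "c18_3_pct",
)


def check_compliance(props: BiodieselProperties, spec: StandardsSpec) -> ComplianceReport:
    """Compare estimated properties against one standard.

    Closed bounds pass on equality (``≥``/``≤`` semantics); open bounds
    (e.g. the ASTM cloud-point ``> 4``) fail on it. Properties the standard
    does not limit are reported ``"not-limited"`` and never affect the
    overall verdict. Full-precision values are compared, not the rounded
    serialization.
    """
    unknown = set(spec.limits) - set(_CHECKABLE)
    if unknown:
        raise KeyError(
            f"standard {spec.name!r} limits unknown properties: {sorted(unknown)}"
        )
    verdicts = {}
    for prop in _CHECKABLE:
        limit = spec.limits.get(prop)
        if limit is None:
            verdicts[prop] = "not-limited"
        else:
            verdicts[prop] = "pass" if limit.contains(getattr(props, prop)) else "fail"
    return ComplianceReport(
        strain_id=props.strain_id, standard=spec.name, verdicts=verdicts
    )


def _standards_payload(source: str | None = None) -> dict:
    if source is None:
        text = (
            resources.files("algadiesel.data").joinpath("standards.json").read_text()
        )
    else:
        with open(source) as fh:
            text = fh.read()
    return json.loads(text)


def available_standards(source: str | None = None) -> list[str]:
    return sorted(_standards_payload(source)["standards"])


def load_standards(name: str, source: str | None = None) -> StandardsSpec:
    """Load a named standard from the packaged (or a user) JSON spec file."""
    payload = _standards_payload(source)["standards"]
    if name not in payload:
        raise KeyError(
            f"unknown standard {name!r}; available: {sorted(payload)}"
        )
    limits = {
        prop: Limit(
            lower=entry.get("lower"),
            upper=entry.get("upper"),
            lower_open=entry.get("lower_open", False),
            upper_open=entry.get("upper_open", False),
        )
        for prop, entry in payload[name].items()
    }
    return StandardsSpec(name=name, limits=limits)
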