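"""Packaged reference datasets for the wild strain (WS) and plasma mutants.

Three small tables accompany the package, transcribed from published
measurements on a marine *Parachlorella kessleri* strain panel (wild strain
WS plus five plasma-mutagenesis mutants M1, M2, M4, M5, M8):

* ``fame_profiles.csv`` — relative FAME percentages per strain; a dash
  marks species below detection;
* ``reference_properties.csv`` — the published ADU/LCSF descriptors and
  fuel-property estimates per strain (2-decimal rounding as printed);
* ``composition_pct_dw.csv`` — protein/carbohydrate/lipid contents in %DW
  at the late exponential phase.
"""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd

from .fa_profile import FameProfile, load_profiles

__all__ = [
    "load_fame_profiles",
    "load_reference_properties",
    "load_composition",
    "STRAINS",
]

STRAINS = ("WS", "M1", "M2", "M4", "M5", "M8")


def _read(name: str) -> str:
    return resources.files("algadiesel.data").joinpath(name).read_text(encoding="utf-8")


def load_fame_profiles() -> list[FameProfile]:
    """The packaged strain-panel FAME profiles (WS, M1, M2, M4, M5, M8)."""
    return load_profiles(io.StringIO(_read("fame_profiles.csv")), sep=",")


def load_reference_properties() -> pd.DataFrame:
    """Published per-strain ADU, LCSF and fuel-property values (indexed by strain)."""
    return pd.read_csv(io.StringIO(_read("reference_properties.csv"))).set_index("strain")


def load_composition() -> pd.DataFrame:
    """Published protein/carbohydrate/lipid contents (%DW), indexed by strain."""
    return pd.read_csv(io.StringIO(_read("composition_pct_dw.csv"))).set_index("strain")
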