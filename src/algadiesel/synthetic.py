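"""Synthetic data generators with known ground truth for every pipeline stage.

Each generator emulates the shape of one kind of raw measurement in a
plasma-mutagenesis / lipid-screening study of a marine microalga:

* batch growth curves — a 2-day lag, an exponential phase to about day
  16–18, then a stationary plateau, with multiplicative log-normal noise;
* dose–mortality tables — sigmoid survival in exposure time with binomial
  colony-count noise;
* mutant screen records — growth/lipid fold-changes drawn around the wild
  strain;
* compositional FAME profiles — Dirichlet jitter around a packaged strain
  archetype, keeping not-detected species at zero;
* assay readings — linear standard curves plus Gaussian signal noise.

Every generator takes a frozen config carrying its own seed and builds one
``numpy.random.default_rng`` per call, so outputs are reproducible in
isolation and in any order, and returns the ground-truth parameters next to
the data.

The growth trajectory is piecewise (lag / exact exponential / plateau)
rather than logistic: a logistic's log-slope is µ(1 − x/K), which at the
realistic inoculum-to-capacity ratios simulated here (0.025 → 0.65 g/L)
biases any finite-window µ estimate several percent low. The piecewise form
matches the lag/log/stationary phenomenology being emulated and keeps µ
identifiable from the log phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fa_profile import FaClassSummary, FameProfile, class_summary
from .growth import GrowthSeries, OdDwCalibration
from .screening import MutantScreenRecord, ScreeningTable

__all__ = [
    "GrowthSimConfig",
    "MortalitySimConfig",
    "ScreenSimConfig",
    "FameSimConfig",
    "AssaySimConfig",
    "gen_growth_curve",
    "gen_mortality_table",
    "gen_screen_records",
    "gen_fame_profiles",
    "gen_assay_readings",
]


@dataclass(frozen=True)
class GrowthSimConfig:
    """Batch growth-curve generator settings (units: g/L, days)."""

    seed: int = 0
    dw0: float = 0.025  # inoculum, 25 mg DW in 1 L
    carrying_capacity: float = 0.65  # stationary-phase biomass
    mu_true: float = 0.20  # day⁻¹
    lag_days: float = 2.0
    noise_sd: float = 0.05  # sd of log-normal multiplicative noise
    t_end: float = 20.0
    dt: float = 2.0  # sampling every couple of days
    od_per_gL: float = 1.0 / 0.24  # OD₆₈₀ units per g/L dry weight

    def __post_init__(self) -> None:
        if min(self.dw0, self.carrying_capacity, self.mu_true, self.dt) <= 0:
            raise ValueError("scale parameters must be positive")


def _piecewise_dw(t: np.ndarray, cfg: GrowthSimConfig) -> np.ndarray:
    tau = np.clip(t - cfg.lag_days, 0.0, None)
    return np.minimum(cfg.carrying_capacity, cfg.dw0 * np.exp(cfg.mu_true * tau))


def gen_growth_curve(cfg: GrowthSimConfig) -> tuple[GrowthSeries, dict]:
    """One strain's growth series plus ground truth.

    Truth includes ``mu_true`` and the OD calibration used, so parameter-
    recovery tests can compare estimates against the generating values.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, cfg.t_end + cfg.dt / 2, cfg.dt)
    dw_clean = _piecewise_dw(t, cfg)
    noise = np.exp(rng.normal(0.0, cfg.noise_sd, size=t.shape)) if cfg.noise_sd else 1.0
    dw = dw_clean * noise
    od = dw * cfg.od_per_gL
    series = GrowthSeries(
        strain_id=f"sim{cfg.seed}", time_days=t, od680=od, dw_gL=dw
    )
    truth = {
        "mu_true": cfg.mu_true,
        "lag_days": cfg.lag_days,
        "carrying_capacity": cfg.carrying_capacity,
        "dw_clean": dw_clean,
        "log_window_days": (cfg.lag_days, min(16.0, cfg.t_end)),
        "calibration": OdDwCalibration(
            slope=1.0 / cfg.od_per_gL, intercept=0.0, r2=1.0
        ),
    }
    return series, truth


@dataclass(frozen=True)
class MortalitySimConfig:
    """Dose–mortality generator: sigmoid survival with binomial counts.

    Defaults reproduce the screening regime being emulated: ~97% expected
    mortality at 40 s (≈9 surviving colonies out of 319 controls), full
    lethality beyond.
    """

    seed: int = 0
    exposures_s: Sequence[float] = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
    t50_s: float = 33.0  # exposure at 50% survival
    steepness: float = 0.5  # per-second logistic slope
    control_colonies: int = 319

    def __post_init__(self) -> None:
        if self.t50_s <= 0 or self.steepness <= 0 or self.control_colonies <= 0:
            raise ValueError("scale parameters must be positive")


def survival_prob(t: np.ndarray | float, cfg: MortalitySimConfig) -> np.ndarray | float:
    """Noise-free survival fraction 1/(1 + exp(steepness·(t − t50)))."""
    return 1.0 / (1.0 + np.exp(cfg.steepness * (np.asarray(t, float) - cfg.t50_s)))


def designed_dose(cfg: MortalitySimConfig, threshold: float = 95.0) -> float | None:
    """Dose the generator is built to make optimal, from expectations alone.

    Smallest grid exposure whose expected mortality reaches ``threshold``
    while the expected surviving colony count is at least 1.
    """
    for t in sorted(cfg.exposures_s):
        p = float(survival_prob(t, cfg))
        if (1 - p) * 100.0 >= threshold and cfg.control_colonies * p >= 1.0:
            return t
    return None


def gen_mortality_table(cfg: MortalitySimConfig) -> tuple[ScreeningTable, dict]:
    """Colony counts per exposure with binomial sampling noise."""
    rng = np.random.default_rng(cfg.seed)
    exposures = sorted(cfg.exposures_s)
    p = np.asarray(survival_prob(np.asarray(exposures), cfg))
    treated = rng.binomial(cfg.control_colonies, p)
    table = ScreeningTable(
        exposures_s=list(exposures),
        treated=[int(x) for x in treated],
        control=[cfg.control_colonies] * len(exposures),
    )
    truth = {
        "expected_mortality_pct": (1 - p) * 100.0,
        "designed_dose_s": designed_dose(cfg),
        "t50_s": cfg.t50_s,
        "steepness": cfg.steepness,
    }
    return table, truth


@dataclass(frozen=True)
class ScreenSimConfig:
    """Mutant screen generator: trait folds drawn around the wild strain."""

    seed: int = 0
    n_mutants: int = 15
    wild_od: float = 0.80
    wild_mu: float = 0.20  # day⁻¹
    wild_lipid_gL: float = 0.22
    log_fold_mean: float = 0.05  # mean of ln(fold) for both traits
    log_fold_sd_growth: float = 0.30
    log_fold_sd_lipid: float = 0.15


def gen_screen_records(
    cfg: ScreenSimConfig,
) -> tuple[list[MutantScreenRecord], MutantScreenRecord, dict]:
    """Mutant records plus the wild reference and the true folds."""
    rng = np.random.default_rng(cfg.seed)
    wild = MutantScreenRecord(
        strain_id="WS",
        od_day10=cfg.wild_od,
        growth_rate=cfg.wild_mu,
        lipid_gL=cfg.wild_lipid_gL,
    )
    fg = np.exp(rng.normal(cfg.log_fold_mean, cfg.log_fold_sd_growth, cfg.n_mutants))
    fl = np.exp(rng.normal(cfg.log_fold_mean, cfg.log_fold_sd_lipid, cfg.n_mutants))
    records = [
        MutantScreenRecord(
            strain_id=f"M{i + 1}",
            od_day10=cfg.wild_od * fg[i],
            growth_rate=cfg.wild_mu * fg[i],
            lipid_gL=cfg.wild_lipid_gL * fl[i],
        )
        for i in range(cfg.n_mutants)
    ]
    truth = {"fold_growth": fg, "fold_lipid": fl}
    return records, wild, truth


@dataclass(frozen=True)
class FameSimConfig:
    """Compositional FAME-profile generator (Dirichlet around an archetype)."""

    seed: int = 0
    archetype: str = "WS"  # strain column of the packaged profile panel
    concentration: float = 500.0  # Dirichlet precision; ∞ → archetype exactly
    n_profiles: int = 1

    def __post_init__(self) -> None:
        if self.concentration <= 0 or self.n_profiles <= 0:
            raise ValueError("concentration and n_profiles must be positive")


def gen_fame_profiles(cfg: FameSimConfig) -> tuple[list[FameProfile], dict]:
    """Profiles jittered around a packaged archetype, each summing to 100.

    Only detected (nonzero) archetype species get jitter; zeros stay zero,
    respecting not-detected semantics. The truth is the class summary of
    the normalized archetype.
    """
    from .datasets import load_fame_profiles  # local import to avoid cycle

    panel = {p.strain_id: p for p in load_fame_profiles()}
    if cfg.archetype not in panel:
        raise KeyError(
            f"unknown archetype {cfg.archetype!r}; available: {sorted(panel)}"
        )
    base = panel[cfg.archetype].normalize()
    species = sorted(base.fractions)
    frac = np.array([base.fractions[fa] for fa in species]) / 100.0
    rng = np.random.default_rng(cfg.seed)
    if np.isfinite(cfg.concentration):
        draws = rng.dirichlet(cfg.concentration * frac, size=cfg.n_profiles)
    else:
        draws = np.tile(frac, (cfg.n_profiles, 1))
    profiles = [
        FameProfile(
            strain_id=f"{cfg.archetype}_sim{cfg.seed}_{i}",
            fractions={fa: 100.0 * v for fa, v in zip(species, row) if v > 0},
        )
        for i, row in enumerate(draws)
    ]
    truth = {"archetype_summary": class_summary(base), "archetype": base}
    return profiles, truth


@dataclass(frozen=True)
class AssaySimConfig:
    """Standard-curve assay generator: signal = slope·conc + intercept + ε."""

    seed: int = 0
    analyte: str = "lipid_SPV"
    slope: float = 0.012  # absorbance per µg/mL
    intercept: float = 0.02
    noise_sd: float = 0.005
    standard_concs: Sequence[float] = (0.0, 25.0, 50.0, 100.0, 200.0)
    true_concs: Sequence[float] = (40.0, 80.0, 150.0)

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be nonzero")


def gen_assay_readings(cfg: AssaySimConfig) -> tuple[dict, dict]:
    """Standard-curve points and sample readings with known concentrations.

    Signals are clamped at 0 (a spectrophotometer cannot read negative
    absorbance); clamped indices are flagged in the output.
    """
    rng = np.random.default_rng(cfg.seed)

    def _signals(concs: np.ndarray) -> tuple[np.ndarray, list[int]]:
        clean = cfg.slope * concs + cfg.intercept
        noisy = clean + (
            rng.normal(0.0, cfg.noise_sd, size=concs.shape) if cfg.noise_sd else 0.0
        )
        clamped = [int(i) for i in np.nonzero(noisy < 0)[0]]
        return np.maximum(noisy, 0.0), clamped

    std_concs = np.asarray(cfg.standard_concs, float)
    samp_concs = np.asarray(cfg.true_concs, float)
    std_sig, std_clamped = _signals(std_concs)
    samp_sig, samp_clamped = _signals(samp_concs)
    data = {
        "standards": list(zip(std_concs.tolist(), std_sig.tolist())),
        "readings": [
            {"sample_id": f"s{i}", "signal": float(sig)}
            for i, sig in enumerate(samp_sig)
        ],
        "clamped_standard_idx": std_clamped,
        "clamped_reading_idx": samp_clamped,
        "analyte": cfg.analyte,
    }
    truth = {
        "slope": cfg.slope,
        "intercept": cfg.intercept,
        "true_concs": samp_concs.tolist(),
    }
    return data, truth
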