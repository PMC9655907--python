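"""Generators: determinism, noiseless limits, and ground-truth recovery."""

import numpy as np
import pytest

from algadiesel.assays import fit_standard_curve, invert
from algadiesel.fa_profile import class_summary
from algadiesel.growth import estimate_mu, fit_calibration, productivity
from algadiesel.screening import rank_mutants, select_exposure
from algadiesel.synthetic import (
    AssaySimConfig,
    FameSimConfig,
    GrowthSimConfig,
    MortalitySimConfig,
    ScreenSimConfig,
    designed_dose,
    gen_assay_readings,
    gen_fame_profiles,
    gen_growth_curve,
    gen_mortality_table,
    gen_screen_records,
    survival_prob,
)


class TestGrowthGenerator:
    def test_same_seed_identical_series(self):
        a, _ = gen_growth_curve(GrowthSimConfig(seed=42))
        b, _ = gen_growth_curve(GrowthSimConfig(seed=42))
        assert np.array_equal(a.dw_gL, b.dw_gL)
        assert np.array_equal(a.od680, b.od680)

    def test_different_seed_differs(self):
        a, _ = gen_growth_curve(GrowthSimConfig(seed=1))
        b, _ = gen_growth_curve(GrowthSimConfig(seed=2))
        assert not np.array_equal(a.dw_gL, b.dw_gL)

    def test_noiseless_log_phase_recovers_mu_exactly(self):
        cfg = GrowthSimConfig(seed=0, noise_sd=0.0)
        series, truth = gen_growth_curve(cfg)
        mu = estimate_mu(series, window=truth["log_window_days"])
        assert mu == pytest.approx(cfg.mu_true, rel=0.02)

    def test_noiseless_bp_matches_analytic_mean_rate(self):
        cfg = GrowthSimConfig(seed=0, noise_sd=0.0)
        series, truth = gen_growth_curve(cfg)
        t = np.asarray(series.time_days)
        dw = np.asarray(series.dw_gL)
        lo, hi = truth["log_window_days"]
        i0, i1 = int(np.argmin(np.abs(t - lo))), int(np.argmin(np.abs(t - hi)))
        res = productivity(dw_window=(t[i0], dw[i0], t[i1], dw[i1]))
        analytic = (dw[i1] - dw[i0]) / (t[i1] - t[i0])
        assert res.bp == pytest.approx(analytic, rel=0.05)

    def test_mu_recovery_median_within_five_percent(self):
        """100 noisy replicates at µ=0.20: median estimate within 5%."""
        estimates = []
        for seed in range(100):
            series, truth = gen_growth_curve(GrowthSimConfig(seed=seed, noise_sd=0.05))
            estimates.append(estimate_mu(series, window=truth["log_window_days"]))
        assert np.median(estimates) == pytest.approx(0.20, rel=0.05)

    def test_plateau_at_carrying_capacity(self):
        cfg = GrowthSimConfig(seed=0, noise_sd=0.0, t_end=40.0)
        series, _ = gen_growth_curve(cfg)
        assert series.dw_gL[-1] == pytest.approx(cfg.carrying_capacity)


class TestMortalityGenerator:
    def test_expected_mortality_at_t50_is_fifty(self):
        cfg = MortalitySimConfig()
        assert survival_prob(cfg.t50_s, cfg) == pytest.approx(0.5)

    def test_large_steepness_is_a_step(self):
        cfg = MortalitySimConfig(steepness=100.0, t50_s=33.0)
        assert survival_prob(32.0, cfg) == pytest.approx(1.0, abs=1e-10)
        assert survival_prob(34.0, cfg) == pytest.approx(0.0, abs=1e-10)

    def test_designed_dose_is_forty_seconds(self):
        assert designed_dose(MortalitySimConfig()) == 40.0

    def test_same_seed_identical_counts(self):
        a, _ = gen_mortality_table(MortalitySimConfig(seed=5))
        b, _ = gen_mortality_table(MortalitySimConfig(seed=5))
        assert a.treated == b.treated

    def test_selected_dose_matches_design_in_most_seeds(self):
        """select_exposure lands on the designed dose in ≥90% of 200 seeds."""
        cfg0 = MortalitySimConfig()
        target = designed_dose(cfg0)
        hits = 0
        for seed in range(200):
            table, _ = gen_mortality_table(MortalitySimConfig(seed=seed))
            if select_exposure(table, threshold=95.0) == target:
                hits += 1
        assert hits >= 180


class TestScreenGenerator:
    def test_folds_recorded_as_truth(self):
        records, wild, truth = gen_screen_records(ScreenSimConfig(seed=3))
        assert len(records) == 15
        for rec, fg, fl in zip(records, truth["fold_growth"], truth["fold_lipid"]):
            assert rec.growth_rate / wild.growth_rate == pytest.approx(fg)
            assert rec.lipid_gL / wild.lipid_gL == pytest.approx(fl)

    def test_ranking_consistent_with_truth(self):
        records, wild, truth = gen_screen_records(ScreenSimConfig(seed=3))
        picked = rank_mutants(records, wild, k=5)
        both_beat = (truth["fold_growth"] > 1) & (truth["fold_lipid"] > 1)
        assert len(picked) == min(5, int(both_beat.sum()))


class TestFameGenerator:
    def test_draws_sum_to_hundred(self):
        profiles, _ = gen_fame_profiles(FameSimConfig(seed=1, n_profiles=20))
        for p in profiles:
            assert p.total == pytest.approx(100.0, abs=1e-9)

    def test_infinite_concentration_returns_archetype(self):
        profiles, truth = gen_fame_profiles(
            FameSimConfig(seed=0, concentration=float("inf"))
        )
        arch = truth["archetype"]
        assert profiles[0].fractions == pytest.approx(arch.fractions)

    def test_zero_species_stay_zero(self):
        profiles, truth = gen_fame_profiles(FameSimConfig(seed=2, n_profiles=10))
        arch = truth["archetype"]
        for p in profiles:
            assert set(p.fractions) <= set(arch.fractions)

    def test_mean_class_summary_near_archetype(self):
        """Averaged over many draws, class totals sit within 1% of the archetype."""
        profiles, truth = gen_fame_profiles(FameSimConfig(seed=7, n_profiles=500))
        sfa = np.mean([class_summary(p).sfa_pct for p in profiles])
        pufa = np.mean([class_summary(p).pufa_pct for p in profiles])
        ref = truth["archetype_summary"]
        assert sfa == pytest.approx(ref.sfa_pct, abs=1.0)
        assert pufa == pytest.approx(ref.pufa_pct, abs=1.0)

    def test_unknown_archetype_rejected(self):
        with pytest.raises(KeyError):
            gen_fame_profiles(FameSimConfig(archetype="M99"))


class TestAssayGenerator:
    def test_noiseless_inversion_is_exact(self):
        data, truth = gen_assay_readings(AssaySimConfig(seed=0, noise_sd=0.0))
        curve = fit_standard_curve(data["standards"])
        for reading, conc in zip(data["readings"], truth["true_concs"]):
            assert invert(curve, reading["signal"]).concentration == pytest.approx(conc)

    def test_noisy_recovery_within_ten_percent(self):
        data, truth = gen_assay_readings(AssaySimConfig(seed=4))
        curve = fit_standard_curve(data["standards"])
        for reading, conc in zip(data["readings"], truth["true_concs"]):
            assert invert(curve, reading["signal"]).concentration == pytest.approx(
                conc, rel=0.10
            )

    def test_signals_never_negative_and_clamps_flagged(self):
        cfg = AssaySimConfig(seed=1, slope=0.001, intercept=0.0, noise_sd=0.5)
        data, _ = gen_assay_readings(cfg)
        signals = [s for _, s in data["standards"]]
        assert min(signals) >= 0.0
        assert len(data["clamped_standard_idx"]) > 0  # huge noise must clamp some


def test_full_pipeline_smoke_from_one_seed():
    """Generate every input kind from one seed and run each downstream stage."""
    seed = 123
    series, gtruth = gen_growth_curve(GrowthSimConfig(seed=seed))
    mu = estimate_mu(series, window=gtruth["log_window_days"])
    assert mu == pytest.approx(gtruth["mu_true"], rel=0.25)

    table, mtruth = gen_mortality_table(MortalitySimConfig(seed=seed))
    dose = select_exposure(table, threshold=95.0)
    assert dose is None or dose in table.exposures_s

    records, wild, _ = gen_screen_records(ScreenSimConfig(seed=seed))
    picked = rank_mutants(records, wild, k=5)
    assert all(fl > 1 and fg > 1 for _, fg, fl in picked)

    profiles, ftruth = gen_fame_profiles(FameSimConfig(seed=seed, n_profiles=3))
    for p in profiles:
        s = class_summary(p)
        assert s.total == pytest.approx(p.total, abs=1e-9)

    data, atruth = gen_assay_readings(AssaySimConfig(seed=seed))
    curve = fit_standard_curve(data["standards"])
    assert curve.slope == pytest.approx(atruth["slope"], rel=0.25)

    # OD↔DW calibration from the simulated series round-trips
    cal = fit_calibration(zip(series.od680, series.dw_gL))
    assert cal.r2 > 0.95
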