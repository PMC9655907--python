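"""FAME label parsing, profile loading/validation, and class summaries."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from algadiesel.fa_profile import (
    FaParseError,
    FameProfile,
    FattyAcid,
    ProfileValidationError,
    class_summary,
    load_profiles,
    parse_fa_name,
)


@pytest.mark.parametrize(
    "label, carbons, db, omega",
    [
        ("C16:0", 16, 0, None),
        ("C18:1 (ω9)", 18, 1, 9),
        ("C18:1(ω9)", 18, 1, 9),
        ("C18:2 (w6)", 18, 2, 6),
        ("  C22:4 ( ω 6 ) ", 22, 4, 6),
    ],
)
def test_parse_fa_name_and_roundtrip(label, carbons, db, omega):
    fa = parse_fa_name(label)
    assert (fa.carbons, fa.double_bonds, fa.omega) == (carbons, db, omega)
    assert parse_fa_name(fa.label) == fa


@pytest.mark.parametrize("bad", ["palmitic", "C18", "18:1", "C18:1 (x9)", "C-2:0"])
def test_parse_rejects_malformed_labels(bad):
    with pytest.raises(FaParseError):
        parse_fa_name(bad)


def test_parse_rejects_chain_below_minimum():
    with pytest.raises(FaParseError, match="below minimum"):
        parse_fa_name("C0:0")


def test_odd_carbon_count_warns_but_parses():
    with pytest.warns(UserWarning, match="odd carbon"):
        fa = parse_fa_name("C17:0")
    assert fa.carbons == 17


def test_omega_isomers_are_distinct_keys():
    a, b = parse_fa_name("C18:1 (ω7)"), parse_fa_name("C18:1 (ω9)")
    bare = parse_fa_name("C18:1")
    assert len({a, b, bare}) == 3
    prof = FameProfile("x", {a: 30.0, b: 40.0, bare: 30.0})
    assert class_summary(prof).mufa_pct == pytest.approx(100.0)


class TestLoadProfiles:
    def test_packaged_panel_values(self, panel):
        ws = panel["WS"]
        assert ws["C18:2 (ω6)"] == pytest.approx(25.28)
        assert ws.total == pytest.approx(99.16)
        # dashes are zeros, not missing
        assert ws["C8:0"] == 0.0

    def test_single_row_table(self):
        profs = load_profiles(io.StringIO("FA,S1\nC16:0,100\n"))
        assert len(profs) == 1 and profs[0].total == pytest.approx(100.0)

    def test_duplicate_labels_rejected(self):
        src = "FA,S1\nC16:0,50\nC16:0,50\n"
        with pytest.raises(ProfileValidationError, match="duplicate"):
            load_profiles(io.StringIO(src))

    def test_negative_cell_rejected(self):
        with pytest.raises(ProfileValidationError, match="negative"):
            load_profiles(io.StringIO("FA,S1\nC16:0,-5\nC18:0,100\n"))

    def test_total_gate_names_strain_and_total(self):
        with pytest.raises(ProfileValidationError, match="S1.*50"):
            load_profiles(io.StringIO("FA,S1\nC16:0,50\n"))

    def test_nd_marker_aliases(self):
        src = "FA,S1\nC16:0,ND\nC18:0,-\nC18:1,100\n"
        profs = load_profiles(io.StringIO(src))
        assert profs[0].total == pytest.approx(100.0)

    def test_tab_delimiter_autodetected(self):
        profs = load_profiles(io.StringIO("FA\tS1\nC16:0\t100\n"))
        assert profs[0]["C16:0"] == 100.0


class TestNormalize:
    def test_scales_to_hundred(self):
        p = FameProfile("x", {parse_fa_name("C16:0"): 50.0})
        assert p.normalize()["C16:0"] == pytest.approx(100.0)
        assert p["C16:0"] == 50.0  # original unchanged

    def test_symmetry(self):
        p = FameProfile(
            "x", {parse_fa_name("C16:0"): 40.0, parse_fa_name("C18:1 (ω9)"): 40.0}
        )
        n = p.normalize()
        assert n["C16:0"] == pytest.approx(50.0)
        assert n["C18:1 (ω9)"] == pytest.approx(50.0)

    def test_idempotent(self):
        p = FameProfile("x", {parse_fa_name("C16:0"): 73.2}).normalize()
        assert p.normalize().total == pytest.approx(p.total, abs=1e-9)

    def test_zero_total_errors(self):
        with pytest.raises(ProfileValidationError):
            FameProfile("x", {}).normalize()


class TestClassSummary:
    def test_ws_pufa_matches_published(self, panel):
        s = class_summary(panel["WS"])
        assert s.pufa_pct == pytest.approx(35.90, abs=0.01)
        assert s.pufa_pct == pytest.approx(1.67 + 25.28 + 8.95)

    def test_pure_saturated_profile(self):
        s = class_summary(FameProfile("x", {parse_fa_name("C16:0"): 100.0}))
        assert (s.sfa_pct, s.mufa_pct, s.pufa_pct, s.adu) == (100.0, 0.0, 0.0, 0.0)

    def test_m8_adu_from_profile(self, panel):
        # 1×(0.49 + 2.73 + 35.39 + 0.58)/100 + 2×4.40/100
        assert class_summary(panel["M8"]).adu == pytest.approx(0.480, abs=0.001)

    def test_pure_oleate_adu_is_one(self):
        s = class_summary(FameProfile("x", {parse_fa_name("C18:1 (ω9)"): 100.0}))
        assert s.adu == pytest.approx(1.0)

    def test_renormalize_flag(self, panel):
        raw = class_summary(panel["WS"])
        renorm = class_summary(panel["WS"], renormalize=True)
        scale = 100.0 / panel["WS"].total
        assert renorm.pufa_pct == pytest.approx(raw.pufa_pct * scale)
        assert renorm.total == pytest.approx(100.0, abs=1e-9)


# ---------------------------------------------------------------------------
# property tests

_species = st.builds(
    FattyAcid,
    carbons=st.sampled_from([14, 16, 18, 20, 22, 24]),
    double_bonds=st.integers(0, 6),
    omega=st.none() | st.integers(3, 9),
)
_profiles = st.dictionaries(
    _species, st.floats(0.01, 60.0), min_size=1, max_size=10
).map(lambda d: FameProfile("rand", d))


@settings(max_examples=100, derandomize=True, deadline=None)
@given(_profiles)
def test_class_conservation(profile):
    """SFA + MUFA + PUFA equals the profile total, for any profile."""
    s = class_summary(profile)
    assert s.total == pytest.approx(profile.total, abs=1e-9)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(_profiles)
def test_scale_equivariance(profile):
    """Class percentages of the normalized profile are 100/total × the raw ones."""
    raw, norm = class_summary(profile), class_summary(profile.normalize())
    scale = 100.0 / profile.total
    for fieldname in ("sfa_pct", "mufa_pct", "pufa_pct", "db4plus_pct", "adu"):
        assert getattr(norm, fieldname) == pytest.approx(
            getattr(raw, fieldname) * scale, rel=1e-9, abs=1e-9
        )


@settings(max_examples=100, derandomize=True, deadline=None)
@given(_profiles)
def test_adu_bound(profile):
    """ADU cannot exceed max double-bond count × (total/100)."""
    s = class_summary(profile)
    max_db = max(fa.double_bonds for fa in profile.fractions)
    assert 0 <= s.adu <= max_db * profile.total / 100.0 + 1e-12
    if s.mufa_pct == 0 and s.pufa_pct == 0:
        assert s.adu == 0


@settings(max_examples=100, derandomize=True, deadline=None)
@given(_profiles)
def test_class_summary_matches_bruteforce(profile):
    """Oracle equivalence: an independent per-species loop gives the same sums."""
    sfa = sum(v for fa, v in profile.fractions.items() if fa.double_bonds == 0)
    mufa = sum(v for fa, v in profile.fractions.items() if fa.double_bonds == 1)
    pufa = sum(v for fa, v in profile.fractions.items() if fa.double_bonds >= 2)
    adu = sum(fa.double_bonds * v / 100 for fa, v in profile.fractions.items())
    s = class_summary(profile)
    assert s.sfa_pct == pytest.approx(sfa)
    assert s.mufa_pct == pytest.approx(mufa)
    assert s.pufa_pct == pytest.approx(pufa)
    assert s.adu == pytest.approx(adu)
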