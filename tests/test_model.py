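"""Closed-form model pieces: Pes regression, Pmax, coupling, EDV."""


import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edvcalc import (
    InvalidInputError,
    coupling_from_pressures,
    estimate_edv,
    estimate_pes,
    pmax_from_timings,
)
from edvcalc.model import PES_INTERCEPT, BeatObservation


class TestEstimatePes:
    @pytest.mark.parametrize(
        "sbp, dbp, expected",
        [
            (117.0, 73.0, 89.9604),  # cohort-mean cuff pressures
            (120.0, 80.0, 0.205 * 120 + 0.898 * 80 + 0.4214),
        ],
    )
    def test_linear_form(self, sbp, dbp, expected):
        assert estimate_pes(sbp, dbp) == pytest.approx(expected, abs=1e-12)

    def test_intercept_only_contract(self):
        # degenerate zero-pressure input, precondition deliberately disabled
        assert estimate_pes(0.0, 0.0, validate=False) == pytest.approx(PES_INTERCEPT)

    @pytest.mark.parametrize("sbp, dbp", [(100, 100), (90, 110), (120, -5), (120, 0)])
    def test_rejects_inverted_or_nonpositive(self, sbp, dbp):
        with pytest.raises(InvalidInputError):
            estimate_pes(sbp, dbp)

    @given(
        dbp=st.floats(40, 110),
        ratio=st.floats(1.35, 2.2),
    )
    def test_result_between_dbp_and_sbp(self, dbp, ratio):
        """End-systolic pressure falls between diastolic and systolic for
        physiological pulse pressures."""
        sbp = dbp * ratio
        pes = estimate_pes(sbp, dbp)
        assert dbp < pes < sbp

    @given(
        sbp=st.floats(80, 200),
        dbp=st.floats(40, 79),
        scale=st.floats(0.5, 2.0),
    )
    def test_affine_in_pressures(self, sbp, dbp, scale):
        base = estimate_pes(sbp, dbp) - PES_INTERCEPT
        scaled = estimate_pes(sbp * scale, dbp * scale) - PES_INTERCEPT
        assert scaled == pytest.approx(scale * base, rel=1e-12)


class TestPmax:
    @pytest.mark.parametrize(
        "pad, et, pep, k, expected",
        [
            (70.0, 300.0, 100.0, 0.53, 70 * (1 + 3 * 0.53)),  # = 181.3
            (70.0, 250.0, 80.0, 0.0, 70.0),  # k=0 collapses to Pad
            (70.0, 100.0, 100.0, 1.0, 140.0),  # ET/PEP=1, k=1 doubles Pad
        ],
    )
    def test_examples(self, pad, et, pep, k, expected):
        assert pmax_from_timings(pad, et, pep, k) == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_pep(self):
        with pytest.raises(InvalidInputError):
            pmax_from_timings(70, 300, 0, 0.53)
        with pytest.raises(InvalidInputError):
            pmax_from_timings(70, 300, -10, 0.53)

    @given(
        pad=st.floats(50, 100),
        et=st.floats(150, 450),
        pep=st.floats(60, 140),
        k=st.floats(0.1, 1.5),
        bump=st.floats(1e-3, 50),
    )
    def test_monotonicity(self, pad, et, pep, k, bump):
        base = pmax_from_timings(pad, et, pep, k)
        assert pmax_from_timings(pad + bump, et, pep, k) > base
        assert pmax_from_timings(pad, et + bump, pep, k) > base
        assert pmax_from_timings(pad, et, pep + bump, k) < base


class TestCouplingFromPressures:
    @pytest.mark.parametrize(
        "pmax, pes, expected",
        [
            (180.0, 90.0, 1.0),
            (90.0, 90.0, 0.0),  # no contractile reserve
            (181.3, 89.9604, 181.3 / 89.9604 - 1.0),  # chained from the above
        ],
    )
    def test_examples(self, pmax, pes, expected):
        assert coupling_from_pressures(pmax, pes) == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_pes(self):
        with pytest.raises(InvalidInputError):
            coupling_from_pressures(180, 0)


class TestEstimateEdv:
    def test_cohort_mean_stroke_volume(self):
        est = estimate_edv(61.0, 1.5)
        assert est.edv_calc == pytest.approx(61 * (1 + 1 / 1.5), abs=1e-12)
        assert est.esv_calc == pytest.approx(est.edv_calc - 61.0, abs=1e-12)

    def test_equal_elastances_double_sv(self):
        assert estimate_edv(50.0, 1.0).edv_calc == pytest.approx(100.0)

    def test_large_coupling_limit(self):
        # Ees/Ea -> inf drives ESV -> 0, EDV -> SV
        assert estimate_edv(50.0, 1e12).edv_calc == pytest.approx(50.0, rel=1e-9)

    def test_v0_offsets_volume(self):
        assert estimate_edv(50.0, 1.0, v0=10.0).edv_calc == pytest.approx(110.0)

    @pytest.mark.parametrize("ratio", [0.0, -1.0])
    def test_rejects_nonpositive_coupling(self, ratio):
        with pytest.raises(InvalidInputError):
            estimate_edv(50.0, ratio)

    @given(
        sv=st.floats(20, 120),
        ratio=st.floats(0.3, 4.0),
        bump=st.floats(1e-3, 2.0),
    )
    def test_decreasing_in_coupling(self, sv, ratio, bump):
        assert estimate_edv(sv, ratio + bump).edv_calc < estimate_edv(sv, ratio).edv_calc


class TestAlgebraicIdentities:
    @given(sv=st.floats(20, 120), ratio=st.floats(0.2, 5.0))
    def test_volume_round_trip(self, sv, ratio):
        """SV/(EDV−SV) recovers the coupling ratio exactly at V0 = 0."""
        edv = estimate_edv(sv, ratio).edv_calc
        assert sv / (edv - sv) == pytest.approx(ratio, rel=1e-12)

    @given(
        pad=st.floats(50, 100),
        pes=st.floats(60, 130),
        et=st.floats(150, 450),
        pep=st.floats(60, 140),
        k=st.floats(0.1, 1.5),
    )
    @settings(max_examples=200)
    def test_pmax_coupling_composition(self, pad, pes, et, pep, k):
        """Composing the Pmax and coupling forms gives the one-line
        theoretical coupling equation."""
        composed = coupling_from_pressures(pmax_from_timings(pad, et, pep, k), pes)
        direct = pad / pes * (1 + k * et / pep) - 1
        assert composed == pytest.approx(direct, abs=1e-12, rel=1e-12)


class TestBeatObservation:
    def test_valid_passes(self, cohort_means_obs):
        cohort_means_obs.validate()

    def test_missing_fields_reported(self):
        obs = BeatObservation("s1", sbp=120, dbp=80)
        assert obs.missing_fields() == ["pep", "et", "sv"]
        assert not obs.complete
        with pytest.raises(InvalidInputError, match="missing"):
            obs.validate()

    def test_rejects_edv_ref_below_sv(self):
        obs = BeatObservation("s1", sbp=120, dbp=80, pep=90, et=280, sv=60, edv_ref=55)
        with pytest.raises(InvalidInputError, match="edv_ref"):
            obs.validate()

    def test_rejects_inverted_pressures(self):
        obs = BeatObservation("s1", sbp=80, dbp=80, pep=90, et=280, sv=60)
        with pytest.raises(InvalidInputError, match="sbp"):
            obs.validate()
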