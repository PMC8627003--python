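"""Growth, digestibility and balance arithmetic against hand-computed values."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rearlegacy.bioenergetics import (
    CompositionProfile,
    TankGrowthRecord,
    adc,
    carbohydrate_content,
    energy_balance,
    growth_performance,
    hatching_rate,
    nitrogen_balance,
    round_half_up,
    total_inorganic_nitrogen,
)

# Printed growth-trial inputs: (w_i, w_f, FI) per treatment cell, 41-day trial;
# expected Growth and SGR at printed precision.
TRIAL_CELLS = [
    ("FTS/M-NSP", 7.2, 34.2, 0.76, 0.66, 3.8),
    ("FTS/H-NSP", 7.1, 30.8, 0.74, 0.58, 3.6),
    ("BFS/M-NSP", 7.5, 34.9, 0.76, 0.67, 3.8),
    ("BFS/H-NSP", 7.5, 31.3, 0.74, 0.58, 3.5),
]


class TestGrowthPerformance:
    @pytest.mark.parametrize("label,wi,wf,fi,growth,sgr", TRIAL_CELLS)
    def test_reported_trial_cells(self, label, wi, wf, fi, growth, sgr):
        rec = TankGrowthRecord(
            n_initial=30, n_final=30, w_initial=wi, w_final=wf,
            duration=41, feed_intake=fi,
        )
        m = growth_performance(rec)
        assert round_half_up(m.growth, 2) == pytest.approx(growth)
        assert round_half_up(m.sgr, 1) == pytest.approx(sgr)

    def test_no_growth_identity(self):
        rec = TankGrowthRecord(n_initial=10, n_final=10, w_initial=10,
                               w_final=10, duration=7, feed_intake=0.5)
        m = growth_performance(rec)
        assert m.growth == 0
        assert m.sgr == 0
        assert m.fcr is None  # undefined, flagged rather than infinite

    def test_sgr_unit_invariant_growth_not(self):
        rec = TankGrowthRecord(n_initial=5, n_final=5, w_initial=7.2,
                               w_final=34.2, duration=41)
        rec_mg = TankGrowthRecord(n_initial=5, n_final=5, w_initial=7200,
                                  w_final=34200, duration=41)
        m, m_mg = growth_performance(rec), growth_performance(rec_mg)
        assert m.sgr == pytest.approx(m_mg.sgr)  # log-ratio is scale-free
        assert m_mg.growth == pytest.approx(1000 * m.growth)

    def test_rejects_nonpositive_weight_and_mortality_gain(self):
        with pytest.raises(ValueError):
            TankGrowthRecord(n_initial=5, n_final=5, w_initial=0,
                             w_final=10, duration=7)
        with pytest.raises(ValueError):
            TankGrowthRecord(n_initial=5, n_final=6, w_initial=5,
                             w_final=10, duration=7)

    def test_survival(self):
        rec = TankGrowthRecord(n_initial=30, n_final=29, w_initial=7,
                               w_final=31, duration=42)
        assert growth_performance(rec).survival == pytest.approx(100 * 29 / 30)


class TestHatchingRate:
    @pytest.mark.parametrize("h,i,expect", [(7, 10, 70.0), (0, 10, 0.0), (10, 10, 100.0)])
    def test_direct_ratio(self, h, i, expect):
        assert hatching_rate(h, i) == expect

    def test_rejects_more_hatched_than_incubated(self):
        with pytest.raises(ValueError):
            hatching_rate(11, 10)


class TestAdc:
    def test_hand_evaluated_formula(self):
        feed = CompositionProfile(role="feed", yttrium=50, crude_protein=300)
        faeces = CompositionProfile(role="faeces", yttrium=150, crude_protein=270)
        # 100 * (1 - 50*270 / (150*300)) = 100 * (1 - 13500/45000)
        assert adc(feed, faeces, "crude_protein") == pytest.approx(70.0)

    def test_fully_digested_and_nothing_absorbed(self):
        feed = CompositionProfile(role="feed", yttrium=50, crude_fat=100)
        assert adc(feed, CompositionProfile(role="faeces", yttrium=120, crude_fat=0),
                   "crude_fat") == pytest.approx(100.0)
        # faeces nutrient:marker ratio equal to feed's -> 0% absorbed
        assert adc(feed, CompositionProfile(role="faeces", yttrium=100, crude_fat=200),
                   "crude_fat") == pytest.approx(0.0)

    def test_scaling_invariances(self):
        feed = CompositionProfile(role="feed", yttrium=50, ash=80)
        faeces = CompositionProfile(role="faeces", yttrium=150, ash=100)
        base = adc(feed, faeces, "ash")
        # joint rescale of both marker concentrations
        feed2 = CompositionProfile(role="feed", yttrium=500, ash=80)
        faeces2 = CompositionProfile(role="faeces", yttrium=1500, ash=100)
        assert adc(feed2, faeces2, "ash") == pytest.approx(base)
        # joint rescale of both nutrient concentrations
        feed3 = CompositionProfile(role="feed", yttrium=50, ash=8)
        faeces3 = CompositionProfile(role="faeces", yttrium=150, ash=10)
        assert adc(feed3, faeces3, "ash") == pytest.approx(base)

    def test_rejects_zero_marker_or_feed_nutrient(self):
        feed = CompositionProfile(role="feed", yttrium=0, ash=80)
        faeces = CompositionProfile(role="faeces", yttrium=100, ash=50)
        with pytest.raises(ValueError, match="marker"):
            adc(feed, faeces, "ash")
        feed2 = CompositionProfile(role="feed", yttrium=50, ash=0)
        with pytest.raises(ValueError, match="positive"):
            adc(feed2, faeces, "ash")


class TestCarbohydrate:
    @pytest.mark.parametrize(
        "cp,fat,ash,expect", [(400, 100, 80, 420), (0, 0, 0, 1000), (600, 300, 100, 0)]
    )
    def test_by_difference(self, cp, fat, ash, expect):
        p = CompositionProfile(role="feed", crude_protein=cp, crude_fat=fat, ash=ash)
        assert carbohydrate_content(p) == pytest.approx(expect)

    def test_rejects_components_above_dm(self):
        p = CompositionProfile(role="feed", crude_protein=700, crude_fat=300, ash=100)
        with pytest.raises(ValueError):
            carbohydrate_content(p)


class TestNitrogenBalance:
    def test_hand_evaluated_chain(self):
        # FI=1 g/d, diet N=50 mg/g, ADC=0.8, body N gain 1230 mg over 41 d
        nb = nitrogen_balance(1.0, 50.0, 0.8, 0.0, 1230.0, 41.0)
        assert nb.digestible_n_intake == pytest.approx(40.0)
        assert nb.retained_n == pytest.approx(30.0)
        assert nb.branchial_urinary_n == pytest.approx(10.0)
        assert nb.n_efficiency == pytest.approx(75.0)

    def test_full_retention(self):
        nb = nitrogen_balance(1.0, 40.0, 0.5, 0.0, 20.0 * 10, 10.0)
        assert nb.branchial_urinary_n == pytest.approx(0.0)
        assert nb.n_efficiency == pytest.approx(100.0)

    def test_zero_digestible_intake_rejected(self):
        with pytest.raises(ValueError):
            nitrogen_balance(1.0, 50.0, 0.0, 0.0, 100.0, 10.0)


class TestEnergyBalance:
    def test_ammonia_energy_constant(self):
        eb = energy_balance(1.0, 20.0, 0.9, bun=1000.0, body_e_initial=0,
                            body_e_final=0, duration=10)
        assert eb.branchial_urinary_energy == pytest.approx(24.85)

    def test_maintenance_partition(self):
        # ME = 10, protein RE 2 (eff 0.5), fat RE 0.9 (eff 0.9) -> 10 - 4 - 1 = 5
        eb = energy_balance(1.0, 10.0, 1.0, bun=0.0, body_e_initial=0,
                            body_e_final=0, duration=10,
                            retained_protein_energy=2.0, retained_fat_energy=0.9)
        assert eb.metabolisable_energy == pytest.approx(10.0)
        assert eb.maintenance_energy == pytest.approx(5.0)

    def test_zero_heat_when_re_equals_me(self):
        eb = energy_balance(1.0, 10.0, 1.0, bun=0.0, body_e_initial=0,
                            body_e_final=100.0, duration=10)
        assert eb.heat_production == pytest.approx(0.0)


@given(
    fi=st.floats(0.01, 10),
    diet_n=st.floats(1, 100),
    adc_n=st.floats(0.01, 1.0),
    dn_body=st.floats(-500, 5000),
    diet_e=st.floats(1, 30),
    adc_e=st.floats(0.01, 1.0),
    de_body=st.floats(-100, 1000),
    t=st.floats(1, 100),
)
@settings(max_examples=200, derandomize=True)
def test_conservation_identities(fi, diet_n, adc_n, dn_body, diet_e, adc_e, de_body, t):
    """DN = RN + BUN, ME = DE - BUE and HE = ME - RE for any admissible input."""
    nb = nitrogen_balance(fi, diet_n, adc_n, 0.0, dn_body, t)
    scale = max(abs(nb.digestible_n_intake), 1e-12)
    assert abs(nb.digestible_n_intake - (nb.retained_n + nb.branchial_urinary_n)) \
        <= 1e-9 * scale
    eb = energy_balance(fi, diet_e, adc_e, nb.branchial_urinary_n, 0.0, de_body, t)
    e_scale = max(abs(eb.digestible_energy), 1e-12)
    assert abs(eb.metabolisable_energy
               - (eb.digestible_energy - eb.branchial_urinary_energy)) <= 1e-9 * e_scale
    assert abs(eb.heat_production
               - (eb.metabolisable_energy - eb.retained_energy)) <= 1e-9 * e_scale


def test_total_inorganic_nitrogen():
    assert total_inorganic_nitrogen(0, 0, 0) == 0
    assert total_inorganic_nitrogen(1.0, 0.5, 1.6) == pytest.approx(3.1)
    assert total_inorganic_nitrogen(0.1, 0, 0) == pytest.approx(0.1)
    with pytest.raises(ValueError):
        total_inorganic_nitrogen(-0.1, 0, 0)


def test_protein_nitrogen_consistency_enforced():
    CompositionProfile(role="feed", nitrogen=48.0, crude_protein=300.0)  # 48*6.25
    with pytest.raises(ValueError, match="6.25"):
        CompositionProfile(role="feed", nitrogen=48.0, crude_protein=350.0)
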