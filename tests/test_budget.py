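"""Budget equations against independent hand evaluations, plus structural
invariants (identity, monotonicity, linearity, additivity)."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefbudget import budget
from reefbudget.budget import (SiteBudget, bite_rate, bite_volume,
                               calibrate_alpha, cca_calcification,
                               coral_calcification, keep_up_assessment,
                               macroboring_erosion, net_production,
                               parrotfish_erosion, scar_proportion,
                               urchin_erosion, urchin_erosion_individual,
                               vertical_growth)
from reefbudget.constants import DEFAULT_CONSTANTS, BudgetConstants
from reefbudget.survey import (BenthicIntercept, ParrotfishObs, SiteSurvey,
                               TaxonTraits, TraitTable, Transect, UrchinObs)

REL = 1e-9


def make_site(intercepts=(), fish=(), urchins=(), horizontal=1000.0,
              n_transects=1):
    transects = [
        Transect(f"T{k}", "S1", 1000.0, horizontal,
                 [BenthicIntercept(f"T{k}", c, cat, "M", chord)
                  for (c, cat, chord) in intercepts])
        for k in range(n_transects)
    ]
    return SiteSurvey("S1", "Palau", "patch", 7.5, 134.5, transects,
                      [ParrotfishObs("T0", s, l) for s, l in fish],
                      [UrchinObs("T0", g, d) for g, d in urchins])


class TestCalcification:
    def test_cca_hand_values(self):
        assert cca_calcification(15.0) == pytest.approx(2.7, rel=REL)
        assert cca_calcification(0.0) == 0.0
        assert cca_calcification(100.0) == pytest.approx(18.0, rel=REL)

    def test_cca_domain(self):
        with pytest.raises(ValueError):
            cca_calcification(101.0)

    def test_single_taxon_hand_evaluation(self):
        # r=1.5, m=1, x=40%, d=1.4, g=0.8, no CCA -> 1.5*(0.4*1.4*0.8*10)
        traits = TraitTable([TaxonTraits("A", 1.0, 1.4, 0.8)])
        t = Transect("T1", "S1", 1000.0, 1000.0 / 1.5,
                     [BenthicIntercept("T1", "A", "coral", "M", 400.0)])
        cal, ca = coral_calcification(t, traits)
        assert cal == pytest.approx(6.72, rel=REL)
        assert ca == 0.0

    def test_zero_cover_is_zero(self):
        traits = TraitTable([])
        t = Transect("T1", "S1", 1000.0, 1000.0)
        assert coral_calcification(t, traits)[0] == 0.0

    def test_linear_in_rugosity_and_cover(self):
        traits = TraitTable([TaxonTraits("A", 1.2, 1.3, 1.5)])
        t1 = Transect("T1", "S1", 1000.0, 1000.0,
                      [BenthicIntercept("T1", "A", "coral", "M", 200.0)])
        base, _ = coral_calcification(t1, traits, r=1.0)
        assert coral_calcification(t1, traits, r=2.0)[0] == \
            pytest.approx(2 * base, rel=REL)
        t2 = Transect("T1", "S1", 1000.0, 1000.0,
                      [BenthicIntercept("T1", "A", "coral", "M", 400.0)])
        assert coral_calcification(t2, traits, r=1.0)[0] == \
            pytest.approx(2 * base, rel=REL)

    def test_missing_trait_names_taxon(self):
        t = Transect("T1", "S1", 1000.0, 1000.0,
                     [BenthicIntercept("T1", "MYSTERY", "coral", "M", 100.0)])
        with pytest.raises(LookupError, match="MYSTERY"):
            coral_calcification(t, TraitTable([]))


class TestParrotfishSubModels:
    def test_bite_volume_hand_values(self):
        assert bite_volume(30.0) == pytest.approx(math.exp(3.12) / 1000, rel=REL)
        assert bite_volume(1e-12) == pytest.approx(math.exp(1.32) / 1000, rel=1e-6)

    def test_bite_volume_monotone(self):
        assert bite_volume(40.0) > bite_volume(30.0)

    def test_scar_proportion_hand_values(self):
        assert scar_proportion(2.46 / 0.089) == pytest.approx(0.5, rel=REL)
        assert scar_proportion(30.0) == pytest.approx(
            1 / (1 + math.exp(-0.21)), rel=REL)
        assert scar_proportion(1e-12) == pytest.approx(
            1 / (1 + math.exp(2.46)), rel=1e-6)

    def test_bite_rate_hand_value(self):
        assert bite_rate(10.0, brc=2.0) == pytest.approx(114.0, rel=REL)

    def test_bite_rate_clamped_at_zero(self):
        # raw value 60*((4.31+0-0.36) - 0.045*9*30) = -492 -> clamp
        assert bite_rate(30.0, brc=0.0) == 0.0

    @given(l1=st.floats(5.0, 60.0), l2=st.floats(5.0, 60.0))
    @settings(max_examples=50, deadline=None)
    def test_bite_rate_decreasing_in_length(self, l1, l2):
        lo, hi = sorted((l1, l2))
        assert bite_rate(lo, brc=30.0) >= bite_rate(hi, brc=30.0)

    def test_one_fish_site_erosion_oracle(self):
        # chained hand evaluation: vol=e^1.92/1000, sp=1/(1+e^1.57), br=114,
        # D=1.3, one 120 m^2 transect -> 5.295167627497537e-4 kg m^-2 y^-1
        traits = TraitTable([TaxonTraits("F", 1.0, 1.2, 0.0, brc=2.0)])
        site = make_site(fish=[("F", 10.0)])
        got = parrotfish_erosion(site, traits, coral_density=1.3)
        assert got == pytest.approx(5.295167627497537e-4, rel=REL)

    def test_two_identical_fish_double_one(self):
        traits = TraitTable([TaxonTraits("F", 1.0, 1.2, 0.0, brc=2.0)])
        one = parrotfish_erosion(make_site(fish=[("F", 10.0)]), traits,
                                 coral_density=1.3)
        two = parrotfish_erosion(make_site(fish=[("F", 10.0)] * 2), traits,
                                 coral_density=1.3)
        assert two == pytest.approx(2 * one, rel=REL)

    def test_no_fish_is_zero(self):
        traits = TraitTable([])
        assert parrotfish_erosion(make_site(), traits, coral_density=1.3) == 0.0

    def test_density_fallback_on_coral_free_site(self):
        site = make_site()
        assert budget.mean_coral_density(site, TraitTable([])) == \
            DEFAULT_CONSTANTS.default_coral_density


class TestUrchinErosion:
    def test_hand_values(self):
        assert urchin_erosion_individual("Diadema", 5.0) == pytest.approx(
            1e-6 * 5 ** 3.42 * 0.365 * 0.57, rel=REL)
        assert urchin_erosion_individual("Echinometra", 3.0) == pytest.approx(
            4e-4 * 3 ** 1.98 * 0.365 * 0.57, rel=REL)
        assert urchin_erosion_individual("Other", 4.0) == pytest.approx(
            1e-4 * 4 ** 2.32 * 0.365 * 0.57, rel=REL)

    def test_vanishes_at_zero_diameter(self):
        for genus in ("Diadema", "Echinometra", "Other"):
            assert urchin_erosion_individual(genus, 1e-9) == pytest.approx(0.0,
                                                                           abs=1e-12)

    @given(d1=st.floats(0.5, 20.0), d2=st.floats(0.5, 20.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_diameter(self, d1, d2):
        lo, hi = sorted((d1, d2))
        for genus in ("Diadema", "Echinometra", "Other"):
            assert urchin_erosion_individual(genus, lo) <= \
                urchin_erosion_individual(genus, hi)

    def test_unknown_genus_rejected(self):
        with pytest.raises(ValueError, match="genus_class"):
            urchin_erosion_individual("Tripneustes", 5.0)

    def test_site_normalization_by_belt_area(self):
        site = make_site(urchins=[("Diadema", 5.0)])
        expected = 1e-6 * 5 ** 3.42 * 0.365 * 0.57 / 6.0
        assert urchin_erosion(site) == pytest.approx(expected, rel=REL)

    def test_additivity_across_genera(self):
        both = make_site(urchins=[("Diadema", 5.0), ("Echinometra", 3.0)])
        d = make_site(urchins=[("Diadema", 5.0)])
        e = make_site(urchins=[("Echinometra", 3.0)])
        assert urchin_erosion(both) == pytest.approx(
            urchin_erosion(d) + urchin_erosion(e), rel=REL)


class TestMacroboring:
    def test_study_scale_values(self):
        # cover fractions matching the reported island-wide erosion rates
        assert macroboring_erosion(0.0058) == pytest.approx(0.058, rel=REL)
        assert macroboring_erosion(0.0044) == pytest.approx(0.044, rel=REL)
        assert macroboring_erosion(0.0) == 0.0

    def test_percent_proportion_confusion_flagged(self):
        with pytest.raises(ValueError, match="proportion"):
            macroboring_erosion(5.8)


class TestNetProduction:
    def test_arithmetic(self):
        b = SiteBudget("S", gross_calcification=10.0, cca_component=0.0,
                       parrotfish_erosion=2.0, urchin_erosion=0.0,
                       macroboring_erosion=0.0, sediment=0.4,
                       mean_coral_density=1.3)
        assert b.net_production == pytest.approx(8.4, rel=REL)
        assert not b.net_erosion

    def test_bare_substrate_nets_the_sediment_term(self):
        site = make_site()
        b = net_production(site, TraitTable([]))
        assert b.net_production == pytest.approx(0.4, rel=REL)

    def test_net_erosion_permitted_and_flagged(self):
        b = SiteBudget("S", 1.0, 0.0, 2.0, 0.0, 0.0, 0.4, 1.3)
        assert b.net_production < 0
        assert b.net_erosion

    @given(cal=st.floats(0, 30), fish=st.floats(0, 3), urch=st.floats(0, 1),
           mb=st.floats(0, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_budget_identity(self, cal, fish, urch, mb):
        b = SiteBudget("S", cal, 0.0, fish, urch, mb, 0.4, 1.3)
        assert b.net_production == pytest.approx(
            cal + 0.4 - (fish + urch + mb), rel=1e-12, abs=1e-12)

    def test_negative_erosion_component_rejected(self):
        with pytest.raises(ValueError):
            SiteBudget("S", 1.0, 0.0, -0.1, 0.0, 0.0, 0.4, 1.3)


class TestVerticalGrowth:
    def test_alpha_from_single_pair_closed_form(self):
        alpha = calibrate_alpha([(9.7, 7.9)])
        assert alpha == pytest.approx((7.9 / 9.7 - 1) / 9.7, rel=REL)

    def test_identity_conversion_gives_zero_alpha(self):
        assert calibrate_alpha([(5.0, 5.0)]) == pytest.approx(0.0, abs=1e-12)

    def test_consistent_pairs_agree_with_either_alone(self):
        a1 = calibrate_alpha([(9.7, 7.9)])
        v2 = 4.0 + 16.0 * a1
        assert calibrate_alpha([(9.7, 7.9), (4.0, v2)]) == \
            pytest.approx(a1, rel=REL)

    def test_unidentifiable_without_production(self):
        with pytest.raises(ValueError):
            calibrate_alpha([(0.0, 0.0)])

    def test_conversion_round_trip(self):
        alpha = calibrate_alpha([(9.7, 7.9)])
        assert vertical_growth(0.0, alpha) == 0.0
        assert vertical_growth(9.7, alpha) == pytest.approx(7.9, rel=REL)
        assert vertical_growth(20.0, alpha) == pytest.approx(12.3478, rel=1e-4)

    def test_apex_clamp_warns(self):
        alpha = calibrate_alpha([(9.7, 7.9)])
        apex = -1 / (2 * alpha)
        with pytest.warns(UserWarning, match="apex"):
            v = vertical_growth(40.0, alpha)
        assert v == pytest.approx(apex + apex ** 2 * alpha, rel=REL)

    def test_monotone_below_apex(self):
        alpha = calibrate_alpha([(9.7, 7.9)])
        grid = np.linspace(0.0, 25.0, 50)
        vals = [vertical_growth(c, alpha) for c in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestKeepUp:
    def test_moderate_scenario_keeps_up(self):
        ok, margin = keep_up_assessment(7.9, "RCP2.6")
        assert ok and margin == pytest.approx(2.9, rel=REL)

    def test_extreme_scenario_does_not(self):
        ok, margin = keep_up_assessment(7.9, "RCP8.5")
        assert not ok and margin == pytest.approx(-1.1, rel=REL)

    def test_tie_counts_as_keeping_up(self):
        ok, margin = keep_up_assessment(6.5, "RCP4.5")
        assert ok and margin == 0.0

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            keep_up_assessment(7.9, "RCP7")


def test_unit_factor_consistency_asserted_at_load():
    with pytest.raises(ValueError, match="unit factors"):
        BudgetConstants(urchin_day_to_year=0.5)
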