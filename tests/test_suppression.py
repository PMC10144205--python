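"""Tests of the mating-competition / parasitism suppression model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cagedemog import suppression as sup
from cagedemog.suppression import ControlScenario


class TestFertileMatingProbability:
    def test_no_sterile_males(self):
        assert sup.fertile_mating_probability(1, 0, 1.0) == 1.0

    def test_ten_to_one_fully_competitive(self):
        assert sup.fertile_mating_probability(1, 10, 1.0) == pytest.approx(1 / 11)

    def test_partial_competitiveness(self):
        assert sup.fertile_mating_probability(1, 10, 0.1625) == pytest.approx(
            1 / (1 + 1.625), abs=1e-4
        )

    def test_undefined_when_no_males(self):
        with pytest.raises(ValueError):
            sup.fertile_mating_probability(0, 0, 1.0)


class TestEffectiveHatch:
    def test_no_release_returns_control_hatch(self):
        s = ControlScenario(sterile_S=0, fertile_F=1, control_hatch_h0=0.8)
        assert sup.effective_hatch(s) == 0.8

    def test_reproduces_sit_hatch_from_fitted_competitiveness(self):
        """c fitted to the SIT arm reproduces its observed 30.59% hatch."""
        c = sup.fried_competitiveness(80.29, 30.59, 0.0, 10.0)
        s = ControlScenario(
            sterile_S=10, fertile_F=1, competitiveness_c=c, control_hatch_h0=0.8029
        )
        assert sup.effective_hatch(s) == pytest.approx(0.3059, abs=1e-4)
        assert c == pytest.approx(0.1625, abs=1e-3)

    def test_limit_of_overwhelming_competition(self):
        hs = [
            sup.effective_hatch(
                ControlScenario(sterile_S=10, fertile_F=1, competitiveness_c=c)
            )
            for c in (1, 10, 100, 1000)
        ]
        assert all(a > b for a, b in zip(hs, hs[1:]))
        assert hs[-1] < 0.01

    @settings(max_examples=100, deadline=None)
    @given(
        c=st.floats(0.01, 5.0),
        ratio=st.floats(0.0, 100.0),
        h0=st.floats(0.05, 1.0),
        hs=st.floats(0.0, 0.04),
    )
    def test_bounded_and_monotone_in_release(self, c, ratio, h0, hs):
        s = ControlScenario(
            sterile_S=ratio, fertile_F=1.0, competitiveness_c=c,
            control_hatch_h0=h0, sterile_cross_hatch_hs=hs,
        )
        h = sup.effective_hatch(s)
        assert hs - 1e-12 <= h <= h0 + 1e-12
        s2 = ControlScenario(
            sterile_S=ratio + 1.0, fertile_F=1.0, competitiveness_c=c,
            control_hatch_h0=h0, sterile_cross_hatch_hs=hs,
        )
        assert sup.effective_hatch(s2) <= h + 1e-12


class TestFriedCompetitiveness:
    def test_perfect_competitor_round_trip(self):
        assert sup.fried_competitiveness(80.0, 80.0 / 11, 0.0, 10.0) == pytest.approx(1.0)

    def test_no_observed_reduction(self):
        assert sup.fried_competitiveness(80.0, 80.0, 0.0, 10.0) == 0.0

    def test_infeasible_hatch_raises(self):
        with pytest.raises(ValueError):
            sup.fried_competitiveness(80.0, 5.0, 10.0, 10.0)

    def test_hatch_above_baseline_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert sup.fried_competitiveness(80.0, 85.0, 0.0, 10.0) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(
        c=st.floats(0.01, 5.0),
        ratio=st.floats(0.1, 50.0),
        h0=st.floats(0.05, 1.0),
        hs=st.floats(0.0, 0.04),
    )
    def test_exact_round_trip_with_effective_hatch(self, c, ratio, h0, hs):
        """fried_competitiveness inverts effective_hatch for any scenario."""
        s = ControlScenario(
            sterile_S=ratio, fertile_F=1.0, competitiveness_c=c,
            control_hatch_h0=h0, sterile_cross_hatch_hs=hs,
        )
        h = sup.effective_hatch(s)
        if h <= hs + 1e-12:
            return
        c_back = sup.fried_competitiveness(100 * h0, 100 * h, 100 * hs, ratio)
        assert c_back == pytest.approx(c, rel=1e-9, abs=1e-12)


class TestRemainingFraction:
    def test_boundary_values(self):
        assert sup.remaining_reproductive_fraction(1.0, 0.5) == 0.0
        assert sup.remaining_reproductive_fraction(0.0, 1.0) == 1.0

    def test_discussion_scale_values(self):
        """High larval parasitism plus SIT leaves ~10% to breed; the weaker
        pupal parasitoid leaves ~20%."""
        assert sup.remaining_reproductive_fraction(0.6336, 0.2037) == pytest.approx(
            0.0746, abs=5e-4
        )
        assert sup.remaining_reproductive_fraction(0.3498, 0.2685) == pytest.approx(
            0.1746, abs=5e-4
        )

    @settings(max_examples=100, deadline=None)
    @given(p=st.floats(0, 1), h=st.floats(0, 1))
    def test_factorization(self, p, h):
        f = sup.remaining_reproductive_fraction
        assert f(p, h) == pytest.approx(f(p, 1.0) * f(0.0, h), abs=1e-12)


class TestReleaseSizing:
    def test_zero_ratio(self):
        assert sup.release_size(500, 0.8, 0.5, 0.0) == 0

    def test_sentinel_sized_release(self):
        assert sup.release_size(500, 0.804, 0.5, 10.0) == 2010

    def test_round_numbers(self):
        assert sup.release_size(100, 1.0, 0.5, 10.0) == 500

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            sup.release_size(500, 0.8, 0.5, -1.0)


class TestAchievedRatio:
    def test_reported_assay_ratios(self):
        assert sup.achieved_ratio(2136.00, 73.76) == 29
        assert sup.achieved_ratio(1716.0, 116.31) == 15

    def test_zero_release(self):
        assert sup.achieved_ratio(0, 50) == 0

    def test_release_without_males_flags_infinite(self):
        assert sup.achieved_ratio(100, 0) == math.inf


class TestProjection:
    def test_neutral_scenario_is_constant(self):
        s = ControlScenario(per_generation_R=1.0)
        traj = sup.project_generations(s, 1000.0, 5, releases=0.0)
        assert np.allclose(traj.sizes, 1000.0)

    def test_geometric_decay_oracle(self):
        """A fixed per-generation multiplier of 0.0746 is plain geometric
        decay."""
        s = ControlScenario(per_generation_R=0.0746)
        traj = sup.project_generations(s, 1000.0, 2, releases=0.0)
        assert traj.sizes[1] == pytest.approx(74.6)
        assert traj.sizes[2] == pytest.approx(5.565, abs=1e-2)

    def test_combined_dominates_single_techniques(self):
        """The combined trajectory never exceeds either single-technique
        trajectory, across a parameter grid."""
        for p in (0.3, 0.65):
            for S in (500.0, 2000.0):
                for R in (1.5, 5.0):
                    kw = dict(competitiveness_c=0.5, control_hatch_h0=0.8,
                              per_generation_R=R)
                    both = sup.project_generations(
                        ControlScenario(parasitism_p=p, **kw), 200.0, 6, releases=S
                    )
                    abc = sup.project_generations(
                        ControlScenario(parasitism_p=p, **kw), 200.0, 6, releases=0.0
                    )
                    sit = sup.project_generations(
                        ControlScenario(parasitism_p=0.0, **kw), 200.0, 6, releases=S
                    )
                    assert (both.sizes <= abc.sizes + 1e-9).all()
                    assert (both.sizes <= sit.sizes + 1e-9).all()

    def test_eradication_in_finite_generations(self):
        """Fixed releases with sub-replacement dynamics drive N below one,
        with the effective ratio growing as the population falls."""
        s = ControlScenario(
            parasitism_p=0.5, competitiveness_c=1.0, per_generation_R=2.0
        )
        traj = sup.project_generations(s, 1000.0, 30, releases=5000.0)
        assert traj.sizes[-1] < 1.0
        finite = traj.ratios[np.isfinite(traj.ratios)]
        assert (np.diff(finite) >= -1e-9).all()

    def test_immigration_floor(self):
        s = ControlScenario(
            parasitism_p=0.9, per_generation_R=1.0, immigration=50.0
        )
        traj = sup.project_generations(s, 1000.0, 20, releases=0.0)
        assert traj.sizes[-1] >= 50.0


class TestAdditivityGap:
    def test_independent_mechanisms_give_zero_gap(self):
        """If the combined hatch equals the SIT-only hatch the joint effect
        is exactly the product of marginals."""
        h_sit = sup.effective_hatch(
            ControlScenario(sterile_S=10, fertile_F=1, competitiveness_c=0.2)
        )
        gap = sup.additivity_gap(0.5, 10.0, 0.2, 0.8, combined_hatch=h_sit)
        assert gap == pytest.approx(0.0, abs=1e-12)

    def test_observed_means_show_synergy(self):
        """Combined-arm hatch below the SIT-only hatch yields a negative gap."""
        gap = sup.additivity_gap(
            0.6336, 10.0, 0.1625, 0.8029, combined_hatch=0.2037
        )
        assert gap < 0

    def test_model_predicted_gap_is_negative_via_ratio_inflation(self):
        gap = sup.additivity_gap(0.65, 10.0, 0.16, 0.80)
        assert gap < 0

    def test_no_parasitism_reduces_to_hatch_difference(self):
        h_sit = sup.effective_hatch(
            ControlScenario(sterile_S=10, fertile_F=1, competitiveness_c=0.3)
        )
        h_obs = 0.9 * h_sit
        gap = sup.additivity_gap(0.0, 10.0, 0.3, 0.8, combined_hatch=h_obs)
        assert gap == pytest.approx((h_obs - h_sit) / 0.8, abs=1e-12)
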