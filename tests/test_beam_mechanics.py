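"""Beam mechanics: neutral axis / second moment against grid-integration
oracles, moment-arm trigonometry, force-ratio limits and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abscission import (
    MorphParams,
    PullScenario,
    engaged_section,
    force_ratio_approx,
    force_ratio_full,
    moment_arm,
    neutral_axis_offset,
    section_moment,
    stress_components,
    validity_check,
    y_max_of,
)

from conftest import grid_section_props

BETA_FIT = 25.9


class TestNeutralAxis:
    def test_pedicle_only_is_symmetric(self, measured_params):
        sec = engaged_section(measured_params, "straight")
        assert neutral_axis_offset(sec) == 0.0

    def test_vanishes_as_base_stiffness_ratio_diverges(self, measured_params):
        sec = engaged_section(measured_params.replace(beta=1e12), "negative")
        assert abs(neutral_axis_offset(sec)) < 1e-6

    def test_negative_section_offset_sign_and_magnitude(self, measured_params):
        p = measured_params.replace(beta=BETA_FIT)
        delta = neutral_axis_offset(engaged_section(p, "negative"))
        assert delta < 0
        assert abs(delta) < p.c

    def test_matches_grid_integration(self, measured_params):
        p = measured_params.replace(beta=BETA_FIT)
        for direction in ("positive", "negative"):
            sec = engaged_section(p, direction)
            delta = neutral_axis_offset(sec)
            _, cx, _ = grid_section_props(sec.regions)
            assert delta == pytest.approx(cx, abs=0.02 + 5e-3 * abs(cx))


class TestSectionMoment:
    def test_pedicle_only_reduces_to_self_moment(self, measured_params):
        p = measured_params
        sec = engaged_section(p, "straight")
        assert section_moment(sec, 0.0) == pytest.approx(
            p.k * math.pi * p.c**4 / 4.0, rel=1e-12
        )

    def test_parallel_axis_minimality(self, measured_params):
        sec = engaged_section(measured_params.replace(beta=BETA_FIT), "negative")
        delta = neutral_axis_offset(sec)
        I_min = section_moment(sec, delta)
        for shift in (-10.0, -1.0, 1.0, 10.0):
            assert section_moment(sec, delta + shift) > I_min

    def test_matches_grid_integration(self, measured_params):
        p = measured_params.replace(beta=BETA_FIT)
        sec = engaged_section(p, "negative")
        delta = neutral_axis_offset(sec)
        _, _, I_oracle = grid_section_props(sec.regions, about_x=delta)
        assert section_moment(sec, delta) == pytest.approx(I_oracle, rel=5e-3)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        beta=st.floats(1.0, 500.0),
        c=st.floats(5.0, 40.0),
        r=st.floats(10.0, 80.0),
        w=st.floats(20.0, 120.0),
        k=st.floats(0.1, 1.0),
    )
    def test_composite_properties_match_oracle_across_parameters(
        self, beta, c, r, w, k
    ):
        p = MorphParams(c=c, r=r, w=w, k=k, beta=beta)
        sec = engaged_section(p, "negative")
        delta = neutral_axis_offset(sec)
        area_o, cx_o, I_o = grid_section_props(sec.regions, about_x=delta)
        assert delta == pytest.approx(cx_o, abs=0.03 + 5e-3 * abs(cx_o))
        assert section_moment(sec, delta) == pytest.approx(I_o, rel=5e-3)
        assert y_max_of(sec, p) == pytest.approx(c + abs(delta), rel=1e-12)


class TestYMax:
    def test_straight_pull_is_pedicle_radius(self, measured_params):
        sec = engaged_section(measured_params, "straight")
        assert y_max_of(sec, measured_params) == measured_params.c

    def test_limit_of_stiff_pedicle(self, measured_params):
        p = measured_params.replace(beta=1e12)
        sec = engaged_section(p, "positive")
        assert y_max_of(sec, p) == pytest.approx(p.c, abs=1e-6)

    def test_negative_within_pedicle_at_fitted_beta(self, measured_params):
        p = measured_params.replace(beta=BETA_FIT)
        sec = engaged_section(p, "negative")
        y = y_max_of(sec, p)
        assert p.c < y < 2 * p.c


class TestMomentArm:
    def test_no_bend_no_arm(self, measured_params):
        scen = PullScenario("positive", theta1=30.0, theta2=30.0)
        assert moment_arm(measured_params, scen) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_gives_full_lever(self, measured_params):
        p = measured_params
        scen = PullScenario("positive", theta1=90.0, theta2=0.0)
        assert moment_arm(p, scen) == pytest.approx(p.L + p.ell, rel=1e-12)

    def test_measured_positive_scenario(self):
        p = MorphParams(L=12_400.0, ell=200.0)
        scen = PullScenario("positive", theta1=90.0, theta2=15.0)
        assert moment_arm(p, scen) == pytest.approx(
            12_600.0 * math.sin(math.radians(75.0)), rel=1e-12
        )
        assert moment_arm(p, scen) == pytest.approx(12_171.0, abs=1.0)

    def test_theta2_exceeding_theta1_rejected(self):
        with pytest.raises(ValueError):
            PullScenario("positive", theta1=10.0, theta2=20.0)


class TestStressComponents:
    def test_pure_tension_when_angles_vanish(self, measured_params):
        p = measured_params
        scen = PullScenario("straight", theta1=0.0, theta2=0.0)
        sec = engaged_section(p, "straight")
        st_, sb = stress_components(1.0, p, sec, scen)
        assert sb == pytest.approx(0.0, abs=1e-15)
        assert st_ == pytest.approx(1.0 / p.pedicle_area, rel=1e-12)

    def test_linearity_in_force(self, measured_params):
        p = measured_params.replace(beta=BETA_FIT)
        scen = PullScenario("negative")
        sec = engaged_section(p, "negative")
        s1 = stress_components(1.0, p, sec, scen)
        s2 = stress_components(2.0, p, sec, scen)
        assert s2[0] == pytest.approx(2 * s1[0], rel=1e-12)
        assert s2[1] == pytest.approx(2 * s1[1], rel=1e-12)

    def test_bending_stress_composes_prior_operations(self, measured_params):
        p = measured_params.replace(beta=BETA_FIT)
        scen = PullScenario("negative")
        sec = engaged_section(p, "negative")
        _, sb = stress_components(1.0, p, sec, scen)
        delta = neutral_axis_offset(sec)
        expected = (
            moment_arm(p, scen) * y_max_of(sec, p) / section_moment(sec, delta)
        )
        assert sb == pytest.approx(expected, rel=1e-12)


class TestForceRatios:
    def test_straight_pull_ratio_is_unity(self, measured_params):
        scen = PullScenario("straight", theta1=0.0, theta2=0.0)
        assert force_ratio_full(measured_params, scen).ratio == pytest.approx(1.0)

    def test_ratio_tends_to_unity_as_bend_vanishes(self, measured_params):
        scen = PullScenario("positive", theta1=30.0, theta2=30.0 - 1e-7)
        assert force_ratio_full(measured_params, scen).ratio == pytest.approx(
            1.0, abs=1e-3
        )

    def test_full_ratio_composes_prior_operations(self, measured_params):
        p = measured_params.replace(beta=BETA_FIT)
        scen = PullScenario("positive")  # theta1=90, theta2=15
        res = force_ratio_full(p, scen)
        sec = engaged_section(p, "positive")
        delta = neutral_axis_offset(sec)
        I = section_moment(sec, delta)
        y = y_max_of(sec, p)
        arm = moment_arm(p, scen)
        expected = 1.0 / (
            math.cos(math.radians(75.0)) + p.pedicle_area * y * arm / I
        )
        assert res.ratio == pytest.approx(expected, rel=1e-12)
        assert (res.y_max, res.I, res.p) == (y, I, arm)

    def test_halfangle_variant_differs_and_is_smaller(self, measured_params):
        scen = PullScenario("positive")
        full = force_ratio_full(measured_params, scen).ratio
        half = force_ratio_full(measured_params, scen, eq32_halfangle=True).ratio
        assert half < full  # cos(Δθ/2) > cos(Δθ) on (0°, 90°]

    def test_approx_pedicle_only_closed_form(self, measured_params):
        p = measured_params
        scen = PullScenario("straight", theta1=90.0, theta2=0.0)
        assert force_ratio_approx(p, scen).ratio == pytest.approx(
            p.c / (4.0 * p.L), rel=1e-12
        )

    def test_approx_undefined_without_bending(self, measured_params):
        with pytest.raises(ZeroDivisionError):
            force_ratio_approx(
                measured_params, PullScenario("positive", theta1=20.0, theta2=20.0)
            )

    def test_approx_is_length_scale_invariant(self, measured_params):
        p = measured_params.replace(beta=BETA_FIT)
        scaled = MorphParams(
            L=10 * p.L, w=10 * p.w, r=10 * p.r, c=10 * p.c, k=p.k,
            ell=10 * p.ell, beta=p.beta,
        )
        for direction in ("positive", "negative"):
            scen = PullScenario(direction)
            assert force_ratio_approx(p, scen).ratio == pytest.approx(
                force_ratio_approx(scaled, scen).ratio, rel=1e-9
            )

    def test_approx_agrees_with_full_in_validity_regime(self, measured_params):
        p = measured_params.replace(beta=BETA_FIT)
        for direction in ("positive", "negative"):
            scen = PullScenario(direction)
            approx = force_ratio_approx(p, scen)
            full = force_ratio_full(p, scen)
            assert approx.valid, approx.warnings
            assert abs(approx.ratio - full.ratio) / full.ratio <= 0.1

    @pytest.mark.parametrize("beta", [1.0, 3.0, 10.0, BETA_FIT, 100.0, 1000.0])
    def test_directional_ordering(self, measured_params, beta):
        """Positive pulls are easiest, negative harder, straight hardest:
        ratio(pos) < ratio(neg) < 1 across the whole stiffness range."""
        p = measured_params.replace(beta=beta)
        r_pos = force_ratio_full(p, PullScenario("positive")).ratio
        r_neg = force_ratio_full(p, PullScenario("negative")).ratio
        assert 0 < r_pos < r_neg < 1.0

    def test_ratio_decreases_with_bend_angle(self, measured_params):
        p = measured_params.replace(beta=BETA_FIT)
        deltas = np.linspace(1.0, 90.0, 30)
        ratios = [
            force_ratio_full(
                p, PullScenario("positive", theta1=90.0, theta2=90.0 - d)
            ).ratio
            for d in deltas
        ]
        assert all(a > b for a, b in zip(ratios, ratios[1:]))


class TestValidityCheck:
    def test_measured_geometry_passes_all_flags(self, measured_params):
        p = measured_params
        flags = validity_check(p, PullScenario("negative"), y_max=1.3 * p.c)
        assert flags == {
            "slender_lever": True,
            "angle_ratio": True,
            "bend_angle": True,
            "y_max_in_pedicle": True,
        }

    def test_neutral_axis_outside_pedicle_flagged(self, measured_params):
        p = measured_params
        flags = validity_check(p, PullScenario("negative"), y_max=2.5 * p.c)
        assert not flags["y_max_in_pedicle"]

    def test_small_bend_angle_flagged(self, measured_params):
        flags = validity_check(
            measured_params,
            PullScenario("positive", theta1=60.0, theta2=50.0),
            y_max=measured_params.c,
        )
        assert not flags["bend_angle"]
        assert not flags["angle_ratio"]
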