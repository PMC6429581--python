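"""Energy branches, minima, barriers, potentials and landmark depths."""

import math

import numpy as np
import pytest

from microwet import (
    BarrierDefinitionError,
    MicrostructureGeometry,
    NoWettedEquilibriumError,
    WettingConstants,
    composite_branch,
    composite_minimum,
    energy_barrier,
    energy_potential,
    equilibrium_contact_patch,
    landmarks,
    shape_function,
    transition_summary,
    wenzel_cos,
    wenzel_roughness_at_depth,
    wetted_branch,
)
from microwet.transition import composite_cos, composite_cos_unbounded

NJ = 1e-9


class TestCompositeMinimum:
    def test_closed_form_depth_is_spacing_independent(self, constants, hex_geom):
        expected_x = 1 + math.cos(math.radians(104))
        for delta in (0.0, 0.5, 1.0, 4.0):
            mn = composite_minimum(hex_geom(delta=delta), constants)
            assert mn.x_star == pytest.approx(expected_x, abs=1e-12)

    @pytest.mark.parametrize(
        "delta,F_expected",
        [(1.0, 3.9513), (0.5, 3.8515), (0.0, 3.3267)],
    )
    def test_minimum_shape_values(self, constants, hex_geom, delta, F_expected):
        mn = composite_minimum(hex_geom(delta=delta), constants)
        assert mn.shape_F == pytest.approx(F_expected, abs=2e-4)

    @pytest.mark.parametrize("theta_y", [100.0, 104.0, 110.0, 120.0])
    @pytest.mark.parametrize("delta", [0.0, 0.25, 0.5, 1.0, 2.0, 4.0])
    def test_closed_form_agrees_with_grid_search(self, hex_geom, theta_y, delta):
        constants = WettingConstants(young_angle_deg=theta_y)
        geom = hex_geom(delta=delta)
        mn = composite_minimum(geom, constants)
        x = np.linspace(1e-6, 1 - 1e-6, 200001)
        F = shape_function(np.asarray(composite_cos(geom, constants, x)))
        assert abs(x[np.argmin(F)] - mn.x_star) < 1e-5
        assert mn.shape_F <= F.min() + 1e-12


class TestBranches:
    def test_composite_branch_landmark_points(self, constants, hex_geom):
        geom = hex_geom(delta=1.0, eta=1.2)
        curve = composite_branch(geom, constants, [0.0, 0.75, 1.0])
        assert curve.shape_F[0] == pytest.approx(4.0, rel=1e-12)  # no penetration
        assert curve.shape_F[1] == pytest.approx(3.9513, abs=1e-4)
        assert not curve.saturated.any()

    def test_composite_saturation_point(self, constants, hex_geom):
        geom = hex_geom(delta=1.0, eta=1.2)
        x_sat = -1 / (2 * math.cos(math.radians(104)))
        curve = composite_branch(geom, constants, [x_sat])
        assert curve.cosine_c[0] == pytest.approx(-1.0, abs=1e-12)
        assert curve.shape_F[0] == pytest.approx(4.0, rel=1e-10)

    def test_wetted_branch_values(self, constants, hex_geom):
        geom = hex_geom(delta=1.0, eta=1.0)
        curve = wetted_branch(geom, constants, [1.0, 4.6, 7.411])
        assert curve.shape_F[0] == pytest.approx(2.8642, abs=2e-4)
        assert curve.shape_F[1] == pytest.approx(3.744, abs=2e-3)
        assert curve.shape_F[2] == pytest.approx(4.0, abs=1e-3)

    def test_branch_energy_is_equilibrium_form(self, constants, hex_geom):
        geom = hex_geom(delta=1.0, eta=1.0)
        curve = composite_branch(geom, constants, np.linspace(0, 2, 21))
        K = constants.energy_scale
        assert np.allclose(curve.gibbs_excess_J, K * np.cbrt(curve.shape_F), rtol=1e-12)

    def test_clamp_policy_plateaus_at_sphere_energy(self, constants, hex_geom):
        geom = hex_geom(delta=1.0, eta=3.0)
        x = np.linspace(2.5, 4.0, 7)  # past saturation
        formal = composite_branch(geom, constants, x, continuation="formal")
        clamped = composite_branch(geom, constants, x, continuation="clamp")
        assert formal.saturated.all() and clamped.saturated.all()
        K = constants.energy_scale
        assert np.allclose(clamped.gibbs_excess_J, K * 4 ** (1 / 3), rtol=1e-12)
        assert np.all(formal.gibbs_excess_J < clamped.gibbs_excess_J + 1e-18)

    def test_formal_extension_past_structure_bottom(self, constants, hex_geom):
        geom = hex_geom(delta=1.0, eta=1.0)
        curve = composite_branch(
            geom, constants, [0.5, 1.5, 3.0], allow_extension=True
        )
        assert curve.cosine_c[2] == pytest.approx(
            composite_cos_unbounded(geom, constants, 3.0), rel=1e-12
        )

    def test_grid_must_increase(self, constants, hex_geom):
        with pytest.raises(ValueError):
            composite_branch(hex_geom(), constants, [0.5, 0.2])


class TestBarrierAndPotential:
    @pytest.mark.parametrize(
        "delta,expected_nJ",
        [(0.0, 7.278), (0.25, 3.126), (0.5, 1.558), (1.0, 0.512)],
    )
    def test_hemisphere_barrier_at_cap_eval(self, constants, hex_geom, delta, expected_nJ):
        dg1 = energy_barrier(hex_geom(delta=delta), constants, eval_x=0.95)
        assert dg1 / NJ == pytest.approx(expected_nJ, abs=2e-3)

    def test_barrier_convention_is_explicit(self, constants, hex_geom):
        geom = hex_geom(delta=1.0)
        dg_095 = energy_barrier(geom, constants, eval_x=0.95)
        dg_099 = energy_barrier(geom, constants, eval_x=0.99)
        assert dg_099 > dg_095  # energy keeps rising toward bottom contact
        assert dg_099 / NJ == pytest.approx(0.74, abs=0.01)

    def test_lotus_barrier_at_bottom_contact(self, constants, lotus_geom):
        dg1 = energy_barrier(lotus_geom, constants)  # default: min(1+eta, x_sat) = 2
        assert dg1 / NJ == pytest.approx(4.18, abs=0.01)

    def test_barrier_eval_must_exceed_minimum(self, constants, hex_geom):
        with pytest.raises(BarrierDefinitionError):
            energy_barrier(hex_geom(delta=1.0), constants, eval_x=0.5)

    @pytest.mark.parametrize(
        "delta,eta,expected_nJ",
        [(0.5, 0.0, 83.39), (1.0, 1.0, 74.37), (4.0, 0.0, 122.26)],
    )
    def test_energy_potential_values(self, constants, hex_geom, delta, eta, expected_nJ):
        dg2 = energy_potential(hex_geom(delta=delta, eta=eta), constants)
        assert dg2 / NJ == pytest.approx(expected_nJ, abs=0.01)

    def test_saturated_wenzel_state_rejected(self, constants, hex_geom):
        # d0 = 0, h0 = 2 r0 pushes r past the Wenzel solvability bound
        geom = hex_geom(delta=0.0, eta=2.0)
        with pytest.raises(NoWettedEquilibriumError):
            energy_potential(geom, constants)

    def test_monotone_trends_in_spacing_and_height(self, constants, hex_geom):
        dg1 = [
            energy_barrier(hex_geom(delta=d), constants, eval_x=0.95)
            for d in (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)
        ]
        dg2 = [
            energy_potential(hex_geom(delta=d), constants)
            for d in (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(dg1) < 0) and np.all(np.diff(dg2) > 0)
        dg1_h = [
            energy_barrier(hex_geom(delta=1.0, eta=e), constants)
            for e in (0.25, 0.5, 0.75, 1.0)
        ]
        dg2_h = [
            energy_potential(hex_geom(delta=1.0, eta=e), constants)
            for e in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert np.all(np.diff(dg1_h) > 0) and np.all(np.diff(dg2_h) < 0)

    def test_maximum_barrier_plateau_for_tall_structures(self, constants, hex_geom):
        # once the structure outlasts Cassie saturation the barrier tops out
        x_sat = -1 / (2 * math.cos(math.radians(104)))
        K = constants.energy_scale
        mn = composite_minimum(hex_geom(delta=1.0), constants)
        expected = K * (4 ** (1 / 3) - mn.shape_F ** (1 / 3))
        for eta in (x_sat - 1, x_sat, 3.0, 9.0):
            dg1 = energy_barrier(hex_geom(delta=1.0, eta=eta), constants)
            assert dg1 == pytest.approx(expected, rel=1e-9)

    def test_scale_invariance_of_energies(self, constants):
        a = MicrostructureGeometry(5e-6, 5e-6, 5e-6)
        b = MicrostructureGeometry(5e-5, 5e-5, 5e-5)
        assert energy_barrier(a, constants) == pytest.approx(
            energy_barrier(b, constants), rel=1e-12
        )
        assert energy_potential(a, constants) == pytest.approx(
            energy_potential(b, constants), rel=1e-12
        )


class TestLandmarks:
    def test_lotus_model_landmarks(self, constants, lotus_geom):
        marks = landmarks(lotus_geom, constants)
        assert marks.x_star == pytest.approx(0.758, abs=1e-3)
        assert marks.x_saturation == pytest.approx(2.0668, abs=1e-4)
        assert marks.x_crossing == pytest.approx(4.607, abs=1e-3)
        assert marks.x_wenzel_limit == pytest.approx(7.4105, abs=1e-4)

    def test_hemisphere_model_has_no_deep_landmarks(self, constants, pachyphylla_geom):
        marks = landmarks(pachyphylla_geom, constants)
        assert marks.x_saturation is None
        assert marks.x_crossing is None

    def test_crossing_agrees_with_dense_grid_sign_change(self, constants, lotus_geom):
        marks = landmarks(lotus_geom, constants)
        x = np.arange(marks.x_saturation + 1e-4, marks.x_wenzel_limit, 1e-4)
        gap = shape_function(
            np.asarray(composite_cos_unbounded(lotus_geom, constants, x))
        ) - shape_function(
            np.asarray(
                wenzel_cos(constants, wenzel_roughness_at_depth(lotus_geom, x))
            )
        )
        (idx,) = np.nonzero(np.diff(np.sign(gap)))
        assert len(idx) == 1
        assert abs(x[idx[0]] - marks.x_crossing) <= 1e-4

    def test_wenzel_limit_saturates_the_wenzel_cosine(self, constants, lotus_geom):
        marks = landmarks(lotus_geom, constants)
        r = wenzel_roughness_at_depth(lotus_geom, marks.x_wenzel_limit)
        assert wenzel_cos(constants, r) == pytest.approx(-1.0, abs=1e-9)


class TestEquilibriumPatch:
    def test_species_contact_patches(self, constants, pachyphylla_geom, lotus_geom):
        euc = equilibrium_contact_patch(pachyphylla_geom, constants)
        lot = equilibrium_contact_patch(lotus_geom, constants)
        assert euc.droplet_radius_R == pytest.approx(1.074e-3, rel=5e-4)
        assert lot.droplet_radius_R == pytest.approx(1.065e-3, rel=5e-4)
        assert euc.area_LS == pytest.approx(0.908e-6, rel=2e-3)
        assert lot.area_LS == pytest.approx(0.298e-6, rel=3e-3)
        assert euc.area_LS / lot.area_LS == pytest.approx(3.04, abs=0.01)

    def test_summary_bundles_everything(self, constants, lotus_geom):
        s = transition_summary(lotus_geom, constants)
        assert s.F_min == pytest.approx(3.9513, abs=1e-4)
        assert s.barrier_eval_x == pytest.approx(2.0)
        assert s.potential_dG2 == pytest.approx(74.37e-9, abs=0.01e-9)
        assert not s.saturated_wetted
        assert s.landmarks.x_wenzel_limit == pytest.approx(7.4105, abs=1e-3)

    def test_summary_flags_saturated_wetted_state(self, constants, hex_geom):
        s = transition_summary(hex_geom(delta=0.0, eta=2.0), constants)
        assert s.saturated_wetted and s.potential_dG2 is None
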