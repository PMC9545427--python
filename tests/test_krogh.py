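"""Krogh-cylinder geometry, consumption and tissue oxygen field."""

import numpy as np
import pytest

import hyperoxr1 as hx
from oracles import bvp_slice


@pytest.fixture(scope="module")
def geometry(constants):
    return hx.capillary_geometry(0.05, constants)


class TestGeometry:
    def test_frozen_example(self, geometry):
        assert geometry.n_cap == pytest.approx(1299.2, abs=0.1)
        assert geometry.r_t == pytest.approx(1.387e-5, rel=1e-3)

    def test_blood_volume_identity(self, constants):
        # the grid construction makes bv = pi*r_c^2/(4*r_t^2) hold exactly
        for bv in (0.001, 0.02, 0.05, 0.17, 0.5, 0.99):
            g = hx.capillary_geometry(bv, constants)
            assert np.pi * g.r_c**2 / (4 * g.r_t**2) == pytest.approx(bv, rel=1e-10)
            assert g.r_t == pytest.approx((g.r_c / 2) * np.sqrt(np.pi / bv), rel=1e-12)

    def test_voxel_size_independence(self, constants):
        a = hx.capillary_geometry(0.05, constants, voxel_volume=1e-9)
        b = hx.capillary_geometry(0.05, constants, voxel_volume=8e-9)
        assert a.r_t == pytest.approx(b.r_t, rel=1e-12)

    @pytest.mark.parametrize("bv", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_blood_volume(self, constants, bv):
        with pytest.raises(hx.DegenerateGeometryError):
            hx.capillary_geometry(bv, constants)


class TestMaxConsumption:
    def test_zero_and_linearity(self, constants, geometry):
        sao2 = hx.hill_saturation(90.0, 37.0, 2.7)
        assert hx.max_consumption_from_oef(0.0, 0.42, sao2, geometry, constants) == 0.0
        m1 = hx.max_consumption_from_oef(0.17, 0.42, sao2, geometry, constants)
        m2 = hx.max_consumption_from_oef(0.34, 0.42, sao2, geometry, constants)
        assert m2 == pytest.approx(2 * m1, rel=1e-12)

    def test_frozen_example_and_flux_balance(self, constants, geometry):
        sao2 = hx.hill_saturation(90.0, 37.0, 2.7)
        m0 = hx.max_consumption_from_oef(0.34, 0.42, sao2, geometry, constants)
        assert m0 == pytest.approx(3.52e-3, rel=2e-3)
        # independent check: delivered O2 flux per capillary / annulus volume
        delivered = (constants.cap_velocity * np.pi * geometry.r_c**2
                     * 0.42 * constants.c0 * sao2 * 0.34)  # mlO2/s
        annulus = np.pi * (geometry.r_t**2 - geometry.r_c**2) * geometry.cap_length
        assert m0 == pytest.approx(delivered / annulus, rel=1e-12)


class TestRadialProfile:
    def test_boundary_and_degenerate(self, constants, geometry):
        k = constants.k_diff
        assert hx.krogh_radial_po2(geometry.r_c, 90.0, 2.4e-4, geometry, k) == 90.0
        r = np.linspace(geometry.r_c, geometry.r_t, 11)
        assert np.allclose(hx.krogh_radial_po2(r, 55.0, 0.0, geometry, k), 55.0)
        with pytest.raises(ValueError):
            hx.krogh_radial_po2(geometry.r_t * 1.1, 90.0, 1e-4, geometry, k)

    def test_frozen_example(self, constants, geometry):
        val = hx.krogh_radial_po2(geometry.r_t, 90.0, 2.4e-4, geometry, 6.748e-14)
        assert val == pytest.approx(89.69, abs=0.01)

    def test_against_uniform_consumption_bvp(self, constants, geometry):
        # same boundary conditions, numerically integrated diffusion equation
        m = 2.4e-4
        rr, po2_oracle, _ = bvp_slice(90.0, m, 0.0, constants.k_diff,
                                      geometry.r_c, geometry.r_t)
        po2 = hx.krogh_radial_po2(rr, 90.0, m, geometry, constants.k_diff)
        assert np.max(np.abs(po2 - po2_oracle)) < 1e-3

    def test_zero_outer_gradient(self, constants, geometry):
        k = constants.k_diff
        h = geometry.r_t * 1e-7
        f = lambda r: hx.krogh_radial_po2(r, 90.0, 2.4e-4, geometry, k, clamp=False)
        grad = (f(geometry.r_t) - f(geometry.r_t - h)) / h
        assert abs(grad) < 1e-4 * abs(f(geometry.r_t)) / geometry.r_t


class TestMichaelisMenten:
    def test_algebraic_points(self):
        assert hx.michaelis_menten_rate(2.0, 1e-3, 2.0) == pytest.approx(5e-4)
        assert hx.michaelis_menten_rate(0.0, 1e-3, 2.0) == 0.0
        assert hx.michaelis_menten_rate(18.0, 1e-3, 2.0) == pytest.approx(9e-4)

    def test_zero_pcrit_steps_at_zero(self):
        assert hx.michaelis_menten_rate(5.0, 1e-3, 0.0) == 1e-3
        assert hx.michaelis_menten_rate(0.0, 1e-3, 0.0) == 0.0


class TestTissueSlice:
    def test_zero_pcrit_reduces_to_closed_form(self, constants, geometry):
        cons = hx.ConsumptionModel(m0=2.4e-4, p_crit=0.0, k_diff=constants.k_diff)
        sol = hx.solve_tissue_slice(90.0, cons, geometry)
        expected = hx.krogh_radial_po2(sol.r_grid, 90.0, 2.4e-4, geometry,
                                       constants.k_diff)
        assert np.allclose(sol.po2, expected, atol=1e-12)
        assert sol.m_eff == 2.4e-4

    def test_zero_consumption_uniform(self, constants, geometry):
        cons = hx.ConsumptionModel(m0=0.0, p_crit=1.0, k_diff=constants.k_diff)
        sol = hx.solve_tissue_slice(64.0, cons, geometry)
        assert np.allclose(sol.po2, 64.0)
        assert sol.clamped_fraction == 0.0

    def test_self_consistency_residual(self, constants, geometry):
        cons = hx.ConsumptionModel(m0=1.5e-3, p_crit=2.0, k_diff=constants.k_diff)
        sol = hx.solve_tissue_slice(70.0, cons, geometry)
        m_check = hx.michaelis_menten_rate(sol.mean_po2, cons.m0, cons.p_crit)
        assert abs(sol.m_eff - m_check) < 1e-6 * cons.m0

    def test_matches_bvp_oracle(self, constants, geometry):
        cons = hx.ConsumptionModel(m0=1.5e-3, p_crit=2.0, k_diff=constants.k_diff)
        sol = hx.solve_tissue_slice(45.0, cons, geometry)
        _, _, mean_oracle = bvp_slice(45.0, cons.m0, cons.p_crit, cons.k_diff,
                                      geometry.r_c, geometry.r_t)
        assert sol.mean_po2 == pytest.approx(mean_oracle, abs=0.5)


@pytest.fixture(scope="module")
def profile(constants):
    return hx.capillary_profile(90.0, 0.42, constants, oef=0.34, mode="saturation")


class TestTissueField:
    def test_zero_consumption_mean_is_capillary_average(self, constants, geometry,
                                                        profile):
        cons = hx.ConsumptionModel(m0=0.0, p_crit=1.0, k_diff=constants.k_diff)
        field = hx.tissue_field(profile, cons, geometry)
        cap_mean = np.trapezoid(profile.po2_of_z, profile.z) / constants.cap_length
        assert field.mean_po2 == pytest.approx(cap_mean, rel=1e-12)
        assert field.clamped_fraction == 0.0

    def test_inner_boundary_and_minimum_location(self, constants, geometry, profile):
        cons = hx.ConsumptionModel(m0=1.2e-3, p_crit=2.0, k_diff=constants.k_diff)
        field = hx.tissue_field(profile, cons, geometry)
        assert np.allclose(field.po2[:, 0], profile.po2_of_z)
        assert field.min_po2 == field.po2[-1, -1]  # outer radius, venous end
        assert field.min_po2 <= field.mean_po2 <= field.po2.max()

    def test_field_matches_scalar_slice_solver(self, constants, geometry, profile):
        cons = hx.ConsumptionModel(m0=1.2e-3, p_crit=2.0, k_diff=constants.k_diff)
        field = hx.tissue_field(profile, cons, geometry)
        for i in (0, 17, 50):
            sol = hx.solve_tissue_slice(float(profile.po2_of_z[i]), cons, geometry)
            assert np.allclose(field.po2[i], sol.po2, atol=1e-8)
            assert field.m_eff_of_z[i] == pytest.approx(sol.m_eff, rel=1e-9)

    def test_delta_field(self, constants, geometry, profile):
        cons = hx.ConsumptionModel(m0=1.2e-3, p_crit=2.0, k_diff=constants.k_diff)
        field = hx.tissue_field(profile, cons, geometry)
        delta = hx.delta_tissue_po2(field, field)
        assert delta.mean == 0.0
        assert np.all(delta.pointwise == 0.0)

    def test_delta_additivity_and_grid_mismatch(self, constants, geometry):
        cons = hx.ConsumptionModel(m0=8e-4, p_crit=1.0, k_diff=constants.k_diff)
        fields = []
        for pao2 in (90.0, 200.0, 600.0):
            prof = hx.capillary_profile(pao2, 0.42, constants, oef=0.2,
                                        mode="saturation")
            fields.append(hx.tissue_field(prof, cons, geometry))
        d_ab = hx.delta_tissue_po2(fields[0], fields[1]).mean
        d_bc = hx.delta_tissue_po2(fields[1], fields[2]).mean
        d_ac = hx.delta_tissue_po2(fields[0], fields[2]).mean
        assert d_ac == pytest.approx(d_ab + d_bc, abs=1e-9)
        other = hx.tissue_field(
            hx.capillary_profile(90.0, 0.42, constants, oef=0.2, n_z=11,
                                 mode="saturation"), cons, geometry)
        with pytest.raises(ValueError):
            hx.delta_tissue_po2(fields[0], other)
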