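"""Synthetic minibeam engine: depth dose, lateral spread, comb plane, LET proxy."""

import numpy as np
import pytest
from scipy import integrate

import pmbrt as pm
from pmbrt.engine import (
    ALPHA_CM,
    P_EXP,
    _E_S,
    _M_PROTON,
    _X0_WATER_CM,
    entrance_letd,
    lateral_sigma,
)


def distal_crossing(z, d, frac):
    target = frac * d.max()
    imax = int(np.argmax(d))
    idx = imax + np.where(d[imax:] < target)[0][0]
    return np.interp(target, [d[idx], d[idx - 1]], [z[idx], z[idx - 1]])


class TestBraggPDD:
    def test_distal_d80_matches_range_rule(self):
        """Distal 80% depth agrees with the power-law range R0 = alpha*E^p."""
        beam = pm.BeamSpec(energy=150.0)
        z = np.arange(0.0, 200.0, 0.05)
        pdd = pm.bragg_pdd(beam, z)
        d80 = distal_crossing(z, pdd.dose, 0.80)
        expected = 10.0 * (0.0022 * 150.0 ** 1.77)
        assert abs(d80 - expected) / expected < 0.02

    def test_low_energy_range(self):
        """A 70 MeV beam stops at about 4 cm."""
        z = np.arange(0.0, 60.0, 0.05)
        pdd = pm.bragg_pdd(pm.BeamSpec(energy=70.0), z)
        d80 = distal_crossing(z, pdd.dose, 0.80)
        assert 40.0 <= d80 <= 42.0

    @pytest.mark.parametrize("energy", [70.0, 100.0, 150.0, 180.0])
    def test_bragg_shape(self, energy):
        """Single global maximum, plateau-to-peak ratio in [0.2, 0.6], zero beyond range."""
        beam = pm.BeamSpec(energy=energy)
        z = np.arange(0.0, 250.0, 0.1)
        d = pm.bragg_pdd(beam, z).dose
        interior = np.where((d[1:-1] > d[:-2]) & (d[1:-1] > d[2:]))[0]
        assert len(interior) == 1
        assert 0.2 <= d[0] / d.max() <= 0.6
        # distal falloff: below 1% of peak within 15 mm of the range
        assert d[z > beam.range_mm + 15.0].max() < 0.01 * d.max()

    def test_entrance_dose_finite(self):
        pdd = pm.bragg_pdd(pm.BeamSpec(energy=120.0), [0.0])
        assert pdd.dose[0] > 0
        assert np.isfinite(pdd.dose[0])

    def test_mu_scale_sets_surface_dose(self):
        pdd = pm.bragg_pdd(pm.BeamSpec(energy=150.0, mu_scale=7.5), [0.0, 10.0])
        assert pdd.dose[0] == pytest.approx(7.5)

    def test_energy_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="energy"):
            pm.BeamSpec(energy=250.0)
        with pytest.raises(ValueError, match="energy"):
            pm.BeamSpec(energy=40.0)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            pm.bragg_pdd(pm.BeamSpec(energy=150.0), [-1.0, 0.0, 1.0])


class TestLateralSigma:
    def test_surface_boundary(self, beam150):
        """At z = 0 with no air gap the spread equals the slit-exit sigma."""
        assert lateral_sigma(beam150, 0.0, 0.0, exit_sigma=0.3) == pytest.approx(0.3, abs=1e-9)

    def test_monotone_in_depth_and_air_gap(self, beam150):
        z = np.linspace(0.0, 150.0, 80)
        s20 = lateral_sigma(beam150, z, 20.0)
        s80 = lateral_sigma(beam150, z, 80.0)
        assert np.all(np.diff(s20) >= 0)
        assert np.all(s80 > s20)
        assert np.all(s20 > 0)

    def test_negative_depth_rejected(self, beam150):
        with pytest.raises(ValueError):
            lateral_sigma(beam150, -1.0, 60.0)

    @pytest.mark.parametrize("energy,z_mm", [(70.0, 20.0), (150.0, 50.0), (150.0, 120.0)])
    def test_mcs_against_quadrature_oracle(self, energy, z_mm):
        """Fermi-Eyges spatial moment recomputed with an independent quad integral."""
        r0_cm = ALPHA_CM * energy ** P_EXP

        def scattering_power(u_cm):
            e = ((r0_cm - u_cm) / ALPHA_CM) ** (1.0 / P_EXP)
            pv = e * (e + 2.0 * _M_PROTON) / (e + _M_PROTON)
            return (_E_S / pv) ** 2 / _X0_WATER_CM

        z_cm = z_mm / 10.0
        var, _ = integrate.quad(
            lambda u: (z_cm - u) ** 2 * scattering_power(u), 0.0, min(z_cm, 0.999 * r0_cm),
            limit=200,
        )
        sigma_mcs_oracle = 10.0 * np.sqrt(var)
        beam = pm.BeamSpec(energy=energy)
        got = lateral_sigma(beam, z_mm, 0.0, exit_sigma=0.0, exit_theta=0.0)
        assert got == pytest.approx(sigma_mcs_oracle, rel=0.01)


class TestCollimator:
    @pytest.mark.parametrize("ctc,expected_cm", [(2.8, 1.1), (3.2, 1.3), (4.0, 1.6)])
    def test_lateral_field_size(self, ctc, expected_cm):
        """(n-1)*ctc rounded to 0.1 cm reproduces the vendor field sizes."""
        col = pm.CollimatorSpec(n_slits=5, ctc=ctc)
        assert pm.collimator_extent(col) == expected_cm

    def test_invalid_collimators_rejected(self):
        with pytest.raises(ValueError):
            pm.CollimatorSpec(n_slits=0)
        with pytest.raises(ValueError):
            pm.CollimatorSpec(slit_width=3.0, ctc=2.8)
        with pytest.raises(ValueError):
            pm.CollimatorSpec(leakage=1.0)
        with pytest.raises(ValueError):
            pm.CollimatorSpec(per_slit_width_jitter=np.full(5, 0.5))


class TestMinibeamDose:
    def test_sigma_zero_limit_single_slit(self):
        """With vanishing blur the plane is PDD inside the slit, zero outside."""
        beam = pm.BeamSpec(energy=150.0)
        col = pm.CollimatorSpec(n_slits=1, leakage=0.0, exit_sigma=1e-3, exit_theta=0.0)
        grid = pm.PhantomGridSpec(x_extent=10.0, z_extent=1.0, dx=0.02, dz=0.5, air_gap=0.0)
        plane = pm.minibeam_dose(beam, col, grid)
        pdd = pm.bragg_pdd(beam, plane.z_coords)
        inside = np.abs(plane.x_coords) < 0.15
        outside = np.abs(plane.x_coords) > 0.35
        assert plane.dose[inside, 0] == pytest.approx(pdd.dose[0], rel=1e-3)
        assert np.all(plane.dose[outside, 0] < 1e-6 * pdd.dose[0])

    def test_lateral_mass_conserved(self, beam150):
        """Without leakage, the lateral integral / PDD is depth independent."""
        col = pm.CollimatorSpec(leakage=0.0)
        grid = pm.PhantomGridSpec(x_extent=60.0, z_extent=150.0, air_gap=60.0)
        plane = pm.minibeam_dose(beam150, col, grid)
        pdd = pm.bragg_pdd(beam150, plane.z_coords).dose
        mass = plane.dose.sum(axis=0) * 0.1 / pdd
        assert mass.max() / mass.min() - 1.0 < 1e-3

    def test_comb_structure_cross_checked_by_peak_finder(self, minibeam_grid, collimator):
        prof = minibeam_grid.lateral_profile(10.0)
        pv = pm.find_peaks_valleys(prof, collimator.ctc)
        assert pv.n_peaks == 5
        assert len(pv.valley_x) == 4
        assert np.max(np.abs(np.diff(pv.peak_x) - collimator.ctc)) < 0.05

    def test_narrow_grid_rejected(self, beam150, collimator):
        grid = pm.PhantomGridSpec(x_extent=20.0, z_extent=170.0, air_gap=60.0)
        with pytest.raises(ValueError, match="margin"):
            pm.minibeam_dose(beam150, collimator, grid)

    def test_spot_sum_fluence_mode(self, collimator):
        beam = pm.BeamSpec(energy=150.0, fluence_mode="spot_sum")
        grid = pm.PhantomGridSpec(x_extent=60.0, z_extent=2.0, dz=0.5, air_gap=60.0)
        plane = pm.minibeam_dose(beam, collimator, grid)
        assert plane.dose.max() > 0


class TestLETProxy:
    def test_monotone_up_to_range(self, beam150):
        z = np.arange(0.0, beam150.range_mm, 0.25)
        let = pm.letd_proxy(beam150, z)
        assert np.all(np.diff(let.letd) >= 0)
        assert let.interp(0.0) < let.interp(0.9 * beam150.range_mm)

    @pytest.mark.parametrize("energy", [70.0, 150.0, 180.0])
    def test_entrance_and_distal_scales(self, energy):
        beam = pm.BeamSpec(energy=energy)
        z = np.arange(0.0, beam.range_mm + 5.0, 0.1)
        let = pm.letd_proxy(beam, z)
        assert 0.5 <= let.letd[0] <= 2.0
        assert 5.0 <= let.letd.max() <= 15.0

    def test_constant_mode_flat(self, beam150):
        let = pm.letd_proxy(beam150, np.arange(0.0, 100.0, 1.0), constant=1.3)
        assert np.all(let.letd == 1.3)

    def test_shape_matches_inverse_residual_range_law(self, beam150):
        """The spike follows (R0 - z + c)^(-q) exactly (closed-form check)."""
        z = np.arange(0.0, 150.0, 0.5)
        let = pm.letd_proxy(beam150, z)
        r0 = beam150.range_mm
        expected = entrance_letd(150.0) + 0.25 * (r0 - z + 0.1) ** -1.5
        np.testing.assert_allclose(let.letd, expected, rtol=1e-12)


class TestQuenching:
    def test_k_zero_identity(self, beam150):
        z = np.arange(0.25, 160.0, 0.5)
        pdd = pm.bragg_pdd(beam150, z)
        let = pm.letd_proxy(beam150, z)
        out = pm.apply_quenching(pdd, let, pm.QuenchModel(k=0.0))
        np.testing.assert_array_equal(out.dose, pdd.dose)

    def test_constant_let_at_reference_is_identity(self, beam150):
        z = np.arange(0.25, 160.0, 0.5)
        pdd = pm.bragg_pdd(beam150, z)
        let = pm.letd_proxy(beam150, z, constant=0.9)
        out = pm.apply_quenching(pdd, let, pm.QuenchModel(k=0.05, let_ref=0.9))
        np.testing.assert_allclose(out.dose, pdd.dose, rtol=1e-12)

    def test_never_increases_dose(self, beam150):
        z = np.arange(0.25, 170.0, 0.5)
        pdd = pm.bragg_pdd(beam150, z)
        let = pm.letd_proxy(beam150, z)
        out = pm.apply_quenching(pdd, let, pm.QuenchModel(k=0.04, let_ref=5.0))
        assert np.all(out.dose <= pdd.dose + 1e-12)

    def test_let_coverage_required(self, beam150):
        pdd = pm.bragg_pdd(beam150, np.arange(0.0, 160.0, 0.5))
        short_let = pm.letd_proxy(beam150, np.arange(0.0, 100.0, 0.5))
        with pytest.raises(ValueError, match="cover"):
            pm.apply_quenching(pdd, short_let, pm.QuenchModel())

    def test_grid_quenching_matches_column_quenching(self, shallow_grid, beam150):
        let = pm.letd_proxy(beam150, shallow_grid.z_coords)
        q = pm.QuenchModel(k=0.03)
        qgrid = pm.apply_quenching(shallow_grid, let, q)
        col = shallow_grid.depth_profile(0.0)
        qcol = pm.apply_quenching(col, let, q)
        np.testing.assert_allclose(qgrid.depth_profile(0.0).dose, qcol.dose, rtol=1e-9)


class TestFilmDigitizeDeterminism:
    def test_same_seed_bit_identical(self, shallow_grid):
        a = pm.film_digitize(shallow_grid, noise_sd=0.01, seed=7)
        b = pm.film_digitize(shallow_grid, noise_sd=0.01, seed=7)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_different_seed_differs(self, shallow_grid):
        a = pm.film_digitize(shallow_grid, noise_sd=0.01, seed=7)
        b = pm.film_digitize(shallow_grid, noise_sd=0.01, seed=8)
        assert np.any(a.pixels != b.pixels)
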