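"""Peak/valley detection, PVDR, central averages, detector footprints."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pmbrt as pm
from conftest import make_comb_profile
from pmbrt.profiles import PeakValleySet


class TestFindPeaksValleys:
    def test_engine_comb_five_peaks_four_valleys(self, fine_comb, collimator):
        pv = pm.find_peaks_valleys(fine_comb, collimator.ctc)
        assert pv.n_peaks == 5
        assert len(pv.valley_x) == 4
        assert np.abs(np.diff(pv.peak_x) - collimator.ctc).max() < 0.05

    def test_flat_profile_rejected(self):
        p = pm.Profile1D(np.linspace(-10, 10, 201), np.full(201, 3.0))
        with pytest.raises(ValueError, match="comb"):
            pm.find_peaks_valleys(p, 2.8)

    def test_single_gaussian_one_peak_no_valleys(self):
        x = np.linspace(-10, 10, 401)
        p = pm.Profile1D(x, np.exp(-x ** 2 / 2.0))
        pv = pm.find_peaks_valleys(p, 2.8)
        assert pv.n_peaks == 1
        assert len(pv.valley_x) == 0

    def test_short_profile_rejected(self):
        p = pm.Profile1D(np.linspace(0, 3, 31), np.sin(np.linspace(0, 3, 31)) + 2)
        with pytest.raises(ValueError, match="span"):
            pm.find_peaks_valleys(p, 2.8)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.01, 100.0),
        shift=st.floats(-5.0, 5.0),
    )
    def test_invariant_to_scaling_and_translation(self, scale, shift, fine_comb, collimator):
        """Peak/valley locations move with the profile and ignore dose scale."""
        base = pm.find_peaks_valleys(fine_comb, collimator.ctc)
        moved = pm.Profile1D(fine_comb.x + shift, fine_comb.dose * scale)
        pv = pm.find_peaks_valleys(moved, collimator.ctc)
        np.testing.assert_allclose(pv.peak_x - shift, base.peak_x, atol=1e-9)
        np.testing.assert_allclose(pv.peak_dose, base.peak_dose * scale, rtol=1e-9)


class TestPVDRProfile:
    def test_simple_ratio(self):
        pv = PeakValleySet(
            peak_x=np.array([0.0, 2.8, 5.6]), peak_dose=np.array([10.0, 10.0, 10.0]),
            valley_x=np.array([1.4, 4.2]), valley_dose=np.array([5.0, 5.0]),
        )
        ratio, info = pm.pvdr_profile(pm.Profile1D([0, 1], [1, 1]), pv)
        assert ratio == pytest.approx(2.0)
        # tie-break lands on the central peak, which has two adjacent valleys
        assert info["peak_index"] == 1
        assert not info["single_valley"]

    def test_flat_comb_gives_unity(self):
        pv = PeakValleySet(
            peak_x=np.array([0.0, 2.8]), peak_dose=np.array([10.0, 10.0]),
            valley_x=np.array([1.4]), valley_dose=np.array([10.0]),
        )
        ratio, _ = pm.pvdr_profile(pm.Profile1D([0, 1], [1, 1]), pv)
        assert ratio == pytest.approx(1.0)

    def test_outermost_peak_uses_single_valley(self):
        pv = PeakValleySet(
            peak_x=np.array([0.0, 2.8]), peak_dose=np.array([12.0, 10.0]),
            valley_x=np.array([1.4]), valley_dose=np.array([4.0]),
        )
        ratio, info = pm.pvdr_profile(pm.Profile1D([0, 1], [1, 1]), pv)
        assert ratio == pytest.approx(3.0)
        assert info["single_valley"]

    def test_toy_profile_against_exhaustive_oracle(self):
        """7-point comb: brute-force extremum labelling agrees with the pipeline."""
        x = np.arange(7, dtype=float)
        d = np.array([1.0, 9.0, 2.0, 8.0, 3.0, 10.0, 1.0])
        # oracle: enumerate interior extrema directly
        peaks = [i for i in range(1, 6) if d[i] > d[i - 1] and d[i] > d[i + 1]]
        valleys = [i for i in range(1, 6) if d[i] < d[i - 1] and d[i] < d[i + 1]]
        j = max(peaks, key=lambda i: d[i])
        adj = [v for v in valleys if abs(peaks.index(j) * 2 - valleys.index(v) * 2) <= 2
               and (v == j - 1 or v == j + 1 or abs(v - j) == 1)]
        adj = [v for v in valleys if abs(v - j) <= 2 and v != j]
        oracle = d[j] / np.mean([d[v] for v in adj])
        prof = pm.Profile1D(x, d)
        pv = pm.find_peaks_valleys(prof, expected_ctc=1.6)
        ratio, _ = pm.pvdr_profile(prof, pv)
        assert ratio == pytest.approx(oracle)


class TestPVDRvsDepth:
    def test_separable_grid_constant_pvdr(self, beam150, collimator):
        """D(x,z) = f(x) g(z) gives a depth-independent PVDR equal to f's own."""
        prof = make_comb_profile(beam150, collimator, pitch=0.1, span=10.0, amplitude=1.0)
        g = np.linspace(1.0, 3.0, 50)
        grid = pm.DoseGrid2D(prof.x, np.linspace(0, 49, 50), np.outer(prof.dose, g))
        pv = pm.find_peaks_valleys(prof, collimator.ctc)
        expected, _ = pm.pvdr_profile(prof, pv)
        curve = pm.pvdr_vs_depth(grid, collimator, depths=[5.0, 20.0, 45.0])
        np.testing.assert_allclose(curve.pvdr, expected, rtol=0.01)

    def test_engine_pvdr_trend_with_depth(self, minibeam_grid, collimator):
        """PVDR >= 1, strictly falling while the combs are distinct, ~1 at 10 cm."""
        depths = np.arange(10.0, 101.0, 10.0)
        curve = pm.pvdr_vs_depth(minibeam_grid, collimator, depths)
        assert np.all(curve.pvdr >= 1.0 - 0.01)
        merged = curve.pvdr <= 1.01
        assert np.all(np.diff(curve.pvdr[~merged]) < 0)  # modulated region decays
        assert np.all(np.abs(curve.pvdr[merged] - 1.0) <= 0.01)  # merged region ~ 1
        assert curve.pvdr[-1] == pytest.approx(1.0, abs=0.01)

    def test_swapping_columns_inverts_ratio(self, minibeam_grid, collimator):
        curve = pm.pvdr_vs_depth(minibeam_grid, collimator, [10.0])
        xp = curve.meta["peak_column_mm"]
        xv = curve.meta["valley_columns_mm"]
        peak = minibeam_grid.depth_profile(xp).interp(10.0)
        valley = np.mean([minibeam_grid.depth_profile(x).interp(10.0) for x in xv])
        assert valley / peak == pytest.approx(1.0 / curve.pvdr[0], rel=1e-6)

    def test_depths_beyond_range_masked(self, beam150, collimator):
        grid_spec = pm.PhantomGridSpec(x_extent=60.0, z_extent=178.0, air_gap=60.0)
        grid = pm.minibeam_dose(beam150, collimator, grid_spec)
        curve = pm.pvdr_vs_depth(grid, collimator, [10.0, 176.0])
        assert np.isfinite(curve.pvdr[0])
        assert np.isnan(curve.pvdr[1])


class TestAverageCentralDose:
    def test_uniform_profile(self):
        p = pm.Profile1D(np.linspace(-10, 10, 401), np.full(401, 7.0))
        assert pm.average_central_dose(p, 2.8) == pytest.approx(7.0)

    def test_ignores_dose_outside_window(self, fine_comb, collimator):
        base = pm.average_central_dose(fine_comb, collimator.ctc)
        perturbed = fine_comb.dose.copy()
        outside = np.abs(fine_comb.x) > 1.5 * collimator.ctc + 1.0
        perturbed[outside] *= 3.0
        p2 = pm.Profile1D(fine_comb.x, perturbed)
        assert pm.average_central_dose(p2, collimator.ctc) == pytest.approx(base, rel=1e-9)

    def test_window_exceeding_profile_rejected(self):
        p = pm.Profile1D(np.linspace(-2, 2, 81), np.full(81, 1.0))
        with pytest.raises(ValueError, match="window"):
            pm.average_central_dose(p, 2.8)

    def test_face_on_scan_preserves_central_average(self, fine_comb, collimator):
        """Footprint averaging moves dose locally: the 3-ctc mean survives within 2%."""
        face = pm.volume_average(fine_comb, pm.microdiamond("face_on"))
        a = pm.average_central_dose(fine_comb, collimator.ctc)
        b = pm.average_central_dose(face, collimator.ctc)
        assert abs(b - a) / a < 0.02


class TestVolumeAverage:
    def test_narrow_kernel_is_identity(self, fine_comb):
        out = pm.volume_average(fine_comb, pm.microdiamond("edge_on"))
        np.testing.assert_array_equal(out.dose, fine_comb.dose)

    def test_face_on_flattens_comb(self, fine_comb, collimator):
        """4 mm disc on a 2.8 mm-period comb: PVDR collapses below 1.3."""
        true_pv = pm.find_peaks_valleys(fine_comb, collimator.ctc)
        true_ratio, _ = pm.pvdr_profile(fine_comb, true_pv)
        face = pm.volume_average(fine_comb, pm.microdiamond("face_on"))
        face_pv = pm.find_peaks_valleys(face, collimator.ctc)
        face_ratio, _ = pm.pvdr_profile(face, face_pv)
        assert true_ratio > 4.0
        assert face_ratio < 1.3

    def test_against_direct_convolution_oracle(self, fine_comb):
        """Chord-weighted disc kernel vs an explicit quadrature integral."""
        det = pm.razor_diode("face_on")
        out = pm.volume_average(fine_comb, det)
        radius = det.diameter / 2.0
        for x0 in (-1.4, 0.0, 0.7):
            u = np.linspace(-radius, radius, 4001)
            w = np.sqrt(radius ** 2 - u ** 2)
            oracle = np.trapezoid(w * fine_comb.interp(x0 + u), u) / np.trapezoid(w, u)
            assert out.interp(x0) == pytest.approx(oracle, rel=2e-3)

    def test_period_mean_conserved(self, fine_comb, collimator):
        face = pm.volume_average(fine_comb, pm.microdiamond("face_on"))
        sel = np.abs(fine_comb.x) <= 1.5 * collimator.ctc
        a = fine_comb.dose[sel].mean()
        b = face.dose[sel].mean()
        assert abs(b - a) / a < 0.02
        assert face.dose.max() < fine_comb.dose.max()

    def test_coarse_sampling_rejected(self, collimator, beam150):
        coarse = make_comb_profile(beam150, collimator, pitch=0.2)
        with pytest.raises(ValueError, match="coarse"):
            pm.volume_average(coarse, pm.microdiamond("face_on"))

    def test_nonuniform_sampling_rejected(self):
        x = np.concatenate([np.linspace(0, 1, 50), np.linspace(1.1, 3, 50)])
        p = pm.Profile1D(np.unique(x), np.ones(np.unique(x).size))
        with pytest.raises(ValueError, match="uniform"):
            pm.volume_average(p, pm.microdiamond("face_on"))


class TestDetectorDepthCorrection:
    @pytest.mark.parametrize("nominal,expected", [(45.0, 47.0), (65.0, 67.0)])
    def test_microdiamond_edge_on_offsets(self, nominal, expected):
        """4 mm disc scanned edge-on: proximal face to centre is +2 mm."""
        assert pm.detector_depth_correction(nominal, pm.microdiamond()) == expected

    def test_face_on_uses_half_thickness(self):
        det = pm.microdiamond("face_on")
        assert pm.detector_depth_correction(45.0, det) == pytest.approx(45.0005)

    def test_zero_size_custom_detector_identity(self):
        det = pm.DetectorSpec("custom", 0.0, 0.0)
        assert pm.detector_depth_correction(12.0, det) == 12.0

    def test_invalid_detector_rejected(self):
        with pytest.raises(ValueError):
            pm.DetectorSpec("microDiamond", 0.001, 4.0)
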