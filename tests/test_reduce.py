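"""Per-frame reduction operations: masking, errors, corrections, binning."""

import numpy as np
import pytest

from powderchain.errors import ReductionError
from powderchain.geometry import DetectorSpec, DiffractionGeometry, q_map
from powderchain.reduce import (
    Frame,
    cake_remap,
    correct_polarization,
    correct_solid_angle,
    divide,
    estimate_errors,
    integrate_azimuthal,
    kahn_polarization,
    solid_angle_factor,
    subtract_radial_background,
    threshold_mask,
)


@pytest.fixture()
def random_frame(rng):
    return Frame(counts=rng.uniform(0, 1000, (64, 64)))


class TestThresholdMask:
    def test_in_range_image_unchanged(self):
        f = Frame(counts=np.full((32, 32), 50.0))
        out = threshold_mask(f, 0.0, 100.0)
        assert not out.mask.any()
        assert np.array_equal(out.counts, f.counts)

    def test_single_saturated_pixel_masked(self):
        counts = np.full((32, 32), 50.0)
        counts[3, 7] = 1e7
        out = threshold_mask(Frame(counts=counts), 0.0, 1e6)
        assert out.mask.sum() == 1
        assert out.mask[3, 7]

    def test_matches_brute_force_enumeration(self, random_frame):
        lo, hi = 200.0, 800.0
        out = threshold_mask(random_frame, lo, hi)
        expected = sum(
            1
            for v in random_frame.counts.ravel()
            if v < lo or v > hi
        )
        assert out.mask.sum() == expected

    def test_all_masked_is_an_error(self):
        with pytest.raises(ReductionError):
            threshold_mask(Frame(counts=np.zeros((32, 32))), 1.0, 2.0)


class TestEstimateErrors:
    @pytest.mark.parametrize(
        "counts,gain,expected",
        [(100.0, 1.0, 10.0), (0.0, 1.0, 1.0), (200.0, 2.0, 20.0)],
    )
    def test_poisson_with_floor(self, counts, gain, expected):
        f = Frame(counts=np.full((32, 32), counts))
        out = estimate_errors(f, gain=gain)
        assert np.all(out.errors == expected)

    def test_negative_unmasked_counts_rejected(self):
        counts = np.zeros((32, 32))
        counts[0, 0] = -5
        with pytest.raises(ReductionError):
            estimate_errors(Frame(counts=counts))
        mask = np.zeros((32, 32), bool)
        mask[0, 0] = True
        estimate_errors(Frame(counts=counts, mask=mask))  # masked: fine


class TestCorrections:
    def test_solid_angle_unity_at_beam_centre(self, geometry_small):
        factor = solid_angle_factor(geometry_small)
        # beam centre (31.5, 31.5) sits between the four central pixels
        assert factor[31, 31] == pytest.approx(1.0, rel=1e-4)

    def test_solid_angle_is_cos_cubed_at_60_degrees(self):
        # construct a pixel exactly at 2theta = 60 deg on an untilted detector
        pix = 100.0 * np.tan(np.deg2rad(60.0)) / 100.0  # lands on index 100
        det = DetectorSpec(16, 128, pixel_size_slow=pix, pixel_size_fast=pix)
        g = DiffractionGeometry(100.0, 0.0, 0.0, 0.0, 0.0, 1.0, det)
        factor = solid_angle_factor(g)
        assert factor[0, 100] == pytest.approx(8.0, rel=1e-12)

    def test_solid_angle_monotone_with_radius_untilted(self, geometry_small):
        factor = solid_angle_factor(geometry_small)
        row = factor[31, 32:]
        assert np.all(np.diff(row) > 0)

    def test_polarization_closed_forms(self):
        assert kahn_polarization(0.0, 0.0, 0.7) == pytest.approx(1.0, abs=1e-15)
        assert kahn_polarization(90.0, 45.0, 0.0) == pytest.approx(0.5, abs=1e-15)
        assert kahn_polarization(90.0, 0.0, 1.0) == pytest.approx(0.0, abs=1e-15)

    def test_polarization_singularity_masks_pixel(self):
        det = DetectorSpec(16, 128, 1.0, 1.0)
        g = DiffractionGeometry(10.0, 0.0, 8.0, 0.0, 0.0, 1.0, det)
        f = Frame(counts=np.ones((16, 128)))
        out = correct_polarization(f, g, 1.0)
        # chi = 0 row at large 2theta approaches the P -> 0 singularity
        assert out.counts[~out.mask].max() < 1e9

    def test_corrections_commute(self, geometry_small, rng):
        f = Frame(counts=rng.uniform(1, 10, (64, 64)),
                  errors=rng.uniform(0.1, 1, (64, 64)))
        a = correct_polarization(correct_solid_angle(f, geometry_small),
                                 geometry_small, 0.5)
        b = correct_solid_angle(correct_polarization(f, geometry_small, 0.5),
                                geometry_small)
        assert np.allclose(a.counts, b.counts, rtol=1e-12)
        assert np.allclose(a.errors, b.errors, rtol=1e-12)


class TestDivide:
    def test_by_one_is_identity(self, random_frame):
        out = divide(random_frame, 1.0)
        assert np.array_equal(out.counts, random_frame.counts)

    def test_by_metadata_monitor(self):
        f = Frame(counts=np.full((32, 32), 10.0),
                  errors=np.full((32, 32), 2.0),
                  metadata={"monitor": 2.0})
        out = divide(f, "monitor")
        assert np.all(out.counts == 5.0)
        assert np.all(out.errors == 1.0)

    def test_missing_metadata_key(self, random_frame):
        with pytest.raises(ReductionError):
            divide(random_frame, "monitor")

    def test_zero_scalar_rejected(self, random_frame):
        with pytest.raises(ReductionError):
            divide(random_frame, 0.0)

    def test_frame_by_frame_quadrature(self):
        a = Frame(counts=np.full((8, 8), 10.0), errors=np.full((8, 8), 1.0))
        b = Frame(counts=np.full((8, 8), 2.0), errors=np.full((8, 8), 0.2))
        out = divide(a, b)
        assert np.all(out.counts == 5.0)
        expected = 5.0 * np.sqrt(0.01 + 0.01)
        assert np.allclose(out.errors, expected, rtol=1e-12)


class TestIntegrateAzimuthal:
    def test_constant_image_gives_flat_profile(self, geometry_small):
        f = Frame(counts=np.full((64, 64), 42.0))
        prof = integrate_azimuthal(f, geometry_small, n_bins=20)
        assert np.allclose(prof.intensity[prof.valid], 42.0, rtol=1e-12)

    def test_bitwise_equal_to_per_pixel_histogram_loop(self, geometry_small,
                                                       rng):
        f = Frame(counts=rng.uniform(0, 100, (64, 64)),
                  errors=rng.uniform(0.1, 2.0, (64, 64)))
        n_bins = 37
        prof = integrate_azimuthal(f, geometry_small, n_bins=n_bins,
                                   splitting="none")
        qm = q_map(geometry_small)
        lo, hi = prof.metadata["radial_range"]
        width = (hi - lo) / n_bins
        sums = np.zeros(n_bins)
        esums = np.zeros(n_bins)
        counts = np.zeros(n_bins)
        for i in range(64):
            for j in range(64):
                r = qm[i, j]
                if r < lo or r > hi:
                    continue
                b = min(int((r - lo) / width), n_bins - 1)
                sums[b] += f.counts[i, j]
                esums[b] += f.errors[i, j] ** 2
                counts[b] += 1.0
        expected = np.where(counts > 0, sums / np.where(counts > 0, counts, 1),
                            np.nan)
        expected_err = np.where(
            counts > 0, np.sqrt(esums) / np.where(counts > 0, counts, 1), np.nan)
        assert np.array_equal(prof.intensity, expected, equal_nan=True)
        assert np.array_equal(prof.errors, expected_err, equal_nan=True)
        assert np.array_equal(prof.bin_counts, counts)

    def test_bbox_weight_conservation(self, geometry_small, rng):
        f = Frame(counts=rng.uniform(0, 100, (64, 64)))
        f.mask[10:20, 30:40] = True
        prof = integrate_azimuthal(f, geometry_small, n_bins=50,
                                   splitting="bbox")
        n_unmasked = (~f.mask).sum()
        assert prof.bin_counts.sum() == pytest.approx(n_unmasked, rel=1e-9)

    def test_bbox_conserves_total_intensity(self, geometry_small, rng):
        f = Frame(counts=rng.uniform(0, 100, (64, 64)))
        prof = integrate_azimuthal(f, geometry_small, n_bins=50,
                                   splitting="bbox")
        total = np.nansum(prof.intensity * prof.bin_counts)
        assert total == pytest.approx(f.counts.sum(), rel=1e-9)

    def test_single_ring_peak_at_2pi_over_d(self, detector512):
        from powderchain.calibrant import Calibrant
        from powderchain.synthetic import RingRenderSpec, render_calibration_image

        g = DiffractionGeometry(300.0, 255.5, 255.5, 0.0, 0.0, 1.0, detector512)
        cal = Calibrant("one", np.array([3.5]))
        frame = render_calibration_image(
            RingRenderSpec(geometry=g, calibrant=cal, background=0.0))
        prof = integrate_azimuthal(frame, g, n_bins=300)
        peak_q = prof.bin_centres[np.nanargmax(prof.intensity)]
        half_bin = np.diff(prof.bin_centres).mean() / 2
        assert abs(peak_q - 2 * np.pi / 3.5) <= half_bin

    def test_equal_value_pixels_give_sigma_over_sqrt_n(self, geometry_small):
        f = Frame(counts=np.full((64, 64), 5.0), errors=np.full((64, 64), 3.0))
        prof = integrate_azimuthal(f, geometry_small, n_bins=2,
                                   radial_range=(0.0, 50.0))
        v = prof.bin_counts > 0
        assert np.allclose(prof.errors[v],
                           3.0 / np.sqrt(prof.bin_counts[v]), rtol=1e-12)

    def test_masked_pixel_values_are_irrelevant(self, geometry_small, rng):
        f = Frame(counts=rng.uniform(0, 100, (64, 64)))
        f.mask[5:25, 5:25] = True
        ref = integrate_azimuthal(f, geometry_small, n_bins=30,
                                  radial_range=(0.0, 7.0))
        fuzzed = f.copy()
        fuzzed.counts[fuzzed.mask] = rng.uniform(-1e9, 1e9,
                                                 int(fuzzed.mask.sum()))
        for split in ("none", "bbox"):
            a = integrate_azimuthal(f, geometry_small, n_bins=30,
                                    radial_range=(0.0, 7.0), splitting=split)
            b = integrate_azimuthal(fuzzed, geometry_small, n_bins=30,
                                    radial_range=(0.0, 7.0), splitting=split)
            assert np.array_equal(a.intensity, b.intensity, equal_nan=True)

    def test_empty_selection_rejected(self, geometry_small):
        f = Frame(counts=np.ones((64, 64)),
                  mask=np.ones((64, 64), bool))
        with pytest.raises(ReductionError):
            integrate_azimuthal(f, geometry_small, n_bins=10)

    def test_radial_units_2theta_and_d(self, geometry_small, rng):
        f = Frame(counts=rng.uniform(1, 2, (64, 64)))
        for unit in ("2theta", "d"):
            prof = integrate_azimuthal(f, geometry_small, n_bins=20,
                                       radial_unit=unit)
            assert prof.radial_unit == unit
            assert np.any(prof.valid)


class TestCakeRemap:
    def test_single_azimuth_bin_equals_integration(self, geometry_small, rng):
        f = Frame(counts=rng.uniform(0, 50, (64, 64)),
                  errors=rng.uniform(0.1, 1, (64, 64)))
        prof = integrate_azimuthal(f, geometry_small, n_bins=25)
        cake = cake_remap(f, geometry_small, n_radial=25, n_azimuthal=1,
                          radial_range=prof.metadata["radial_range"])
        assert np.array_equal(cake.intensity[0], prof.intensity,
                              equal_nan=True)

    @pytest.mark.parametrize("split", ["none", "bbox"])
    def test_chi_weighted_collapse_matches_integration(self, geometry_small,
                                                       rng, split):
        f = Frame(counts=rng.uniform(0, 50, (64, 64)),
                  errors=rng.uniform(0.1, 1, (64, 64)))
        prof = integrate_azimuthal(f, geometry_small, n_bins=25,
                                   splitting=split)
        cake = cake_remap(f, geometry_small, n_radial=25, n_azimuthal=9,
                          splitting=split,
                          radial_range=prof.metadata["radial_range"])
        wsum = cake.weights.sum(axis=0)
        num = np.where(cake.weights > 0, cake.weights * cake.intensity, 0.0)
        collapse = num.sum(axis=0) / np.where(wsum > 0, wsum, 1.0)
        both = (prof.bin_counts > 0) & (wsum > 0)
        rel = np.abs(collapse[both] - prof.intensity[both]) / np.abs(
            prof.intensity[both])
        assert rel.max() < 1e-9

    def test_azimuth_coverage_weight_equals_pixel_count(self, geometry_small,
                                                        rng):
        f = Frame(counts=rng.uniform(0, 50, (64, 64)))
        f.mask[::7, ::5] = True
        cake = cake_remap(f, geometry_small, n_radial=30, n_azimuthal=12,
                          splitting="none")
        assert cake.weights.sum() == pytest.approx((~f.mask).sum(), rel=1e-12)

    def test_ideal_ring_ridge_constant_across_azimuth(self, detector512):
        from powderchain.calibrant import Calibrant
        from powderchain.synthetic import RingRenderSpec, render_calibration_image

        g = DiffractionGeometry(300.0, 255.5, 255.5, 0.0, 0.0, 1.0, detector512)
        cal = Calibrant("one", np.array([3.5]))
        frame = render_calibration_image(
            RingRenderSpec(geometry=g, calibrant=cal, background=0.0))
        cake = cake_remap(frame, g, n_radial=120, n_azimuthal=24,
                          radial_range=(1.0, 2.5))
        ridge = np.nanargmax(np.where(cake.weights > 0, cake.intensity,
                                      -np.inf), axis=1)
        rows = cake.weights.sum(axis=1) > 0
        assert np.ptp(ridge[rows]) <= 1

    def test_partial_azimuth_window_crossing_seam(self, geometry_small, rng):
        f = Frame(counts=rng.uniform(1, 2, (64, 64)))
        cake = cake_remap(f, geometry_small, n_radial=10, n_azimuthal=4,
                          azimuth_range=(150.0, 210.0))
        assert cake.weights.sum() > 0
        # only pixels with chi in the wrapped 60-degree window contribute
        from powderchain.geometry import chi_map

        chi = chi_map(geometry_small)
        in_window = (chi >= 150.0) | (chi <= -150.0)
        assert cake.weights.sum() == pytest.approx(in_window.sum(), rel=1e-12)


class TestBackgroundSubtraction:
    def test_zero_iterations_is_identity(self, geometry_small, rng):
        f = Frame(counts=rng.uniform(0, 10, (64, 64)))
        out = subtract_radial_background(f, geometry_small, iterations=0)
        assert np.array_equal(out.counts, f.counts)

    def test_smooth_profile_residual_near_zero(self):
        from powderchain.reduce import RadialProfile

        x = np.linspace(1, 5, 200)
        prof = RadialProfile("q", x, 100.0 + 10.0 * x,
                             errors=np.full(200, 0.1))
        out = subtract_radial_background(prof, iterations=20, window=20)
        # away from the smoothing-window edge effects the envelope equals
        # the peak-free profile
        assert np.max(np.abs(out.intensity[30:-30])) < 1.0

    def test_peak_area_preserved_within_2_percent(self):
        from powderchain.reduce import RadialProfile

        x = np.linspace(1, 9, 800)
        sigma = 0.15
        peak = 500.0 * np.exp(-((x - 5.0) ** 2) / (2 * sigma**2))
        prof = RadialProfile("q", x, 40.0 + 6.0 * x + peak,
                             errors=np.full(800, 1.0))
        out = subtract_radial_background(prof, iterations=60, clip_factor=1.0)
        dx = x[1] - x[0]
        area = out.intensity[np.abs(x - 5.0) < 1.0].sum() * dx
        true_area = 500.0 * sigma * np.sqrt(2 * np.pi)
        assert area == pytest.approx(true_area, rel=0.02)
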