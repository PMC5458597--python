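"""Geometry refinement and the three calibration routes."""

import numpy as np
import pytest

from powderchain.calibrant import Calibrant
from powderchain.calibrate import (
    calibrate_auto_single,
    calibrate_manual,
    load_calibration,
    refine_geometry,
    save_calibration,
    solve_multi_distance,
)
from powderchain.errors import (
    CalibrationError,
    FileFormatError,
    RingFindError,
    SingularCalibration,
)
from powderchain.geometry import DetectorSpec, DiffractionGeometry, predict_ring
from powderchain.ringfind import RingPointSet
from powderchain.synthetic import (
    RingRenderSpec,
    render_calibration_image,
    render_distance_series,
)


def exact_point_sets(geom, d_spacings, n=64):
    """Noiseless ring point sets lying exactly on the predicted conics."""
    sets = []
    for i, d in enumerate(d_spacings):
        conic = predict_ring(geom, d)
        f, s = conic.sample(n)
        sets.append(RingPointSet(i, d, np.column_stack([f, s]), np.full(n, 1e4)))
    return sets


@pytest.fixture(scope="module")
def truth_geometry(detector512):
    return DiffractionGeometry(300.0, 250.0, 262.0, 1.2, -0.8, 0.7, detector512)


class TestRefineGeometry:
    def test_already_optimal_input_stays_put(self, truth_geometry):
        sets = exact_point_sets(truth_geometry, [2.7, 2.3, 1.9, 1.6, 1.35])
        res = refine_geometry(sets, truth_geometry, fixed=("wavelength",))
        assert res.residual_rms_q < 1e-10
        assert res.geometry.distance == pytest.approx(300.0, rel=1e-10)
        assert set(res.uncertainties) | set(res.fixed_parameters) == {
            "distance", "beam_centre_fast", "beam_centre_slow",
            "tilt_pitch", "tilt_yaw", "wavelength",
        }

    def test_recovery_from_perturbed_start(self, truth_geometry):
        sets = exact_point_sets(truth_geometry, [2.7, 2.3, 1.9, 1.6, 1.35])
        start = truth_geometry.replace(
            distance=300.0 * 1.05,
            tilt_pitch=truth_geometry.tilt_pitch + 2.0,
            beam_centre_fast=truth_geometry.beam_centre_fast + 3.0,
        )
        res = refine_geometry(sets, start, fixed=("wavelength",))
        g = res.geometry
        assert g.distance == pytest.approx(300.0, rel=1e-4)
        assert g.beam_centre_fast == pytest.approx(250.0, abs=1e-3)
        assert g.tilt_pitch == pytest.approx(1.2, abs=1e-4)

    def test_distance_wavelength_degeneracy_single_ring(self, truth_geometry):
        sets = exact_point_sets(truth_geometry, [2.7])
        with pytest.raises(SingularCalibration) as err:
            refine_geometry(sets, truth_geometry, fixed=())
        assert {"distance", "wavelength"} & set(err.value.parameters)

    def test_too_few_points_rejected(self, truth_geometry):
        # 6 points cannot constrain 5 free parameters (need >= 2 + n_free)
        sets = exact_point_sets(truth_geometry, [2.7], n=6)
        with pytest.raises(CalibrationError):
            refine_geometry(sets, truth_geometry, fixed=("wavelength",))

    def test_full_free_refinement_reports_six_parameters(self, truth_geometry):
        sets = exact_point_sets(truth_geometry, [2.7, 2.3, 1.9, 1.35, 1.1, 0.95])
        res = refine_geometry(sets, truth_geometry, fixed=())
        assert len(res.uncertainties) == 6
        assert res.fixed_parameters == ()

    def test_agrees_with_grid_search_on_2d_slice(self, truth_geometry):
        # brute-force grid over (distance, pitch) with the other four
        # parameters clamped must place the optimum at the refined solution
        sets = exact_point_sets(truth_geometry, [2.7, 1.9, 1.35])
        fixed = ("beam_centre_fast", "beam_centre_slow", "tilt_yaw", "wavelength")
        res = refine_geometry(sets, truth_geometry, fixed=fixed)

        from powderchain.geometry import pixel_to_angles

        def cost(dist, pitch):
            g = truth_geometry.replace(distance=dist, tilt_pitch=pitch)
            total = 0.0
            for ps in sets:
                q = pixel_to_angles(g, ps.points[:, 0], ps.points[:, 1]).q
                total += np.sum((q - 2 * np.pi / ps.d_spacing) ** 2)
            return total

        dists = np.linspace(299.9, 300.1, 21)
        pitches = np.linspace(1.1, 1.3, 21)
        grid = np.array([[cost(D, p) for p in pitches] for D in dists])
        i, j = np.unravel_index(np.argmin(grid), grid.shape)
        assert dists[i] == pytest.approx(res.geometry.distance, abs=0.011)
        assert pitches[j] == pytest.approx(res.geometry.tilt_pitch, abs=0.011)


class TestAutoSingle:
    def test_noiseless_recovery(self, detector512, ceria, truth_geometry):
        frame = render_calibration_image(
            RingRenderSpec(geometry=truth_geometry, calibrant=ceria, max_rings=5))
        res = calibrate_auto_single(frame, detector512, ceria, wavelength=0.7)
        g = res.geometry
        assert abs(g.distance - 300.0) / 300.0 < 1e-3
        assert abs(g.beam_centre_fast - 250.0) < 0.2
        assert abs(g.beam_centre_slow - 262.0) < 0.2
        assert abs(g.tilt_pitch - 1.2) < 0.05
        assert abs(g.tilt_yaw + 0.8) < 0.05
        assert res.routine == "auto_single"

    def test_beam_centre_off_detector_points_to_manual_route(self, detector512,
                                                             ceria):
        geom = DiffractionGeometry(250.0, -300.0, 256.0, 0.0, 0.0, 0.7,
                                   detector512)
        frame = render_calibration_image(
            RingRenderSpec(geometry=geom, calibrant=ceria, max_rings=8))
        with pytest.raises((RingFindError, CalibrationError)):
            calibrate_auto_single(frame, detector512, ceria, wavelength=0.7)

    def test_low_angle_only_with_free_wavelength_is_ambiguous(self, detector512):
        # two rings spanning < 5 degrees cannot separate distance from
        # wavelength: the refinement must report the degeneracy, not a number
        cal = Calibrant("lowq", np.array([20.0, 14.0]))
        geom = DiffractionGeometry(900.0, 256.0, 256.0, 0.0, 0.0, 0.7,
                                   detector512)
        frame = render_calibration_image(
            RingRenderSpec(geometry=geom, calibrant=cal))
        with pytest.raises((SingularCalibration, RingFindError)):
            calibrate_auto_single(frame, detector512, cal, wavelength=None)


class TestMultiDistance:
    def test_two_distance_one_ring_closed_form(self, detector512):
        # r = (D0 + delta) tan(2theta): two distances determine D0 exactly
        cal = Calibrant("one", np.array([3.0]))
        geom = DiffractionGeometry(200.0, 256.0, 256.0, 0.0, 0.0, 0.9,
                                   detector512)
        frames = render_distance_series(
            RingRenderSpec(geometry=geom, calibrant=cal), [0.0, 40.0])
        res = solve_multi_distance(
            list(zip(frames, [0.0, 40.0])), detector512, cal,
            wavelength_known=0.9)
        assert res.geometry.distance == pytest.approx(200.0, rel=1e-3)
        assert res.routine == "auto_multi"

    def test_five_distances_free_wavelength(self, detector512, ceria):
        geom = DiffractionGeometry(300.0, 258.0, 251.0, 0.0, 0.0, 0.7,
                                   detector512)
        deltas = [0.0, 20.0, 40.0, 60.0, 80.0]
        frames = render_distance_series(
            RingRenderSpec(geometry=geom, calibrant=ceria, max_rings=4), deltas)
        res = solve_multi_distance(list(zip(frames, deltas)), detector512, ceria)
        assert abs(res.geometry.distance - 300.0) / 300.0 < 1e-3
        assert abs(res.geometry.wavelength - 0.7) / 0.7 < 1e-3
        assert "wavelength" in res.uncertainties

    def test_duplicate_increments_rejected(self, detector512, ceria):
        geom = DiffractionGeometry(300.0, 256.0, 256.0, 0.0, 0.0, 0.7,
                                   detector512)
        frames = render_distance_series(
            RingRenderSpec(geometry=geom, calibrant=ceria, max_rings=3),
            [0.0, 0.0])
        with pytest.raises(CalibrationError):
            solve_multi_distance(list(zip(frames, [0.0, 0.0])), detector512,
                                 ceria, wavelength_known=0.7)


class TestManual:
    def test_tilt45_partial_rings_from_perturbed_guess(self, detector512,
                                                       silicon):
        det = DetectorSpec(1024, 1024, 0.2, 0.2)
        truth = DiffractionGeometry(250.0, 200.0, 500.0, 45.0, 0.0, 1.0, det)
        frame = render_calibration_image(
            RingRenderSpec(geometry=truth, calibrant=silicon, max_rings=5))
        guess = truth.replace(
            distance=250.0 * 1.05, tilt_pitch=47.0,
            beam_centre_fast=205.0, beam_centre_slow=495.0)
        res = calibrate_manual(frame, det, silicon, guess, max_rings=5)
        g = res.geometry
        assert abs(g.distance - 250.0) / 250.0 < 1e-3
        assert abs(g.tilt_pitch - 45.0) < 0.1
        assert res.routine == "manual"

    def test_guess_equal_truth_converges_immediately(self, detector512, ceria,
                                                     truth_geometry):
        frame = render_calibration_image(
            RingRenderSpec(geometry=truth_geometry, calibrant=ceria,
                           max_rings=4))
        res = calibrate_manual(frame, detector512, ceria, truth_geometry,
                               max_rings=4)
        assert abs(res.geometry.distance - 300.0) / 300.0 < 1e-4

    def test_wildly_wrong_tilt_reports_ring_finding_failure(self, silicon):
        det = DetectorSpec(1024, 1024, 0.2, 0.2)
        truth = DiffractionGeometry(250.0, 200.0, 500.0, 45.0, 0.0, 1.0, det)
        frame = render_calibration_image(
            RingRenderSpec(geometry=truth, calibrant=silicon, max_rings=5))
        with pytest.raises((RingFindError, CalibrationError)):
            calibrate_manual(frame, det, silicon,
                             truth.replace(tilt_pitch=15.0), max_rings=5)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, detector512, ceria,
                                  truth_geometry):
        sets = exact_point_sets(truth_geometry, [2.7, 1.9, 1.35])
        res = refine_geometry(sets, truth_geometry, fixed=("wavelength",),
                              routine="manual", calibrant_name="CeO2_SRM674b")
        path = str(tmp_path / "cal.nxs")
        save_calibration(res, path)
        back = load_calibration(path)
        for name in ("distance", "beam_centre_fast", "beam_centre_slow",
                     "tilt_pitch", "tilt_yaw", "wavelength"):
            assert getattr(back.geometry, name) == pytest.approx(
                getattr(res.geometry, name), abs=1e-12)
        assert back.uncertainties == res.uncertainties
        assert back.routine == "manual"
        assert back.calibrant_name == "CeO2_SRM674b"
        assert back.fixed_parameters == ("wavelength",)

    def test_missing_wavelength_named_in_error(self, tmp_path, detector512,
                                               ceria, truth_geometry):
        import h5py

        sets = exact_point_sets(truth_geometry, [2.7, 1.9])
        res = refine_geometry(sets, truth_geometry, fixed=("wavelength",))
        path = str(tmp_path / "cal.nxs")
        save_calibration(res, path)
        with h5py.File(path, "a") as fh:
            del fh["entry/calibration/wavelength"]
        with pytest.raises(FileFormatError, match="wavelength"):
            load_calibration(path)

    def test_unreadable_file_rejected(self, tmp_path):
        p = tmp_path / "junk.nxs"
        p.write_text("not hdf5")
        with pytest.raises(FileFormatError):
            load_calibration(str(p))


class TestStatisticalProperties:
    def test_recovery_within_5_uncertainties_with_noise(self, detector512,
                                                        ceria):
        # a handful of noisy geometries here; the full 20-geometry sweep
        # lives in the acceptance suite
        rng = np.random.default_rng(42)
        for k in range(3):
            truth = DiffractionGeometry(
                distance=rng.uniform(250, 450),
                beam_centre_fast=rng.uniform(220, 290),
                beam_centre_slow=rng.uniform(220, 290),
                tilt_pitch=rng.uniform(-2, 2),
                tilt_yaw=rng.uniform(-2, 2),
                wavelength=0.7,
                detector=detector512,
            )
            frame = render_calibration_image(RingRenderSpec(
                geometry=truth, calibrant=ceria, max_rings=5,
                noise="poisson", seed=100 + k))
            res = calibrate_auto_single(frame, detector512, ceria,
                                        wavelength=0.7)
            for name, sigma in res.uncertainties.items():
                err = abs(getattr(res.geometry, name) - getattr(truth, name))
                assert err <= 5 * max(sigma, 1e-12), (name, err, sigma)

    def test_uncertainty_shrinks_with_point_count(self, detector512, ceria):
        truth = DiffractionGeometry(300.0, 255.0, 250.0, 0.5, -0.3, 0.7,
                                    detector512)
        frame = render_calibration_image(RingRenderSpec(
            geometry=truth, calibrant=ceria, max_rings=5, noise="poisson",
            seed=11))
        lo = calibrate_auto_single(frame, detector512, ceria, wavelength=0.7,
                                   n_profiles=64)
        hi = calibrate_auto_single(frame, detector512, ceria, wavelength=0.7,
                                   n_profiles=256)
        ratio_n = np.sqrt(hi.n_points / lo.n_points)
        ratio_sigma = (lo.uncertainties["distance"]
                       / hi.uncertainties["distance"])
        # 1/sqrt(n) scaling within a loose factor
        assert 0.5 * ratio_n < ratio_sigma < 2.0 * ratio_n

    def test_multi_distance_consistent_with_single_image(self, detector512,
                                                         ceria):
        truth = DiffractionGeometry(320.0, 254.0, 259.0, 0.0, 0.0, 0.7,
                                    detector512)
        deltas = [0.0, 30.0, 60.0]
        frames = render_distance_series(RingRenderSpec(
            geometry=truth, calibrant=ceria, max_rings=4, noise="poisson",
            seed=21), deltas)
        multi = solve_multi_distance(list(zip(frames, deltas)), detector512,
                                     ceria, wavelength_known=0.7)
        single = calibrate_auto_single(frames[0], detector512, ceria,
                                       wavelength=0.7)
        combined = np.hypot(multi.uncertainties["distance"],
                            single.uncertainties["distance"])
        assert abs(multi.geometry.distance - single.geometry.distance) \
            <= 5 * combined + 0.02
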