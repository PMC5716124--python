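"""Acquisition simulator tests: protocol angles, forward projection against
the chord-length oracle, and the exposure-noise law."""

import numpy as np
import pytest

from cbctiq.acquisition import (
    AcquisitionProtocol,
    ScanGeometry,
    TruncationError,
    add_exposure_noise,
    desk_geometry,
    forward_project,
    protocol_angles,
    simulate_scan,
    study_protocols,
)
from cbctiq.phantoms import make_cylinder_phantom


def chord_length(radius_mm, impact_parameter_mm):
    """Analytic chord of a circle at a given perpendicular ray distance."""
    if abs(impact_parameter_mm) >= radius_mm:
        return 0.0
    return 2.0 * np.sqrt(radius_mm**2 - impact_parameter_mm**2)


class TestProtocolAngles:
    def test_short_scan_spacing(self, protocols_by_name):
        angles = protocol_angles(protocols_by_name["6"])
        assert angles.size == 100
        assert np.allclose(np.diff(angles), 2.0)
        assert angles[0] == 270.0

    def test_full_scan_spacing(self, protocols_by_name):
        angles = protocol_angles(protocols_by_name["2"])
        assert angles.size == 360
        assert np.allclose(np.diff(angles), 1.0)

    def test_two_projection_degenerate(self):
        p = AcquisitionProtocol("t", 0, 0, 360, "CW", 2, 1.0)
        assert np.allclose(np.diff(protocol_angles(p)), 180.0)

    def test_sampling_rate_column(self):
        rates = [p.sampling_rate_deg for p in study_protocols()]
        assert rates == pytest.approx([2.0, 1.0, 0.9, 0.8, 0.6, 2.0, 1.0, 0.5, 1.0])

    def test_forbidden_line_crossing_warns(self):
        p = AcquisitionProtocol("cross", 90, 290, 200, "CW", 50, 10.0)
        with pytest.warns(UserWarning, match="180 deg line"):
            protocol_angles(p)

    def test_study_short_scan_avoids_forbidden_line(self, protocols_by_name):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            protocol_angles(protocols_by_name["6"])

    def test_inconsistent_arc_rejected(self):
        with pytest.raises(ValueError, match="inconsistent arc"):
            AcquisitionProtocol("bad", 270, 120, 200, "CW", 100, 13.5)


class TestForwardProjection:
    def test_central_ray_through_water_cylinder(self, water_phantom, geometry):
        prof = forward_project(water_phantom, geometry, 0.0)
        center = prof[geometry.detector_pixels // 2 - 1 : geometry.detector_pixels // 2 + 1]
        assert center == pytest.approx(0.005 * 220.0, rel=0.01)

    def test_rays_missing_phantom_are_zero(self, water_phantom, geometry):
        prof = forward_project(water_phantom, geometry, 30.0)
        u = geometry.u_coords_mm()
        # impact parameter of each ray (tangent geometry)
        b = geometry.sad_mm * np.sin(np.arctan(u / geometry.sdd_mm))
        assert np.all(prof[np.abs(b) > 112.0] == 0.0)

    def test_all_air_phantom_projects_to_zero(self, geometry):
        ph = make_cylinder_phantom(spacing_mm=1.0)
        ph.mu_grid[:] = 0.0
        ph.label_grid[:] = 0
        ph.labels = {0: "air"}
        assert np.all(forward_project(ph, geometry, 13.0) == 0.0)

    def test_chord_length_oracle_random_rays(self, geometry):
        # 0.5 mm voxels and ray sampling; rays away from grazing incidence
        ph = make_cylinder_phantom(spacing_mm=0.5, margin_mm=5.0)
        rng = np.random.default_rng(7)
        u = geometry.u_coords_mm()
        b_all = geometry.sad_mm * np.sin(np.arctan(u / geometry.sdd_mm))
        checked = 0
        while checked < 50:
            angle = rng.uniform(0, 360)
            prof = forward_project(ph, geometry, angle, step_fraction=0.5)
            idx = rng.integers(0, u.size, size=10)
            for k in idx:
                if abs(b_all[k]) > 0.9 * 110.0:
                    continue
                expected = 0.005 * chord_length(110.0, b_all[k])
                assert prof[k] == pytest.approx(expected, rel=0.01, abs=2e-4)
                checked += 1
        assert checked >= 50

    def test_truncation_detected(self):
        geom = ScanGeometry(detector_pixels=64, pixel_pitch_mm=1.0)
        ph = make_cylinder_phantom(spacing_mm=1.0)
        with pytest.raises(TruncationError, match="truncation"):
            forward_project(ph, geom, 0.0)
        with pytest.warns(UserWarning, match="truncation"):
            forward_project(ph, geom, 0.0, allow_truncation=True)


class TestExposureNoise:
    def test_poisson_mean_and_variance(self, geometry):
        # law of large numbers over 10^5 identical pixels: realised mean
        # matches the expected counts within 1%, and variance = mean for the
        # pure Poisson mode
        p = AcquisitionProtocol("t", 180, 180, 360, "CW", 360, 13.5)
        big = np.full((1, 100000), 1.1)
        scan = add_exposure_noise(big, p, geometry, np.array([0.0]), 4.0e5, seed=1)
        expected = 4.0e5 * p.mu_per_projection * np.exp(-1.1)
        assert scan.frames.mean() == pytest.approx(expected, rel=0.01)
        assert scan.frames.var() == pytest.approx(expected, rel=0.05)
        assert scan.frames.min() >= 0

    def test_doubling_mu_per_projection_doubles_expected_counts(self, geometry):
        # 100 vs 200 projections at the same total MU: twice the exposure,
        # hence twice the expected counts per frame
        p100 = AcquisitionProtocol("a", 270, 110, 200, "CW", 100, 13.5)
        p200 = AcquisitionProtocol("b", 270, 110, 200, "CW", 200, 13.5)
        ideal1 = np.full((1, 16), 0.7)
        e100 = add_exposure_noise(ideal1, p100, geometry, np.array([270.0]), 4.0e5, seed=0)
        e200 = add_exposure_noise(ideal1, p200, geometry, np.array([270.0]), 4.0e5, seed=0)
        expected_ratio = p100.mu_per_projection / p200.mu_per_projection
        assert expected_ratio == 2.0
        # compare the Poisson means, not single draws
        m100 = 4.0e5 * p100.mu_per_projection * np.exp(-0.7)
        m200 = 4.0e5 * p200.mu_per_projection * np.exp(-0.7)
        assert m100 == pytest.approx(2 * m200)
        assert e100.frames.shape == e200.frames.shape

    def test_noiseless_frames_equal_expected_counts(self, geometry, water_phantom, protocols_by_name, ideal_projections):
        p = protocols_by_name["6"]
        ideal = ideal_projections("water", "6")
        scan = simulate_scan(water_phantom, p, geometry, noiseless=True, ideal=ideal)
        expected = scan.fluence_per_mu * p.mu_per_projection * np.exp(-ideal)
        assert np.array_equal(scan.frames, expected)
        # and the log transform inverts exactly
        assert scan.log_line_integrals() == pytest.approx(ideal, abs=1e-12)

    def test_same_seed_reproduces_scan(self, geometry, water_phantom, protocols_by_name, ideal_projections):
        p = protocols_by_name["6"]
        ideal = ideal_projections("water", "6")
        s1 = simulate_scan(water_phantom, p, geometry, seed=42, ideal=ideal)
        s2 = simulate_scan(water_phantom, p, geometry, seed=42, ideal=ideal)
        assert np.array_equal(s1.frames, s2.frames)
        s3 = simulate_scan(water_phantom, p, geometry, seed=43, ideal=ideal)
        assert not np.array_equal(s1.frames, s3.frames)

    def test_total_mu_conserved(self, protocols_by_name, geometry, water_phantom, ideal_projections):
        for name in ("1", "6", "9"):
            p = protocols_by_name[name]
            scan = simulate_scan(water_phantom, p, geometry, noiseless=True,
                                 ideal=ideal_projections("water", name))
            assert scan.total_mu() == pytest.approx(p.total_mu, rel=1e-12)

    def test_saturation_warns_and_clips(self, geometry):
        p = AcquisitionProtocol("hot", 180, 180, 360, "CW", 2, 13.5)
        ideal = np.zeros((2, 4))
        with pytest.warns(UserWarning, match="saturation"):
            scan = add_exposure_noise(ideal, p, geometry, np.array([0.0, 180.0]),
                                      fluence_per_mu=1e7, seed=0)
        assert scan.frames.max() <= geometry.count_ceiling

    def test_electronic_noise_added(self, geometry):
        p = AcquisitionProtocol("t", 180, 180, 360, "CW", 360, 13.5)
        ideal = np.full((2, 20000), 0.5)
        pure = add_exposure_noise(ideal, p, geometry, np.array([0.0, 180.0]), 4.0e5, seed=3)
        noisy = add_exposure_noise(ideal, p, geometry, np.array([0.0, 180.0]), 4.0e5,
                                   seed=3, electronic_noise_sd=50.0)
        assert noisy.frames.var() > pure.frames.var()


def test_desk_geometry_covers_pelvis_extent():
    geom = desk_geometry()
    assert geom.fov_radius_mm > 170.0
    assert geom.detector_pixels == 512
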