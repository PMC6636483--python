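"""Morphometry: calibration, segmentation, thickness, area, roughness."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from cartmorph.morphometry import (
    CalibrationError,
    FitError,
    GeometryError,
    SegmentationError,
    calibrate_scale,
    cartilage_area,
    extract_boundaries,
    fit_idealized_surface,
    mean_thickness,
    measure_profile,
    normalized_roughness,
    rms_roughness,
)
from cartmorph.profiles import CartilageProfile, build_profile
from cartmorph.presets import GeometrySettings
from cartmorph.scoring import Lesion, LesionDepth
from cartmorph.synthetic import ResolutionError, render_section_image

from conftest import flat_profile


class TestCalibration:
    def test_one_mm_ruler_at_two_um_per_px(self, smooth_profile):
        img = render_section_image(smooth_profile, pixel_size=2.0)
        assert calibrate_scale(img, known_length=1000.0) == pytest.approx(2.0, rel=0.01)

    def test_identity_scale(self):
        img = np.full((50, 1200), 40, dtype=np.uint8)
        img[40:43, 100:1100] = 0  # 1000 px bar
        assert calibrate_scale(img, known_length=1000.0) == pytest.approx(1.0)

    def test_blank_image_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_scale(np.full((50, 50), 40, dtype=np.uint8))


class TestSegmentation:
    def test_round_trip_thickness_within_two_pixels(self, smooth_profile):
        scale = 2.0
        img = render_section_image(smooth_profile, pixel_size=scale)
        profile = extract_boundaries(img, scale)
        t, _ = mean_thickness(profile)
        assert t == pytest.approx(200.0, abs=2 * scale)

    def test_flat_band_pixel_thickness(self):
        """A flat 200 um band rendered at 2 um/px is ~100 px thick."""
        profile = flat_profile(200.0)
        img = render_section_image(profile, pixel_size=2.0)
        tissue_cols = (img > 120).sum(axis=0)
        band = tissue_cols[tissue_cols > 0]
        assert np.median(band) == pytest.approx(100, abs=2)

    def test_uniform_background_raises(self):
        with pytest.raises(SegmentationError, match="0 components"):
            extract_boundaries(np.full((80, 5000), 40, dtype=np.uint8), 2.0)

    def test_multiple_bands_counted(self):
        img = np.full((100, 5000), 40, dtype=np.uint8)
        img[10:30] = 200
        img[60:80] = 200
        with pytest.raises(SegmentationError, match="2 components"):
            extract_boundaries(img, 2.0)

    def test_injected_texture_recovered_at_fine_scale(self, geometry):
        """5 um RMS fibrillation survives the raster round trip within 15%."""
        profile = build_profile(200.0, 5.0, geometry, np.random.default_rng(3))
        img = render_section_image(profile, pixel_size=1.0)
        extracted = extract_boundaries(img, 1.0)
        rms, _ = rms_roughness(extracted)
        assert rms == pytest.approx(5.0, rel=0.15)

    def test_coarse_pixels_refused(self, smooth_profile):
        with pytest.raises(ResolutionError):
            render_section_image(smooth_profile, pixel_size=80.0)


class TestThickness:
    def test_flat_parallel_planes_exact(self):
        profile = flat_profile(200.0)
        t, points = mean_thickness(profile)
        assert len(points) == 20
        assert t == pytest.approx(200.0, abs=1e-9)
        assert points == pytest.approx(np.full(20, 200.0), abs=1e-9)

    def test_arc_normal_separation(self, geometry):
        """On the curved base the perpendicular separation equals the true
        offset used to build the parallel tidemark."""
        profile = build_profile(180.0, 0.0, geometry, np.random.default_rng(1))
        t, _ = mean_thickness(profile)
        assert t == pytest.approx(180.0, abs=1.0)

    def test_convergence_in_n_points(self, geometry):
        profile = build_profile(220.0, 0.0, geometry, np.random.default_rng(2))
        t20, _ = mean_thickness(profile, n_points=20)
        t2000, _ = mean_thickness(profile, n_points=2000)
        assert t20 == pytest.approx(t2000, rel=0.02)

    def test_n_points_lower_bound(self, smooth_profile):
        with pytest.raises(ValueError):
            mean_thickness(smooth_profile, n_points=1)


class TestArea:
    def test_rectangle(self):
        profile = flat_profile(200.0)
        assert cartilage_area(profile) == pytest.approx(1_400_000.0, rel=1e-9)

    def test_triangle_wedge(self):
        """Separation ramping 0 -> 200 um across the 7 mm window."""
        roi = (-3500.0, 3500.0)
        profile = flat_profile(
            200.0, surface_y=lambda x: np.clip((x - roi[0]) / 7000.0, 0, 1) * 200.0 + 1e-9
        )
        assert cartilage_area(profile, window=roi) == pytest.approx(700_000.0, rel=1e-6)

    def test_shoelace_oracle_on_random_profiles(self, rng):
        """Trapezoidal area agrees with an independent polygon-area oracle
        (shapely) within 0.1% on random smooth valid profiles."""
        from shapely.geometry import Polygon

        for _ in range(100):
            t = rng.uniform(120, 280)
            profile = build_profile(t, rng.uniform(0, 8), GeometrySettings(),
                                    np.random.default_rng(rng.integers(2**31)))
            lo, hi = profile.roi
            xs = profile.surface[:, 0]
            m = (xs >= lo) & (xs <= hi)
            surf = profile.surface[m]
            x_t = np.linspace(lo, hi, 2000)
            tid = np.column_stack([
                x_t, np.interp(x_t, profile.tidemark[:, 0], profile.tidemark[:, 1])
            ])
            ring = np.vstack([surf, tid[::-1]])
            oracle = Polygon(ring).area
            ours = cartilage_area(profile)
            assert ours == pytest.approx(oracle, rel=1e-3)

    def test_boundary_crossing_rejected(self):
        profile = flat_profile(200.0)
        crossing = CartilageProfile(
            surface=profile.surface.copy(),
            tidemark=np.column_stack([profile.tidemark[:, 0],
                                      profile.tidemark[:, 1] + 300.0]),
            roi=profile.roi,
            flanks=profile.flanks,
        )
        with pytest.raises(GeometryError):
            cartilage_area(crossing)


class TestIdealizedSurface:
    def test_flat_flanks_give_constant(self):
        profile = flat_profile(200.0)
        ideal = fit_idealized_surface(profile)
        xs = np.linspace(*profile.roi, 50)
        assert ideal(xs) == pytest.approx(np.full(50, 200.0), abs=1e-9)

    def test_quadratic_recovered_exactly(self):
        coeffs = (450.0, 0.01, -1.0e-5)
        quad = lambda x: coeffs[0] + coeffs[1] * x + coeffs[2] * x**2
        profile = flat_profile(200.0, surface_y=quad)
        ideal = fit_idealized_surface(profile)
        assert ideal.coefficients == pytest.approx(np.array(coeffs), rel=1e-6, abs=1e-9)

    def test_lesioned_roi_does_not_bias_fit(self, geometry):
        """Deep lesions inside the ROI leave the flank-only fit within 2 um
        of the generator's base curve."""
        lesions = (Lesion(LesionDepth.FULL_DEPTH, 0.5),)
        profile = build_profile(200.0, 0.0, geometry, np.random.default_rng(5),
                                lesions=lesions)
        ideal = fit_idealized_surface(profile)
        xs = np.linspace(*profile.roi, 200)
        base = 1000.0 - xs**2 / (2 * geometry.condyle_radius)
        assert np.max(np.abs(ideal(xs) - base)) < 2.0

    def test_missing_flanks_raise(self):
        profile = flat_profile(200.0)
        starved = CartilageProfile(
            surface=profile.surface, tidemark=profile.tidemark,
            roi=profile.roi,
            flanks=((profile.roi[0] - 1.0, profile.roi[0]),
                    (profile.roi[1], profile.roi[1] + 1.0)),
        )
        with pytest.raises(FitError, match="flank"):
            fit_idealized_surface(starved)


class TestRoughness:
    def test_zero_when_real_equals_ideal(self):
        profile = flat_profile(200.0)
        rms, n = rms_roughness(profile)
        assert rms == pytest.approx(0.0, abs=1e-9)
        assert n == len(profile.surface_roi())

    def test_sinusoid_amplitude_over_sqrt2(self):
        """A = 10 um sinusoidal deviation, densely sampled: RMS = 10/sqrt(2)."""
        wave = lambda x: 200.0 + np.where(
            (x >= -3500) & (x <= 3500), 10.0 * np.sin(2 * np.pi * x / 700.0), 0.0
        )
        profile = flat_profile(200.0, spacing=1.0, surface_y=wave)
        rms, _ = rms_roughness(profile)
        assert rms == pytest.approx(10.0 / np.sqrt(2), rel=0.005)

    def test_constant_offset(self):
        # step strictly inside the ROI so flank points stay pristine
        step = lambda x: 200.0 - np.where((x >= -3490) & (x <= 3490), 7.0, 0.0)
        profile = flat_profile(200.0, surface_y=step)
        rms, _ = rms_roughness(profile)
        assert rms == pytest.approx(7.0, rel=0.005)

    def test_monotone_in_injected_fibrillation(self, geometry):
        """Mean measured RMS strictly increases over a 5-level injected
        ladder (Spearman rho = 1), 20 replicates each."""
        levels = [1.0, 2.5, 5.0, 7.5, 10.0]
        means = []
        for i, level in enumerate(levels):
            vals = [
                rms_roughness(build_profile(200.0, level, geometry,
                                            np.random.default_rng(1000 * i + r)))[0]
                for r in range(20)
            ]
            means.append(np.mean(vals))
        rho, _ = spearmanr(levels, means)
        assert rho == pytest.approx(1.0)
        assert means == sorted(means)


class TestNormalizedRoughness:
    def test_reported_ratio_convention(self):
        assert normalized_roughness(5.39, 242.82) == pytest.approx(22.2, abs=0.05)

    def test_zero_rms(self):
        assert normalized_roughness(0.0, 150.0) == 0.0

    def test_ratio_identity(self):
        assert normalized_roughness(150.0, 150.0) == pytest.approx(1000.0)

    def test_zero_thickness_rejected(self):
        with pytest.raises(GeometryError):
            normalized_roughness(5.0, 0.0)

    def test_result_invariant_consistency(self, geometry):
        r = measure_profile(build_profile(200.0, 5.0, geometry, np.random.default_rng(9)))
        assert r.normalized_roughness == pytest.approx(
            1000.0 * r.rms_roughness / r.thickness_mean, abs=1e-9
        )
        assert len(r.thickness_points) == 20
        assert r.area >= 0 and r.rms_roughness >= 0


class TestGeometricInvariances:
    def test_uniform_scaling(self, geometry):
        """Scaling all coordinates by c scales thickness and RMS by c, area
        by c^2, and leaves the normalized ratio unchanged."""
        p = build_profile(200.0, 5.0, geometry, np.random.default_rng(11))
        c = 2.0
        scaled = CartilageProfile(
            surface=p.surface * c, tidemark=p.tidemark * c,
            roi=(p.roi[0] * c, p.roi[1] * c),
            flanks=tuple((a * c, b * c) for a, b in p.flanks),
        )
        r1 = measure_profile(p)
        r2 = measure_profile(scaled)
        assert r2.thickness_mean == pytest.approx(c * r1.thickness_mean, rel=1e-6)
        assert r2.rms_roughness == pytest.approx(c * r1.rms_roughness, rel=1e-6)
        assert r2.area == pytest.approx(c**2 * r1.area, rel=1e-6)
        assert r2.normalized_roughness == pytest.approx(r1.normalized_roughness, rel=1e-6)

    def test_rigid_motion_changes_little(self, geometry):
        """Translating and slightly rotating the whole section (flanks
        included) moves thickness, area and RMS by < 0.5%."""
        p = build_profile(200.0, 5.0, geometry, np.random.default_rng(13))
        theta = np.deg2rad(0.5)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        shift = np.array([250.0, -90.0])

        def transform(poly):
            return poly @ rot.T + shift

        surf = transform(p.surface)
        tid = transform(p.tidemark)
        x0 = transform(np.array([[p.roi[0], 1000.0 - p.roi[0]**2 / (2 * geometry.condyle_radius)]]))[0, 0]
        moved = CartilageProfile(
            surface=surf, tidemark=tid,
            roi=(x0, x0 + 7000.0),
            flanks=((surf[0, 0], x0), (x0 + 7000.0, surf[-1, 0])),
        )
        r1, r2 = measure_profile(p), measure_profile(moved)
        assert r2.thickness_mean == pytest.approx(r1.thickness_mean, rel=0.005)
        assert r2.area == pytest.approx(r1.area, rel=0.005)
        assert r2.rms_roughness == pytest.approx(r1.rms_roughness, abs=0.005 * r1.thickness_mean)
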