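"""Collimator geometry: LEHR defaults, focal mappings, magnification,
Jacobian, PSF kernels, regions, FOV maps and serialization."""

import numpy as np
import pytest

from focalspect import collimators as cg
from focalspect.phantoms import make_liver_phantom, plan_orbit
from focalspect.volumes import centered_grid


class TestMakeCollimator:
    def test_lehr_defaults_exact(self):
        spec = cg.make_collimator("conebeam", 50.0)
        assert spec.hole_length == 24.05
        assert spec.hole_diameter == 1.11
        assert spec.septal_thickness == 0.16
        assert spec.crystal_extent == (533.0, 387.0)
        assert spec.focal_length == 500.0

    def test_parallel_has_infinite_focal_length(self):
        assert np.isinf(cg.make_collimator("parallel").focal_length)

    def test_multifocal_focus_zone_half_crystal(self):
        spec = cg.make_collimator("multifocal", 50.0)
        assert spec.focus_extent == (267.0, 194.0)
        # half the area: quarter in each linear dimension product
        area_ratio = (spec.focus_extent[0] * spec.focus_extent[1]) \
            / (spec.crystal_extent[0] * spec.crystal_extent[1])
        assert area_ratio == pytest.approx(0.25, abs=0.01)
        assert spec.diverge_focal_length < 0

    @pytest.mark.parametrize("kind,focal", [
        ("unknown", 50.0), ("conebeam", None), ("conebeam", -5.0),
        ("multifocal", 0.0),
    ])
    def test_invalid_arguments_raise(self, kind, focal):
        with pytest.raises(ValueError):
            cg.make_collimator(kind, focal)


class TestMagnification:
    def test_parallel_identity(self):
        spec = cg.make_collimator("parallel")
        assert cg.magnification(spec, "single", 123.0) == 1.0

    def test_conebeam_similar_triangles(self):
        spec = cg.make_collimator("conebeam", 50.0)
        assert cg.magnification(spec, "single", 250.0) == pytest.approx(2.0)
        assert cg.magnification(spec, "single", 0.0) == pytest.approx(1.0)

    def test_beyond_focal_point_raises(self):
        spec = cg.make_collimator("conebeam", 50.0)
        with pytest.raises(ValueError):
            cg.magnification(spec, "single", 510.0)

    def test_multifocal_anisotropic_regions(self):
        spec = cg.make_collimator("multifocal", 50.0)
        mx, my = cg.magnification(spec, "diverge_x_focus_y", 250.0)
        assert mx < 1.0 < my

    def test_monotone_and_continuous_in_z(self):
        spec = cg.make_collimator("conebeam", 50.0)
        z = np.linspace(0.0, 400.0, 200)
        m = cg.magnification(spec, "single", z)
        assert np.all(np.diff(m) > 0)
        assert np.all(np.abs(np.diff(m)) < 0.1)  # no jumps

    def test_diverging_shrinks(self):
        spec = cg.make_collimator("multifocal", 50.0)
        m = cg.axis_magnification(spec, "diverge", np.array([100.0, 300.0]))
        assert np.all(m < 1.0)
        assert m[1] < m[0]


class TestJacobian:
    def test_center_pixel_unity(self, all_collimators):
        for spec in all_collimators.values():
            assert cg.jacobian_sensitivity(spec, 0.0, 0.0) == \
                pytest.approx(1.0)

    def test_conebeam_closed_form(self):
        spec = cg.make_collimator("conebeam", 50.0)
        expected = 1.0 / np.cos(np.arctan(100.0 / 500.0)) ** 2
        assert cg.jacobian_sensitivity(spec, 100.0, 0.0) == \
            pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.04, abs=0.005)

    def test_parallel_unity_everywhere(self):
        spec = cg.make_collimator("parallel")
        u = np.linspace(-260, 260, 11)
        assert np.allclose(cg.jacobian_sensitivity(spec, u, u[:, None]),
                           1.0)

    def test_at_least_one(self, all_collimators):
        u = np.linspace(-260, 260, 21)
        v = np.linspace(-190, 190, 15)
        for spec in all_collimators.values():
            jac = cg.jacobian_sensitivity(spec, u[:, None], v[None, :])
            assert np.all(jac >= 1.0 - 1e-12)


class TestPSFKernel:
    def test_kernel_sums_to_sensitivity(self):
        spec = cg.make_collimator("conebeam", 50.0)
        kernel, sens = cg.psf_kernel(spec, "single", 200.0, 4.7)
        assert kernel.sum() == pytest.approx(sens, rel=1e-6)
        assert sens == pytest.approx(
            spec.parallel_sensitivity
            * cg.region_sensitivity_factor(spec, "single"), rel=1e-12)

    def test_zero_depth_width_matches_quadrature(self):
        spec = cg.make_collimator("parallel")
        sx, sy = cg.psf_sigmas(spec, "single", 0.0)
        expected = np.hypot(
            2 * np.sqrt(2 * np.log(2)) * cg.aperture_sigma(spec, 0.0),
            spec.intrinsic_fwhm) / (2 * np.sqrt(2 * np.log(2)))
        assert sx == pytest.approx(expected, rel=1e-9)
        assert sx == sy

    def test_fwhm_monotone_in_z(self, all_collimators):
        z = np.linspace(0.0, 380.0, 60)
        for name, spec in all_collimators.items():
            region = spec.regions[0]
            sx, sy = cg.psf_sigmas(spec, region, z)
            assert np.all(np.diff(sx) >= -1e-12), name
            assert np.all(np.diff(sy) >= -1e-12), name

    def test_geometric_width_linear_limit(self):
        """With no intrinsic blur the width grows linearly in z."""
        spec = cg.CollimatorSpec("parallel", np.inf, intrinsic_fwhm=0.0)
        z = np.array([100.0, 200.0, 400.0])
        sx, _ = cg.psf_sigmas(spec, "single", z)
        assert sx[1] / sx[0] == pytest.approx(2.0, rel=1e-9)
        assert sx[2] / sx[0] == pytest.approx(4.0, rel=1e-9)

    def test_invalid_inputs(self):
        spec = cg.make_collimator("parallel")
        with pytest.raises(ValueError):
            cg.psf_kernel(spec, "single", -1.0, 4.7)
        with pytest.raises(ValueError):
            cg.psf_kernel(spec, "single", 10.0, 0.0)


class TestRegions:
    def test_regions_partition_detector(self):
        spec = cg.make_collimator("multifocal", 50.0)
        rid = cg.region_id_map(spec, 4.7)
        assert set(np.unique(rid)) == {0, 1, 2, 3}
        weights = cg.blend_weights(spec, 4.7)
        total = sum(weights.values())
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_blend_band_two_pixels_wide(self):
        spec = cg.make_collimator("multifocal", 50.0)
        pitch = 4.7
        mask = cg.blend_mask(spec, pitch)
        u, v = cg.detector_axes(spec, pitch)
        half = spec.focus_extent[0] / 2.0
        # along the central row, the partial-weight band at the x
        # boundary spans exactly the pixels within one pitch of it
        row = mask[:, mask.shape[1] // 2]
        expected = np.abs(np.abs(u) - half) < pitch
        assert np.array_equal(row, expected)

    def test_single_region_no_blend(self):
        spec = cg.make_collimator("conebeam", 50.0)
        assert not cg.blend_mask(spec, 4.7).any()


class TestFOV:
    def test_multifocal_fov_equals_parallel(self):
        """The calibrated diverging focal length restores the
        parallel-hole field of view at any distance."""
        mf = cg.make_collimator("multifocal", 50.0)
        w = mf.crystal_extent[0] / 2.0
        for z in (150.0, 250.0, 350.0):
            edge = cg.detector_to_object(mf, 0, np.array([w]), z)[0]
            assert abs(edge - w) < 4.7  # within one pixel

    def test_mapping_continuous_at_region_boundary(self):
        mf = cg.make_collimator("multifocal", 50.0)
        wf = mf.focus_extent[0] / 2.0
        for z in (100.0, 300.0):
            lo = cg.detector_to_object(mf, 0, np.array([wf - 1e-6]), z)[0]
            hi = cg.detector_to_object(mf, 0, np.array([wf + 1e-6]), z)[0]
            assert lo == pytest.approx(hi, abs=1e-3)

    def test_fraction_map_properties(self):
        bundle = make_liver_phantom((32, 32, 24), 7.0, tumor_radius_mm=10.0)
        orbit = plan_orbit(bundle, 12, 1.0)
        par = cg.make_collimator("parallel")
        cb = cg.make_collimator("conebeam", 50.0)
        frac_par = cg.fov_fraction_map(par, orbit, bundle.labels)
        frac_cb = cg.fov_fraction_map(cb, orbit, bundle.labels)
        body = bundle.labels.data > 0
        # the small phantom sits fully under the parallel crystal
        assert np.all(frac_par.data[body] == 1.0)
        # voxels at the rotation center are always imaged
        center_idx = tuple(np.rint(bundle.labels.index_coords(
            orbit.center_mm)).astype(int))
        assert frac_cb.data[center_idx] == 1.0

    def test_conebeam_sees_liver_better_than_lung(self):
        bundle = make_liver_phantom((48, 48, 32), 7.0, tumor_radius_mm=14.0)
        orbit = plan_orbit(bundle, 16, 1.0)
        cb = cg.make_collimator("conebeam", 50.0)
        frac = cg.fov_fraction_map(cb, orbit, bundle.labels)
        liver = frac.data[bundle.mask("liver")].mean()
        lung = frac.data[bundle.mask("lung")].mean()
        assert liver > lung


def test_spec_text_roundtrip(all_collimators):
    for spec in all_collimators.values():
        text = cg.spec_to_text(spec)
        back = cg.spec_from_text(text)
        assert back == spec


def test_psf_bank_shapes():
    spec = cg.make_collimator("multifocal", 50.0)
    z = np.linspace(30.0, 400.0, 32)
    bank = cg.PSFBank(spec, 4.7, z)
    assert set(bank.sigmas_px) == set(spec.regions)
    for sx, sy in bank.sigmas_px.values():
        assert sx.shape == z.shape and sy.shape == z.shape
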