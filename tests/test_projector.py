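"""Fast CFD projector: warp geometry, point-source counts, linearity,
Poisson noise and determinism."""

import numpy as np
import pytest

from focalspect import collimators as cg
from focalspect import phantoms as phf
from focalspect import physics as ph
from focalspect import projector as prj
from focalspect.volumes import centered_grid
from focalspect.warp import ViewOperator, rotate_warp


def _delta_volume(grid, world_point):
    act = np.zeros(grid.shape, dtype=np.float32)
    idx = np.rint(grid.index_coords(np.asarray(world_point))).astype(int)
    act[tuple(idx)] = 1.0
    return act, grid.world_coords(idx)


class TestRotateWarp:
    def test_zero_degree_parallel_is_identity(self, single_view_orbit):
        # grid parities chosen so the warped lattice coincides with the
        # voxel lattice: the resampling is then the exact identity
        spec = cg.make_collimator("parallel")
        vol = centered_grid((25, 24, 17), 7.0)
        rng = np.random.default_rng(0)
        vol.data[4:20, 4:20, 4:12] = rng.random((16, 16, 8)).astype(
            np.float32)
        warped, op = rotate_warp(vol, single_view_orbit, 0, spec)
        assert warped.sum() == pytest.approx(vol.data.sum(), rel=1e-5)
        assert warped.max() == pytest.approx(vol.data.max(), rel=1e-5)
        # values survive unchanged (angle 0, parallel: pure re-indexing)
        assert np.isin(np.round(vol.data[vol.data > 0], 5),
                       np.round(warped[warped > 0], 5)).all()

    def test_point_maps_to_magnified_position(self, single_view_orbit):
        spec = cg.make_collimator("conebeam", 50.0)
        grid = centered_grid((64, 64, 48), 4.7)
        act, snapped = _delta_volume(grid, (50.0, 94.0, 0.0))
        warped, op = rotate_warp(grid.like(act), single_view_orbit, 0, spec)
        z = 300.0 - snapped[0]
        expected_u = float(cg.object_to_detector(spec, 0, snapped[1], z))
        iu, iv, idp = np.unravel_index(np.argmax(
            warped.sum(axis=2)[..., None]), warped.shape)
        proj = warped.sum(axis=(1, 2))
        centroid_u = float((proj * op.u_mm).sum() / proj.sum())
        assert abs(centroid_u - expected_u) < grid.voxel_size

    def test_warp_sampling_concentration(self, single_view_orbit):
        """A magnified point gathers with sampling density Mx * My."""
        spec = cg.make_collimator("conebeam", 50.0)
        grid = centered_grid((64, 64, 48), 4.7)
        act, snapped = _delta_volume(grid, (50.0, 20.0, -10.0))
        warped, op = rotate_warp(grid.like(act), single_view_orbit, 0,
                                 spec)
        m = float(cg.magnification(spec, "single", 300.0 - snapped[0]))
        assert warped.sum() == pytest.approx(m * m, rel=0.05)


class TestPrimaryProjection:
    def test_zero_activity_zero_projection(self, tiny_liver):
        bundle, orbit = tiny_liver
        spec = cg.make_collimator("conebeam", 50.0)
        pr = prj.CFDProjector(spec, orbit, bundle.density)
        out = pr.forward(np.zeros(bundle.density.shape, np.float32), 0)
        assert not out.any()

    @pytest.mark.parametrize("kind,focal", [("parallel", None),
                                            ("conebeam", 50.0)])
    def test_point_source_counts_match_analytic(self, single_view_orbit,
                                                kind, focal):
        """Point in air: total counts = sensitivity x magnification^2
        x acceptance-plane factor x crystal absorption, within 1%."""
        spec = cg.make_collimator(kind, focal)
        grid = centered_grid((64, 64, 48), 4.7)
        dens = grid.like(np.zeros(grid.shape, np.float32), "density")
        act, snapped = _delta_volume(grid, (50.0, 0.0, 0.0))
        pr = prj.CFDProjector(spec, single_view_orbit, dens)
        total = pr.forward(act, 0, time_s=20.0).sum()
        z = 300.0 - snapped[0]
        m = 1.0 if kind == "parallel" else \
            spec.focal_length / (spec.focal_length - z)
        expected = (spec.parallel_sensitivity * m * m
                    * cg.region_sensitivity_factor(spec, "single")
                    * prj.crystal_absorption(spec, 140.0) * 20.0)
        assert total == pytest.approx(expected, rel=0.01)

    def test_linearity(self, tiny_liver):
        bundle, orbit = tiny_liver
        spec = cg.make_collimator("multifocal", 50.0)
        pr = prj.CFDProjector(spec, orbit, bundle.density)
        rng = np.random.default_rng(5)
        a = rng.random(bundle.density.shape).astype(np.float32)
        b = rng.random(bundle.density.shape).astype(np.float32)
        lhs = pr.forward(2.0 * a + 3.0 * b, 2)
        rhs = 2.0 * pr.forward(a, 2) + 3.0 * pr.forward(b, 2)
        assert np.allclose(lhs, rhs, rtol=1e-4, atol=1e-6 * lhs.max())

    def test_delta_peaks_at_ray_traced_position(self, single_view_orbit):
        """Forward projection of an in-FOV delta peaks within one pixel
        of its ray-traced detector position."""
        grid = centered_grid((64, 64, 48), 4.7)
        dens = grid.like(np.zeros(grid.shape, np.float32), "density")
        rng = np.random.default_rng(11)
        for kind, focal in (("parallel", None), ("conebeam", 50.0),
                            ("multifocal", 50.0)):
            spec = cg.make_collimator(kind, focal)
            pr = prj.CFDProjector(spec, single_view_orbit, dens)
            for _ in range(3):
                pt = rng.uniform([-60, -100, -60], [80, 100, 60])
                act, snapped = _delta_volume(grid, pt)
                proj = pr.forward(act, 0)
                z = 300.0 - snapped[0]
                eu = float(cg.object_to_detector(spec, 0, snapped[1], z))
                ev = float(cg.object_to_detector(spec, 1, snapped[2], z))
                u_ax, v_ax = cg.detector_axes(spec, grid.voxel_size)
                iu, iv = np.unravel_index(np.argmax(proj), proj.shape)
                err = np.hypot(u_ax[iu] - eu, v_ax[iv] - ev)
                assert err <= 1.8 * grid.voxel_size, (kind, pt, err)

    def test_attenuation_reduces_counts(self, tiny_liver):
        bundle, orbit = tiny_liver
        spec = cg.make_collimator("parallel")
        pr_att = prj.CFDProjector(spec, orbit, bundle.density)
        vac = bundle.density.like(
            np.zeros(bundle.density.shape, np.float32), "density")
        pr_vac = prj.CFDProjector(spec, orbit, vac)
        att = pr_att.forward(bundle.activity.data, 0).sum()
        free = pr_vac.forward(bundle.activity.data, 0).sum()
        assert att < 0.8 * free


@pytest.fixture(scope="module")
def mean_projections(tiny_liver):
    bundle, orbit = tiny_liver
    spec = cg.make_collimator("parallel")
    opts = prj.ProjectorOptions(n_scatter_histories=30_000, seed=3)
    return prj.project(bundle, spec, orbit, opts)


class TestProjectEndToEnd:

    def test_doubling_time_doubles_means(self, tiny_liver):
        bundle, orbit = tiny_liver
        spec = cg.make_collimator("parallel")
        orbit2 = cg.DetectorOrbit(orbit.angles_deg, orbit.radii_mm,
                                  2.0 * orbit.time_per_view_s,
                                  orbit.center_mm)
        o1 = prj.ProjectorOptions(n_scatter_histories=20_000, seed=3)
        p1 = prj.project(bundle, spec, orbit, o1)
        p2 = prj.project(bundle, spec, orbit2, o1)
        assert np.allclose(2.0 * p1.windows["photopeak"],
                           p2.windows["photopeak"], rtol=1e-4,
                           atol=1e-3)

    def test_scatter_off_is_primary_only(self, tiny_liver,
                                         mean_projections):
        bundle, orbit = tiny_liver
        spec = cg.make_collimator("parallel")
        opts = prj.ProjectorOptions(include_scatter=False, seed=3)
        prim = prj.project(bundle, spec, orbit, opts)
        diff = mean_projections.windows["photopeak"] \
            - prim.windows["photopeak"]
        assert np.all(diff >= -1e-4)
        assert diff.sum() == pytest.approx(
            mean_projections.meta["scatter_photopeak_total"], rel=1e-3)

    def test_meta_totals_consistent(self, mean_projections):
        m = mean_projections.meta
        assert m["primary_photopeak_total"] > 0
        assert m["scatter_photopeak_total"] > 0
        total = mean_projections.windows["photopeak"].sum()
        assert total == pytest.approx(m["primary_photopeak_total"]
                                      + m["scatter_photopeak_total"],
                                      rel=1e-3)


class TestPoisson:
    def _means(self, tiny_liver):
        bundle, orbit = tiny_liver
        spec = cg.make_collimator("parallel")
        opts = prj.ProjectorOptions(include_scatter=False, seed=0)
        return prj.project(bundle, spec, orbit, opts)

    def test_zero_mean_gives_zero_counts(self, tiny_liver):
        ps = self._means(tiny_liver)
        counts = prj.add_poisson(ps, 1)
        zero = ps.windows["photopeak"] == 0
        assert np.all(counts.windows["photopeak"][zero] == 0)

    def test_sample_mean_within_3_sigma(self, tiny_liver):
        ps = self._means(tiny_liver)
        mu = float(ps.windows["photopeak"].max())
        draws = np.array([
            prj.add_poisson(ps, s).windows["photopeak"].max(
            ) if False else prj.add_poisson(ps, s).windows["photopeak"][
                np.unravel_index(np.argmax(ps.windows["photopeak"]),
                                 ps.windows["photopeak"].shape)]
            for s in range(300)], dtype=float)
        assert abs(draws.mean() - mu) < 3.0 * np.sqrt(mu / len(draws))

    def test_same_seed_identical(self, tiny_liver):
        ps = self._means(tiny_liver)
        a = prj.add_poisson(ps, 9)
        b = prj.add_poisson(ps, 9)
        assert np.array_equal(a.windows["photopeak"],
                              b.windows["photopeak"])

    def test_requires_mean_kind(self, tiny_liver):
        ps = prj.add_poisson(self._means(tiny_liver), 0)
        with pytest.raises(ValueError):
            prj.add_poisson(ps, 1)
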