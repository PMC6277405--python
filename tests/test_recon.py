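"""OSEM reconstruction: adjointness, MLEM fixed point, convergence,
scatter-correction modes and the optimal-k search."""

import numpy as np
import pytest

from focalspect import collimators as cg
from focalspect import metrics as mt
from focalspect import phantoms as phf
from focalspect import projector as prj
from focalspect import recon as rc


@pytest.fixture(scope="module")
def small_study():
    """Liver phantom, parallel collimator, noiseless + noisy counts."""
    bundle = phf.make_liver_phantom((32, 32, 24), 7.0, tumor_radius_mm=14.0)
    orbit = phf.plan_orbit(bundle, 16, 20.0)
    spec = cg.make_collimator("parallel")
    opts = prj.ProjectorOptions(n_scatter_histories=60_000, seed=2)
    means = prj.project(bundle, spec, orbit, opts)
    counts = prj.add_poisson(means, 3)
    return bundle, orbit, spec, means, counts


def test_adjointness_all_collimators(tiny_liver, all_collimators):
    """<A x, y> == <x, A^T y> — the key correctness property of the
    warp/PSF transposition used by the back-projector."""
    bundle, orbit = tiny_liver
    rng = np.random.default_rng(0)
    for name, spec in all_collimators.items():
        pr = prj.CFDProjector(spec, orbit, bundle.density)
        for view in (0, 3, 5):
            x = rng.random(bundle.density.shape).astype(np.float32)
            nu, nv = cg.detector_shape(spec, bundle.density.voxel_size)
            y = rng.random((nu, nv)).astype(np.float32)
            lhs = float((pr.forward(x, view) * y).sum())
            rhs = float((x * pr.adjoint(y, view)).sum())
            assert abs(lhs - rhs) / abs(lhs) < 1e-5, (name, view)


def test_mlem_fixed_point(small_study):
    """measured == forward(x) implies a unit multiplicative update."""
    bundle, orbit, spec, means, _ = small_study
    model = rc.OSEMModel(means, bundle.density,
                         rc.ReconSettings(scatter_mode="none",
                                          n_subsets=1, n_iterations=1))
    x = bundle.activity.data.astype(np.float32)
    # synthesize measurements exactly equal to the forward model
    y = np.stack([model.projector.forward(x, v, time_s=model._t_eff)
                  for v in range(orbit.n_views)])
    fixed = prj.ProjectionSet(windows={"photopeak": y}, kind="mean",
                              orbit=orbit, spec=spec,
                              pixel_pitch=means.pixel_pitch)
    model2 = rc.OSEMModel(fixed, bundle.density,
                          rc.ReconSettings(scatter_mode="none",
                                           n_subsets=1, n_iterations=1))
    sens = model2.subset_sensitivities()[0]
    acc = np.zeros_like(x)
    for v in range(orbit.n_views):
        ratio = y[v] / np.maximum(
            model2.projector.forward(x, v, time_s=model2._t_eff), 1e-10)
        acc += model2.projector.adjoint(ratio, v, time_s=model2._t_eff)
    # the fixed point holds on the activity support (elsewhere rays hit
    # zero-signal pixels whose 0/0 ratio is conventionally zero)
    support = x > 1e-3 * x.max()
    mult = acc[support] / sens[support]
    assert np.allclose(mult, 1.0, atol=1e-5)


def test_noiseless_recovery_converges(small_study):
    """Noiseless data, scatter off both sides: tumor recovery near 100%
    and essentially converged by iteration 10."""
    bundle, orbit, spec, _, _ = small_study
    opts = prj.ProjectorOptions(include_scatter=False)
    means = prj.project(bundle, spec, orbit, opts)
    res = rc.osem(means, bundle.density,
                  rc.ReconSettings(scatter_mode="none",
                                   save_every_iteration=True))
    tumor = mt.erode_one_pixel(bundle.mask("tumor"))
    recs = {it: mt.activity_recovery(vol, bundle.activity, tumor)
            for it, vol in res.iterations.items()}
    assert 90.0 < recs[10] < 112.0
    assert abs(recs[10] - recs[8]) < 2.0  # converged


def test_nonnegativity_and_mask_freeze(small_study):
    bundle, orbit, spec, _, counts = small_study
    res = rc.osem(counts, bundle.density,
                  rc.ReconSettings(scatter_mode="none", n_iterations=2))
    assert np.all(res.activity.data >= 0)
    # voxels outside the update mask keep their initialization
    outside = ~res.update_mask
    if outside.any():
        init = rc.OSEMModel(counts, bundle.density).initial_volume()
        assert np.array_equal(res.activity.data[outside], init[outside])


def test_likelihood_monotone_one_subset(small_study):
    """Full MLEM (one subset) on noiseless data increases the Poisson
    log-likelihood monotonically."""
    bundle, orbit, spec, means, _ = small_study
    res = rc.osem(means, bundle.density,
                  rc.ReconSettings(scatter_mode="none", n_subsets=1,
                                   n_iterations=6, track_likelihood=True))
    ll = np.array(res.log_likelihood)
    assert np.all(np.diff(ll) > -1e-3 * np.abs(ll[0]))


def test_initialization_insensitivity(small_study):
    """Converged tumor recovery changes < 0.5% between two uniform
    initialization scales."""
    bundle, orbit, spec, _, counts = small_study
    tumor = mt.erode_one_pixel(bundle.mask("tumor"))
    recs = []
    for scale in (1.0, 37.0):
        model = rc.OSEMModel(counts, bundle.density,
                             rc.ReconSettings(scatter_mode="none"))
        base_init = model.initial_volume
        model.initial_volume = lambda: scale * base_init()
        res = model.fit()
        recs.append(mt.activity_recovery(res.activity, bundle.activity,
                                         tumor))
    assert abs(recs[0] - recs[1]) <= 0.5


def test_dew_zero_k_equals_none(small_study):
    bundle, orbit, spec, _, counts = small_study
    shared = prj.CFDProjector(spec, orbit, bundle.density)
    a = rc.osem(counts, bundle.density, projector=shared,
                scatter_mode="dew", dew_k=0.0, n_iterations=3)
    b = rc.osem(counts, bundle.density, projector=shared,
                scatter_mode="none", n_iterations=3)
    assert np.allclose(a.activity.data, b.activity.data, rtol=1e-5,
                       atol=1e-6)


def test_dew_term_linear_in_k():
    rng = np.random.default_rng(0)
    sw = rng.poisson(5.0, (4, 20, 20)).astype(float)
    t1 = rc.scatter_estimate_dew(sw, 0.4)
    t2 = rc.scatter_estimate_dew(sw, 0.8)
    assert np.allclose(2.0 * t1, t2, rtol=1e-6)


def test_mc_scatter_term_zero_for_zero_density(small_study):
    bundle, orbit, spec, _, counts = small_study
    vac = bundle.density.like(np.zeros(bundle.density.shape, np.float32),
                              "density")
    model = rc.OSEMModel(counts, vac, rc.ReconSettings(
        scatter_mode="mc", mc_histories_per_iter=5_000))
    term = model.scatter_term_mc(bundle.activity.data,
                                 np.random.default_rng(0))
    assert term.sum() == 0.0


def test_reproducible_given_seed(small_study):
    bundle, orbit, spec, _, counts = small_study
    st = rc.ReconSettings(scatter_mode="mc", n_iterations=2,
                          mc_histories_per_iter=20_000, rng_seed=11)
    a = rc.osem(counts, bundle.density, st)
    b = rc.osem(counts, bundle.density, st)
    assert np.array_equal(a.activity.data, b.activity.data)


def test_optimal_k_identity_case(small_study):
    """When the photopeak scatter is exactly k_true x the (smoothed)
    scatter window, the grid search recovers k_true."""
    bundle, orbit, spec, means, _ = small_study
    k_true = 0.6
    # construct projections whose photopeak = primary + k_true * smooth(sw)
    opts = prj.ProjectorOptions(include_scatter=False)
    primary = prj.project(bundle, spec, orbit, opts).windows["photopeak"]
    sw = means.windows["scatter_window"]
    pp = primary + rc.scatter_estimate_dew(sw, k_true)[...]
    synth = prj.ProjectionSet(
        windows={"photopeak": pp, "scatter_window": sw}, kind="mean",
        orbit=orbit, spec=spec, pixel_pitch=means.pixel_pitch,
        meta={"scatter_photopeak_total": float(
            rc.scatter_estimate_dew(sw, k_true).sum())})
    k_grid = k_true * np.array([0.5, 0.75, 1.0, 1.25, 1.5])
    k_star, details = rc.optimal_k_search(
        synth, bundle, k_grid=k_grid,
        settings=rc.ReconSettings(scatter_mode="dew", n_iterations=10),
        return_details=True)
    assert k_star == pytest.approx(k_true, abs=0.16)
    # local convexity around the minimum
    i = int(np.argmin(details["mse"]))
    assert details["mse"][i] <= details["mse"][i - 1]
    assert details["mse"][i] <= details["mse"][i + 1]


def test_optimal_k_boundary_raises(small_study):
    bundle, orbit, spec, means, counts = small_study
    with pytest.raises(ValueError):
        rc.optimal_k_search(
            counts, bundle, k_grid=[5.0, 6.0, 7.0],
            settings=rc.ReconSettings(scatter_mode="dew", n_iterations=1))


def test_infinite_crystal_removes_truncation():
    bundle = phf.make_liver_phantom((32, 32, 24), 7.0,
                                    tumor_radius_mm=12.0)
    orbit = phf.plan_orbit(bundle, 8, 1.0)
    spec = cg.make_collimator("conebeam", 50.0)
    big = rc.infinite_crystal_spec(spec, bundle, orbit)
    assert big.crystal_extent[0] >= spec.crystal_extent[0]
    frac = cg.fov_fraction_map(big, orbit, bundle.labels)
    body = bundle.labels.data > 0
    assert np.all(frac.data[body] == 1.0)


def test_summary_mentions_settings(small_study):
    bundle, orbit, spec, _, counts = small_study
    res = rc.osem(counts, bundle.density,
                  rc.ReconSettings(scatter_mode="dew", dew_k=0.5,
                                   n_iterations=1))
    text = res.summary()
    assert "dew" in text and "8 x 1" in text
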