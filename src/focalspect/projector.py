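"""Fast Monte Carlo forward projector: convolution-based forced detection.

Primary photons are projected deterministically: the activity and density
grids are rotate+warped into the detector-aligned frame of each view,
attenuated along the (now axis-aligned) accepted ray paths, convolved
plane-by-plane with the distance-dependent region PSF, and weighted by
the flat-detector Jacobian and the collimator sensitivity.  A single
convolution per focusing/diverging region per depth plane models the
detector response — the acceleration that makes the projector fast.

Scattered photons are transported by Monte Carlo (Woodcock tracking,
Klein-Nishina angles) with forced detection: at every interaction the
photon deposits, per view and energy window, a deterministic weight
proportional to the probability of scattering toward the detector and
being recorded in the window; the deposited "effective scatter source"
is then pushed through the same warp+PSF machinery as the primaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from . import collimators as cg
from . import physics as ph
from .phantoms import PhantomBundle
from .volumes import VoxelVolume
from .warp import ViewOperator

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
DEFAULT_SCATTER_HISTORIES = 200_000
DEFAULT_MAX_ORDER = 3
# Effective NaI(Tl) attenuation energy scaling (photoelectric dominated).
_NAI_MU_EXPONENT = 2.5


def _mu_crystal(spec: cg.CollimatorSpec, energy_kev):
    return spec.crystal_attenuation * (140.0 / np.asarray(energy_kev,
                                                          float)) ** _NAI_MU_EXPONENT


def crystal_absorption(spec: cg.CollimatorSpec, energy_kev, sec_theta=1.0):
    """Probability that a photon crossing the crystal interacts in it."""
    tau = _mu_crystal(spec, energy_kev) * cg.CRYSTAL_THICKNESS_MM / 10.0
    return 1.0 - np.exp(-tau * sec_theta)


@dataclass
class ProjectionSet:
    """Per-view, per-window detector images plus acquisition metadata."""

    windows: dict            # name -> (n_views, nu, nv) float or int array
    kind: str                # 'mean' or 'counts'
    orbit: cg.DetectorOrbit
    spec: cg.CollimatorSpec
    pixel_pitch: float
    rng_seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("mean", "counts"):
            raise ValueError("kind must be 'mean' or 'counts'")
        for name, arr in self.windows.items():
            if self.kind == "mean" and np.any(arr < 0):
                raise ValueError(f"negative means in window {name!r}")

    @property
    def n_views(self) -> int:
        return self.orbit.n_views


class CFDProjector:
    """Warp + attenuate + convolve projector for one system geometry.

    ``forward``/``adjoint`` are an exactly transposed operator pair (the
    requirement for a consistent OSEM back-projection).  The projector
    output is in mean counts per unit time for unit window efficiency;
    window/primary efficiency factors are applied by the callers.
    """

    def __init__(self, spec: cg.CollimatorSpec, orbit: cg.DetectorOrbit,
                 density: VoxelVolume,
                 energy_resolution: float = ph.DEFAULT_ENERGY_RESOLUTION,
                 pixel_pitch: float | None = None):
        self.spec = spec
        self.orbit = orbit
        self.density = density
        self.grid = density
        self.energy_resolution = energy_resolution
        self.pitch = pixel_pitch or density.voxel_size
        self.blend = cg.blend_weights(spec, self.pitch)
        self.region_sens = {r: cg.region_sensitivity_factor(spec, r)
                            for r in spec.regions}
        self._ops: dict = {}
        self._trans: dict = {}
        self._sj: dict = {}
        self._mu140_mm = float(ph.mu_water(ph.EMISSION_KEV)) / 10.0

    # -- per-view pieces ---------------------------------------------------
    def op(self, view: int) -> ViewOperator:
        if view not in self._ops:
            self._ops[view] = ViewOperator(self.spec, self.orbit, view,
                                           self.grid, self.pitch)
        return self._ops[view]

    def transmission(self, view: int, op: ViewOperator | None = None,
                     mu_scale: float = 1.0):
        """exp(-integral mu dl) from each warped voxel to the detector."""
        if view not in self._trans:
            op = op or self.op(view)
            rho = op.gather(np.ascontiguousarray(self.density.data,
                                                 dtype=np.float32))
            cum = np.cumsum(rho, axis=2) - 0.5 * rho
            cum *= self._mu140_mm * self.pitch
            cum *= op.sec_theta[:, :, None].astype(np.float32)
            self._trans[view] = cum  # store the optical depth
        tau = self._trans[view]
        return np.exp(-mu_scale * tau)

    def sj_map(self, view: int, op: ViewOperator | None = None):
        """Geometric sensitivity x crystal absorption per detector pixel.

        The hole-acceptance model has a tilt-invariant angular shape
        (hole diameter and septa grow with offset exactly as the holes
        lengthen), so the per-pixel sensitivity is the parallel-hole
        value with only the oblique crystal-absorption dependence; the
        focal solid-angle amplification enters through the warp sampling
        density and the per-region acceptance-plane factor.
        """
        if view not in self._sj:
            op = op or self.op(view)
            pabs = crystal_absorption(self.spec, ph.EMISSION_KEV,
                                      op.sec_theta)
            self._sj[view] = (self.spec.parallel_sensitivity
                              * pabs).astype(np.float32)
        return self._sj[view]

    def _blend_window(self, op: ViewOperator):
        return {r: w[op.u_slice, op.v_slice]
                for r, w in self.blend.items()}

    def _sigmas_px(self, op: ViewOperator):
        kinds_x = sorted({self.spec.axis_kind(r, 0)
                          for r in self.spec.regions})
        kinds_y = sorted({self.spec.axis_kind(r, 1)
                          for r in self.spec.regions})
        z = np.minimum(op.d_planes, 0.95 * self.spec.focal_length
                       if np.isfinite(self.spec.focal_length) else np.inf)
        fg = cg.geometric_fwhm(self.spec, z)
        out_x, out_y = {}, {}
        for kinds, out in ((kinds_x, out_x), (kinds_y, out_y)):
            for kind in kinds:
                m = cg.axis_magnification(self.spec, kind, z)
                fwhm = np.sqrt((m * fg) ** 2 + self.spec.intrinsic_fwhm**2)
                out[kind] = fwhm * _FWHM_TO_SIGMA / self.pitch
        return out_x, out_y

    # -- forward / adjoint -------------------------------------------------
    def forward(self, act_data: np.ndarray, view: int,
                op: ViewOperator | None = None, mu_scale: float = 1.0,
                time_s: float = 1.0) -> np.ndarray:
        """Mean projection (nu, nv) of an activity grid, one view."""
        op = op or self.op(view)
        warped = op.gather(np.ascontiguousarray(act_data, dtype=np.float32))
        warped *= self.transmission(view, op, mu_scale)
        proj = self._convolve_sum(warped, op)
        proj *= self.sj_map(view, op)
        if time_s != 1.0:
            proj *= time_s
        return op.embed(proj)

    def adjoint(self, residual: np.ndarray, view: int,
                op: ViewOperator | None = None, mu_scale: float = 1.0,
                time_s: float = 1.0) -> np.ndarray:
        """Exact transpose of :meth:`forward`."""
        op = op or self.op(view)
        res = op.extract(np.asarray(residual)) * self.sj_map(view, op)
        if time_s != 1.0:
            res = res * time_s
        stack = self._spread_planes(res.astype(np.float32), op)
        stack *= self.transmission(view, op, mu_scale)
        return op.scatter_adj(stack)

    def sensitivity_volume(self, views) -> np.ndarray:
        """Back-projection of unit projections over the given views."""
        out = np.zeros(self.grid.shape, dtype=np.float64)
        nu, nv = cg.detector_shape(self.spec, self.pitch)
        ones = np.ones((nu, nv), dtype=np.float32)
        for v in views:
            out += self.adjoint(ones, int(v))
        return out.astype(np.float32)

    def _convolve_sum(self, warped, op: ViewOperator):
        sig_x, sig_y = self._sigmas_px(op)
        multi = self.spec.kind == "multifocal"
        proj = np.zeros((op.nu, op.nv), dtype=np.float32)
        for k in range(op.nd):
            plane = warped[:, :, k]
            if not plane.any():
                continue
            bx = {kx: gaussian_filter1d(plane, s[k], axis=0)
                  for kx, s in sig_x.items()}
            if not multi:
                (kx,), (ky,) = sig_x.keys(), sig_y.keys()
                proj += self.region_sens["single"] * \
                    gaussian_filter1d(bx[kx], sig_y[ky][k], axis=1)
                continue
            for region, w in self._blend_window(op).items():
                kx = self.spec.axis_kind(region, 0)
                ky = self.spec.axis_kind(region, 1)
                proj += (self.region_sens[region] * w) * \
                    gaussian_filter1d(bx[kx], sig_y[ky][k], axis=1)
        return proj

    def _spread_planes(self, res, op: ViewOperator):
        sig_x, sig_y = self._sigmas_px(op)
        multi = self.spec.kind == "multifocal"
        stack = np.empty(op.warped_shape, dtype=np.float32)
        if multi:
            parts = {r: (res * w * self.region_sens[r]).astype(np.float32)
                     for r, w in self._blend_window(op).items()}
        else:
            res = res * np.float32(self.region_sens["single"])
        for k in range(op.nd):
            if not multi:
                (kx,), (ky,) = sig_x.keys(), sig_y.keys()
                plane = gaussian_filter1d(res, sig_y[ky][k], axis=1)
                stack[:, :, k] = gaussian_filter1d(plane, sig_x[kx][k],
                                                   axis=0)
                continue
            acc = np.zeros_like(res)
            for region, part in parts.items():
                kx = self.spec.axis_kind(region, 0)
                ky = self.spec.axis_kind(region, 1)
                p = gaussian_filter1d(part, sig_y[ky][k], axis=1)
                acc += gaussian_filter1d(p, sig_x[kx][k], axis=0)
            stack[:, :, k] = acc
        return stack


# ---------------------------------------------------------------------------
# Monte Carlo scatter transport with forced detection
# ---------------------------------------------------------------------------

def transport_scatter(activity: VoxelVolume, density: VoxelVolume,
                      spec: cg.CollimatorSpec, orbit: cg.DetectorOrbit,
                      windows: dict, n_histories: int, rng,
                      max_order: int = DEFAULT_MAX_ORDER,
                      energy_resolution: float = ph.DEFAULT_ENERGY_RESOLUTION,
                      views=None):
    """Sample scatter interactions and build per-view forced-detection
    scatter-source volumes, one per energy window.

    Returns ``{window_name: (n_views, nx, ny, nz) float32}`` holding, per
    view, an isotropic-equivalent emission density (Bq) that — projected
    through the CFD machinery with the window's attenuation — yields the
    mean scatter projection per second of acquisition.
    """
    if n_histories <= 0:
        raise ValueError("n_histories must be positive")
    views = np.arange(orbit.n_views) if views is None else np.asarray(views)
    shape = activity.shape
    nvox = int(np.prod(shape))
    act = activity.data.reshape(-1).astype(np.float64)
    a_tot = act.sum()
    out = {name: np.zeros((len(views),) + shape, dtype=np.float32)
           for name in windows}
    if a_tot <= 0:
        return out

    p = act / a_tot
    vox = rng.choice(nvox, size=n_histories, p=p)
    ijk = np.array(np.unravel_index(vox, shape)).T.astype(np.float64)
    pos = activity.world_coords(ijk + rng.random((n_histories, 3)) - 0.5)
    dirs = _isotropic_dirs(n_histories, rng)
    energy = np.full(n_histories, ph.EMISSION_KEV)
    weight = np.full(n_histories, a_tot / n_histories)

    rho = density.data.astype(np.float32)
    rho_max = float(rho.max())
    if rho_max <= 0:
        return out
    sampler = ph._default_sampler()
    view_geom = [_view_vectors(orbit, int(v)) for v in views]

    for _ in range(max_order):
        alive = weight > 0
        pos, inside = _woodcock_step(pos, dirs, energy, weight, rho,
                                     rho_max, density, rng)
        weight = np.where(inside, weight, 0.0)
        if not np.any(weight > 0):
            break
        # Implicit capture: carry the Compton branch probability.
        pc = ph.mu_compton_water(energy) / ph.mu_water(energy)
        weight = weight * pc
        _deposit(out, windows, pos, dirs, energy, weight, spec, orbit,
                 views, view_geom, activity, energy_resolution)
        theta, e_out = sampler.sample(energy, rng)
        dirs = _rotate_dirs(dirs, theta, rng)
        energy = e_out
        weight = np.where(energy > 55.0, weight, 0.0)
    return out


def _isotropic_dirs(n, rng):
    cos_t = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def _woodcock_step(pos, dirs, energy, weight, rho, rho_max, density, rng,
                   max_iter=128):
    """Advance each photon to its next real interaction (delta tracking)."""
    n = len(pos)
    mu_mm = ph.mu_water(energy) * rho_max / 10.0  # majorant, per mm
    pos = pos.copy()
    pending = weight > 0
    inside = pending.copy()
    for _ in range(max_iter):
        idx = np.nonzero(pending)[0]
        if idx.size == 0:
            break
        step = -np.log(rng.random(idx.size)) / mu_mm[idx]
        pos[idx] += dirs[idx] * step[:, None]
        fi = density.index_coords(pos[idx])
        ii = np.rint(fi).astype(int)
        ok = np.all((ii >= 0) & (ii < np.array(rho.shape)), axis=1)
        local = np.zeros(idx.size, dtype=np.float32)
        local[ok] = rho[ii[ok, 0], ii[ok, 1], ii[ok, 2]]
        real = rng.random(idx.size) < local / rho_max
        inside[idx[~ok]] = False
        pending[idx[~ok]] = False
        pending[idx[real & ok]] = False
    inside[pending] = False  # pathological loops count as escaped
    return pos, inside


def _rotate_dirs(dirs, theta, rng):
    """Rotate each direction by polar angle theta, uniform azimuth."""
    phi = rng.uniform(0.0, 2.0 * np.pi, len(theta))
    # Build an orthonormal frame around each direction.
    d = dirs
    helper = np.where(np.abs(d[:, 2:3]) < 0.9,
                      np.tile([0.0, 0.0, 1.0], (len(d), 1)),
                      np.tile([1.0, 0.0, 0.0], (len(d), 1)))
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    st, ct = np.sin(theta), np.cos(theta)
    return (d * ct[:, None] + (e1 * np.cos(phi)[:, None]
                               + e2 * np.sin(phi)[:, None]) * st[:, None])


def _view_vectors(orbit, view):
    r_hat, u_hat = orbit.view_frame(view)
    return r_hat, u_hat, orbit.radii_mm[view]


def _deposit(out, windows, pos, dirs, energy, weight, spec, orbit, views,
             view_geom, grid, energy_resolution):
    live = weight > 0
    if not np.any(live):
        return
    p = pos[live] - orbit.center_mm
    d_in = dirs[live]
    e_in = energy[live]
    w = weight[live]
    vox = np.rint(grid.index_coords(pos[live])).astype(int)
    shape = grid.shape
    ok_v = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
    flat = np.ravel_multi_index(
        (vox[ok_v, 0], vox[ok_v, 1], vox[ok_v, 2]), shape)
    kn_tot = ph.klein_nishina_total(e_in)
    pabs140 = crystal_absorption(spec, ph.EMISSION_KEV)
    z_axis = np.array([0.0, 0.0, 1.0])
    for iv, (r_hat, u_hat, radius) in enumerate(view_geom):
        z = radius - p @ r_hat
        x = p @ u_hat
        y = p[:, 2]
        zc = np.clip(z, 1.0, 0.95 * spec.focal_length
                     if np.isfinite(spec.focal_length) else np.inf)
        u = cg.object_to_detector(spec, 0, x, zc)
        v = cg.object_to_detector(spec, 1, y, zc)
        vec = ((u - x)[:, None] * u_hat[None, :]
               + (v - y)[:, None] * z_axis[None, :]
               + zc[:, None] * r_hat[None, :])
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
        cos_s = np.clip((d_in * vec).sum(axis=1), -1.0, 1.0)
        e_det = ph.compton_scatter_energy(e_in, np.arccos(cos_s))
        kn = ph.klein_nishina_differential(e_in, cos_s) / kn_tot
        base = w * kn * 4.0 * np.pi
        pabs_ratio = crystal_absorption(spec, e_det) / pabs140
        for name, window in windows.items():
            dep = base * ph.window_detection_prob(e_det, window,
                                                  energy_resolution)
            dep = dep * pabs_ratio
            acc = np.bincount(flat, weights=dep[ok_v],
                              minlength=int(np.prod(shape)))
            out[name][iv] += acc.reshape(shape).astype(np.float32)


# ---------------------------------------------------------------------------
# End-to-end projection
# ---------------------------------------------------------------------------

@dataclass
class ProjectorOptions:
    """Options for the end-to-end fast projector."""

    include_scatter: bool = True
    n_scatter_histories: int = DEFAULT_SCATTER_HISTORIES
    max_order: int = DEFAULT_MAX_ORDER
    energy_resolution: float = ph.DEFAULT_ENERGY_RESOLUTION
    photopeak: ph.EnergyWindow = ph.PHOTOPEAK_WINDOW
    scatter_window: ph.EnergyWindow = ph.SCATTER_WINDOW
    simulate_scatter_window: bool = True
    pixel_pitch: float | None = None
    seed: int = 0


def _window_mu_scale(window: ph.EnergyWindow) -> float:
    """Attenuation scaling for photons around the window's center energy."""
    return float(ph.mu_water(window.center_kev) / ph.mu_water(ph.EMISSION_KEV))


def cfd_primary(bundle: PhantomBundle, spec, orbit, view,
                projector: CFDProjector | None = None,
                window: ph.EnergyWindow = ph.PHOTOPEAK_WINDOW,
                energy_resolution: float = ph.DEFAULT_ENERGY_RESOLUTION):
    """Mean photopeak projection of primary (unscattered) photons."""
    projector = projector or CFDProjector(spec, orbit, bundle.density,
                                          energy_resolution)
    eff = float(ph.window_detection_prob(ph.EMISSION_KEV, window,
                                         energy_resolution))
    return projector.forward(bundle.activity.data, view,
                             time_s=orbit.time_per_view_s) * eff


def cfd_scatter(bundle: PhantomBundle, spec, orbit, view, n_histories, rng,
                windows=None, max_order=DEFAULT_MAX_ORDER,
                energy_resolution=ph.DEFAULT_ENERGY_RESOLUTION,
                projector: CFDProjector | None = None):
    """Mean scattered-photon projections per energy window, one view."""
    windows = windows or {"photopeak": ph.PHOTOPEAK_WINDOW,
                          "scatter_window": ph.SCATTER_WINDOW}
    projector = projector or CFDProjector(spec, orbit, bundle.density,
                                          energy_resolution)
    sources = transport_scatter(bundle.activity, bundle.density, spec, orbit,
                                windows, int(n_histories), rng,
                                max_order=max_order,
                                energy_resolution=energy_resolution,
                                views=[view])
    result = {}
    for name, window in windows.items():
        result[name] = projector.forward(sources[name][0], view,
                                         mu_scale=_window_mu_scale(window),
                                         time_s=orbit.time_per_view_s)
    return result


def project(bundle: PhantomBundle, spec: cg.CollimatorSpec,
            orbit: cg.DetectorOrbit,
            options: ProjectorOptions | None = None) -> ProjectionSet:
    """Full fast-projector simulation: mean projections per window."""
    opt = options or ProjectorOptions()
    projector = CFDProjector(spec, orbit, bundle.density,
                             opt.energy_resolution, opt.pixel_pitch)
    nu, nv = cg.detector_shape(spec, projector.pitch)
    n = orbit.n_views
    t = orbit.time_per_view_s
    eff_pp = float(ph.window_detection_prob(ph.EMISSION_KEV, opt.photopeak,
                                            opt.energy_resolution))
    eff_sw = float(ph.window_detection_prob(ph.EMISSION_KEV,
                                            opt.scatter_window,
                                            opt.energy_resolution))
    primary = np.zeros((n, nu, nv), dtype=np.float32)
    for view in range(n):
        primary[view] = projector.forward(bundle.activity.data, view,
                                          time_s=t)
    photopeak = primary * eff_pp
    scatter_win = primary * eff_sw
    meta = {"primary_photopeak_total": float(photopeak.sum()),
            "scatter_photopeak_total": 0.0,
            "scatter_window_scatter_total": 0.0}

    if opt.include_scatter:
        windows = {"photopeak": opt.photopeak}
        if opt.simulate_scatter_window:
            windows["scatter_window"] = opt.scatter_window
        rng = np.random.default_rng(opt.seed)
        sources = transport_scatter(bundle.activity, bundle.density, spec,
                                    orbit, windows, opt.n_scatter_histories,
                                    rng, max_order=opt.max_order,
                                    energy_resolution=opt.energy_resolution)
        for view in range(n):
            sc = projector.forward(sources["photopeak"][view], view,
                                   mu_scale=_window_mu_scale(opt.photopeak),
                                   time_s=t)
            photopeak[view] += sc
            meta["scatter_photopeak_total"] += float(sc.sum())
            if opt.simulate_scatter_window:
                sc2 = projector.forward(
                    sources["scatter_window"][view], view,
                    mu_scale=_window_mu_scale(opt.scatter_window), time_s=t)
                scatter_win[view] += sc2
                meta["scatter_window_scatter_total"] += float(sc2.sum())

    windows_out = {"photopeak": photopeak}
    if opt.simulate_scatter_window:
        windows_out["scatter_window"] = scatter_win
    return ProjectionSet(windows=windows_out, kind="mean", orbit=orbit,
                         spec=spec, pixel_pitch=projector.pitch, meta=meta)


def add_poisson(projections: ProjectionSet, seed: int) -> ProjectionSet:
    """Draw independent Poisson counts from a mean-kind projection set."""
    if projections.kind != "mean":
        raise ValueError("add_poisson requires mean-kind projections")
    rng = np.random.default_rng(seed)
    counts = {}
    for name, arr in projections.windows.items():
        if np.any(arr < 0):
            raise ValueError("negative means")
        counts[name] = rng.poisson(arr).astype(np.int32)
    return ProjectionSet(windows=counts, kind="counts",
                         orbit=projections.orbit, spec=projections.spec,
                         pixel_pitch=projections.pixel_pitch, rng_seed=seed,
                         meta=dict(projections.meta))
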