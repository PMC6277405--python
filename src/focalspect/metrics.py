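"""Evaluation metrics for the phantom study: VOIs, activity recovery,
recovery profiles, ensemble noise, truncation fractions and equal-noise
scan-time analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import binary_erosion, generate_binary_structure, \
    map_coordinates

from . import collimators as cg
from .phantoms import PhantomBundle
from .volumes import VoxelVolume


@dataclass
class VOISet:
    """Tumor / background-liver / lung volumes of interest."""

    tumor: np.ndarray
    background_liver: np.ndarray
    lung: np.ndarray


def erode_one_pixel(mask: np.ndarray) -> np.ndarray:
    """One pass of 6-connected erosion (partial-volume guard)."""
    return binary_erosion(mask, generate_binary_structure(3, 1))


def geometric_sensitivity_volume(spec: cg.CollimatorSpec,
                                 orbit: cg.DetectorOrbit,
                                 grid: VoxelVolume) -> VoxelVolume:
    """Mean in-crystal magnification product per voxel over the orbit.

    A cheap proxy for the spatial sensitivity pattern of a focusing
    collimator: Mx * My where the voxel projects inside the crystal,
    zero where it does not, averaged over views.
    """
    idx = np.indices(grid.shape).reshape(3, -1).T
    world = grid.world_coords(idx) - orbit.center_mm
    half_u = spec.crystal_extent[0] / 2.0
    half_v = spec.crystal_extent[1] / 2.0
    acc = np.zeros(world.shape[0])
    for view in range(orbit.n_views):
        r_hat, u_hat = orbit.view_frame(view)
        z = orbit.radii_mm[view] - world @ r_hat
        ok = z > 0
        if np.isfinite(spec.focal_length):
            ok &= z < 0.95 * spec.focal_length
        zc = np.clip(z, 1.0, 0.95 * spec.focal_length
                     if np.isfinite(spec.focal_length) else np.inf)
        x = world @ u_hat
        y = world[:, 2]
        u = cg.object_to_detector(spec, 0, x, zc)
        v = cg.object_to_detector(spec, 1, y, zc)
        ok &= (np.abs(u) <= half_u) & (np.abs(v) <= half_v)
        if spec.kind == "parallel":
            m = 1.0
        else:
            mx = _axis_m(spec, 0, u, zc)
            my = _axis_m(spec, 1, v, zc)
            m = mx * my
        acc += np.where(ok, m, 0.0)
    return grid.like((acc / orbit.n_views).reshape(grid.shape)
                     .astype(np.float32), "fraction")


def _axis_m(spec, axis, u, z):
    w, wf = spec.crystal_extent[axis] / 2.0, \
        (spec.focus_extent[axis] / 2.0 if spec.kind == "multifocal"
         else spec.crystal_extent[axis] / 2.0)
    m_conv = spec.focal_length / (spec.focal_length - z)
    if spec.kind != "multifocal":
        return m_conv
    fd = abs(spec.diverge_focal_length)
    return np.where(np.abs(u) <= wf, m_conv, fd / (fd + z))


def build_vois(phantom: PhantomBundle, spec: cg.CollimatorSpec,
               orbit: cg.DetectorOrbit,
               hot_percentile: float = 50.0) -> VOISet:
    """The phantom-study VOIs.

    Tumor: tumor label eroded by one pixel.  Background liver: the
    cone-beam hot region — liver voxels above the ``hot_percentile`` of
    the collimator's geometric-sensitivity map — minus the (uneroded)
    tumor.  Lung: built the same way without a tumor to subtract.
    """
    tumor_label = phantom.mask("tumor")
    tumor = erode_one_pixel(tumor_label)
    sens = geometric_sensitivity_volume(spec, orbit, phantom.labels).data
    liver = phantom.mask("liver") | tumor_label
    lung = phantom.mask("lung")
    bg = liver & ~tumor_label
    thr = np.percentile(sens[liver], hot_percentile) if liver.any() else 0.0
    bg &= sens >= thr
    thr_l = np.percentile(sens[lung], hot_percentile) if lung.any() else 0.0
    return VOISet(tumor=tumor, background_liver=bg,
                  lung=lung & (sens >= thr_l))


def activity_recovery(recon: VoxelVolume, reference: VoxelVolume,
                      voi_mask) -> float:
    """Reconstructed / true activity in a VOI, in percent."""
    voi = np.asarray(voi_mask, dtype=bool)
    if not voi.any():
        raise ValueError("empty VOI")
    ref = float(reference.data[voi].sum())
    if ref == 0:
        raise ValueError("reference VOI holds no activity")
    return 100.0 * float(recon.data[voi].sum()) / ref


def noise_level(realizations, voi_mask, mode: str = "ensemble") -> float:
    """Noise normalized to the mean activity of the VOI.

    ``ensemble`` (default): per-voxel SD across realizations, averaged
    over the VOI, divided by the VOI mean.  ``spatial``: in-VOI spatial
    SD averaged across realizations, same normalization.
    """
    vols = [r.data if isinstance(r, VoxelVolume) else np.asarray(r)
            for r in realizations]
    if len(vols) < 2 and mode == "ensemble":
        raise ValueError("ensemble noise needs at least two realizations")
    voi = np.asarray(voi_mask, dtype=bool)
    if not voi.any():
        raise ValueError("empty VOI")
    stack = np.stack([v[voi] for v in vols])  # (n_real, n_vox)
    mean = float(stack.mean())
    if mean == 0:
        raise ValueError("VOI mean activity is zero")
    if mode == "ensemble":
        return float(stack.std(axis=0, ddof=1).mean()) / mean
    if mode == "spatial":
        return float(stack.std(axis=1, ddof=1).mean()) / mean
    raise ValueError(f"unknown noise mode {mode!r}")


def recovery_profile(recon: VoxelVolume, start_mm, stop_mm,
                     n_samples: int = 100, normalize: bool = True):
    """1D activity profile along a world-space line, optionally
    normalized to its maximum."""
    p0 = np.asarray(start_mm, dtype=float)
    p1 = np.asarray(stop_mm, dtype=float)
    t = np.linspace(0.0, 1.0, n_samples)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    ci = recon.index_coords(pts).T
    if np.any(ci < -0.5) or np.any(ci > (np.array(recon.shape)[:, None]
                                         - 0.5)):
        raise ValueError("profile line leaves the grid")
    prof = map_coordinates(recon.data.astype(np.float64), ci, order=1,
                           mode="nearest")
    if normalize and prof.max() > 0:
        prof = prof / prof.max()
    dist = t * np.linalg.norm(p1 - p0)
    return dist, prof


def truncation_fraction(fov_fraction: VoxelVolume, organ_mask,
                        threshold: float = 0.5) -> float:
    """Percent of the organ seen by more than half of the projections."""
    organ = np.asarray(organ_mask, dtype=bool)
    if not organ.any():
        raise ValueError("empty organ mask")
    seen = fov_fraction.data > threshold
    return 100.0 * float(seen[organ].sum()) / float(organ.sum())


def equal_noise_time(times_s, noise_values, reference_noise: float):
    """Seconds per view at which a noise-vs-time curve matches a
    reference noise level (monotone PCHIP interpolation).

    Returns the interpolated time; raises if the reference noise lies
    outside the sampled curve range.
    """
    t = np.asarray(times_s, dtype=float)
    n = np.asarray(noise_values, dtype=float)
    order = np.argsort(t)
    t, n = t[order], n[order]
    # noise decreases with time; interpolate time as a function of noise
    n_dec = n[::-1]
    t_dec = t[::-1]
    if not np.all(np.diff(n_dec) > 0):
        # enforce strict monotonicity for the interpolant
        n_dec = np.maximum.accumulate(n_dec + 1e-12 * np.arange(len(n_dec)))
    if not (n_dec[0] <= reference_noise <= n_dec[-1]):
        raise ValueError("reference noise outside the sampled curve range")
    interp = PchipInterpolator(n_dec, t_dec)
    return float(interp(reference_noise))


def _power_fit(t, n):
    """Least-squares fit n = a * t^b in log space."""
    b, log_a = np.polyfit(np.log(t), np.log(n), 1)
    return float(np.exp(log_a)), float(b)


def equal_noise_report(curves: dict, reference: str,
                       reference_time_s: float, method: str = "pchip"):
    """Equal-noise scan times of every collimator against a reference.

    ``curves`` maps a collimator name to ``(times_s, noise_values)``.
    ``method`` is ``"pchip"`` (monotone interpolation of the sampled
    curve) or ``"power"`` (least-squares fit of n = a t^b, robust for
    few noise realizations at few durations).  Returns
    ``{name: (seconds, percent_of_reference)}``.
    """
    t_ref = np.asarray(curves[reference][0], dtype=float)
    n_ref = np.asarray(curves[reference][1], dtype=float)
    out = {}
    if method == "power":
        a_ref, b_ref = _power_fit(t_ref, n_ref)
        ref_noise = a_ref * reference_time_s**b_ref
        for name, (t, n) in curves.items():
            a, b = _power_fit(np.asarray(t, float), np.asarray(n, float))
            sec = float((ref_noise / a) ** (1.0 / b))
            out[name] = (sec, 100.0 * sec / reference_time_s)
        return out
    if method != "pchip":
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(t_ref)
    ref_noise = float(PchipInterpolator(t_ref[order],
                                        n_ref[order])(reference_time_s))
    for name, (t, n) in curves.items():
        sec = equal_noise_time(t, n, ref_noise)
        out[name] = (sec, 100.0 * sec / reference_time_s)
    return out
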