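"""Rotate+warp resampling between the object grid and detector-aligned
frames, with an exact adjoint.

For each view the object volume is resampled onto a detector-aligned grid
indexed by (u, v, d): u, v are detector pixel coordinates and d is depth
from the collimator face, sampled at the projection pixel pitch.  The
sample position in the object combines the gantry rotation and the
per-plane focal warp x = u + d * t(u) in a single trilinear interpolation
pass, so that every accepted ray becomes a line of constant (u, v).

The gather (object -> warped) and scatter (warped -> object) operations
use identical trilinear weights, making ``scatter_adj`` the exact matrix
transpose of ``gather`` — the property OSEM back-projection relies on.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import collimators as cg
from .volumes import VoxelVolume


@njit(cache=True)
def _gather_kernel(flat, base, fx, fy, fz, valid, sx, sy, out):
    for i in range(base.size):
        if valid[i]:
            b = base[i]
            ax, ay, az = fx[i], fy[i], fz[i]
            c00 = flat[b] * (1 - az) + flat[b + 1] * az
            c01 = flat[b + sy] * (1 - az) + flat[b + sy + 1] * az
            c10 = flat[b + sx] * (1 - az) + flat[b + sx + 1] * az
            c11 = flat[b + sx + sy] * (1 - az) + flat[b + sx + sy + 1] * az
            out[i] = ((c00 * (1 - ay) + c01 * ay) * (1 - ax)
                      + (c10 * (1 - ay) + c11 * ay) * ax)
        else:
            out[i] = 0.0


@njit(cache=True)
def _scatter_kernel(vals, base, fx, fy, fz, valid, sx, sy, acc):
    for i in range(base.size):
        if valid[i]:
            v = vals[i]
            if v != 0.0:
                b = base[i]
                ax, ay, az = fx[i], fy[i], fz[i]
                wx0 = 1 - ax
                wy0, wy1 = 1 - ay, ay
                wz0, wz1 = 1 - az, az
                acc[b] += v * wx0 * wy0 * wz0
                acc[b + 1] += v * wx0 * wy0 * wz1
                acc[b + sy] += v * wx0 * wy1 * wz0
                acc[b + sy + 1] += v * wx0 * wy1 * wz1
                acc[b + sx] += v * ax * wy0 * wz0
                acc[b + sx + 1] += v * ax * wy0 * wz1
                acc[b + sx + sy] += v * ax * wy1 * wz0
                acc[b + sx + sy + 1] += v * ax * wy1 * wz1


class ViewOperator:
    """Geometry and resampling for one view of an orbit."""

    def __init__(self, spec: cg.CollimatorSpec, orbit: cg.DetectorOrbit,
                 view: int, grid: VoxelVolume, pixel_pitch: float | None = None):
        self.spec = spec
        self.orbit = orbit
        self.view = view
        self.grid_shape = grid.shape
        pitch = pixel_pitch or grid.voxel_size
        self.pitch = pitch
        self.nu, self.nv = cg.detector_shape(spec, pitch)
        self.u_mm, self.v_mm = cg.detector_axes(spec, pitch)

        r_hat, u_hat = orbit.view_frame(view)
        radius = orbit.radii_mm[view]
        # Depth slab covering the object grid along the view direction.
        corners = np.array(np.meshgrid(*[(0, s - 1) for s in grid.shape],
                                       indexing="ij")).reshape(3, -1).T
        world = grid.world_coords(corners) - orbit.center_mm
        s_proj = world @ r_hat
        d_lo = max(radius - s_proj.max() - pitch, 0.5 * pitch)
        d_hi = radius - s_proj.min() + pitch
        if np.isfinite(spec.focal_length):
            d_hi = min(d_hi, 0.95 * spec.focal_length)
        # Anchor the depth planes to the grid-center depth so that, for
        # axis-aligned views, planes coincide with voxel planes and the
        # resampling adds no depth smoothing.
        grid_center = grid.world_coords((np.array(grid.shape) - 1) / 2.0)
        d_center = radius - float((grid_center - orbit.center_mm) @ r_hat)
        k0 = int(np.ceil((d_lo - d_center) / pitch))
        self.nd = max(int(np.floor((d_hi - d_center) / pitch)) - k0 + 1, 1)
        self.d_planes = d_center + (k0 + np.arange(self.nd)) * pitch

        # Restrict the detector window to the object's projected
        # footprint plus the PSF support (the operator is identical to
        # the full-crystal one outside of negligible kernel tails).
        zc = np.clip(s_proj[:, None] * 0 + self.d_planes[[0, -1]][None, :],
                     0.5 * pitch, None)
        uc = cg.object_to_detector(spec, 0, (world @ u_hat)[:, None], zc)
        vc = cg.object_to_detector(spec, 1, world[:, 2:3], zc)
        sig_max = float(np.max(cg.psf_sigmas(
            spec, spec.regions[0], self.d_planes[-1],
            axis_kinds=("focus", "focus") if spec.kind != "parallel"
            else ("parallel", "parallel"))))
        margin = 4.0 * sig_max + 3.0 * pitch
        iu0 = int(np.floor((uc.min() - margin - self.u_mm[0]) / pitch))
        iu1 = int(np.ceil((uc.max() + margin - self.u_mm[0]) / pitch)) + 1
        iv0 = int(np.floor((vc.min() - margin - self.v_mm[0]) / pitch))
        iv1 = int(np.ceil((vc.max() + margin - self.v_mm[0]) / pitch)) + 1
        self.u_slice = slice(max(iu0, 0), min(iu1, self.nu))
        self.v_slice = slice(max(iv0, 0), min(iv1, self.nv))
        self.full_shape = (self.nu, self.nv)
        self.u_mm = self.u_mm[self.u_slice]
        self.v_mm = self.v_mm[self.v_slice]
        self.nu = len(self.u_mm)
        self.nv = len(self.v_mm)

        # Separable sample coordinates (fractional voxel indices).
        x_obj = cg.detector_to_object(spec, 0, self.u_mm[:, None],
                                      self.d_planes[None, :])  # (nu, nd)
        y_obj = cg.detector_to_object(spec, 1, self.v_mm[:, None],
                                      self.d_planes[None, :])  # (nv, nd)
        depth = radius - self.d_planes  # distance center->plane along r_hat
        cx = (orbit.center_mm[0] + depth[None, :] * r_hat[0]
              + x_obj * u_hat[0])  # (nu, nd)
        cy = (orbit.center_mm[1] + depth[None, :] * r_hat[1]
              + x_obj * u_hat[1])  # (nu, nd)
        cz = orbit.center_mm[2] + y_obj  # (nv, nd)
        inv = 1.0 / grid.voxel_size
        fx = ((cx - grid.origin[0]) * inv)[:, None, :]
        fy = ((cy - grid.origin[1]) * inv)[:, None, :]
        fz = ((cz - grid.origin[2]) * inv)[None, :, :]
        shape = (self.nu, self.nv, self.nd)
        coords = np.empty((3,) + shape, dtype=np.float32)
        coords[0] = np.broadcast_to(fx, shape)
        coords[1] = np.broadcast_to(fy, shape)
        coords[2] = np.broadcast_to(fz, shape)
        self._build_weights(coords)

        # Obliquity of the accepted ray per detector pixel.
        self.sec_theta = cg.sec_theta(spec, self.u_mm[:, None],
                                      self.v_mm[None, :])
        self.jacobian = cg.jacobian_sensitivity(spec, self.u_mm[:, None],
                                                self.v_mm[None, :])

    def _build_weights(self, coords):
        n = np.array(self.grid_shape)
        flat = coords.reshape(3, -1)
        cp = flat + 1.0  # padded-frame coordinates
        valid = np.all((cp >= 0.0) & (cp <= n[:, None] + 1.0), axis=0)
        i0 = np.floor(cp).astype(np.int32)
        frac = (cp - i0).astype(np.float32)
        np.clip(i0, 0, n[:, None], out=i0)
        self._pad_shape = tuple(int(s) + 2 for s in self.grid_shape)
        sy = self._pad_shape[2]
        sx = self._pad_shape[1] * sy
        self._base = i0[0] * sx + i0[1] * sy + i0[2]
        self._strides = (sx, sy, 1)
        self._frac = frac
        self._valid = valid

    @property
    def warped_shape(self):
        return (self.nu, self.nv, self.nd)

    def embed(self, window_image: np.ndarray) -> np.ndarray:
        """Place a footprint-window image into the full detector frame."""
        full = np.zeros(self.full_shape, dtype=window_image.dtype)
        full[self.u_slice, self.v_slice] = window_image
        return full

    def extract(self, full_image: np.ndarray) -> np.ndarray:
        """Crop a full detector image to the footprint window."""
        return np.ascontiguousarray(full_image[self.u_slice, self.v_slice])

    def gather(self, vol_data: np.ndarray) -> np.ndarray:
        """Resample the object volume onto the warped (u, v, d) grid."""
        vp = np.zeros(self._pad_shape, dtype=np.float32)
        vp[1:-1, 1:-1, 1:-1] = vol_data
        fx, fy, fz = self._frac
        sx, sy, _ = self._strides
        out = np.empty(self._base.size, dtype=np.float32)
        _gather_kernel(vp.ravel(), self._base, fx, fy, fz, self._valid,
                       sx, sy, out)
        return out.reshape(self.warped_shape)

    def scatter_adj(self, warped: np.ndarray) -> np.ndarray:
        """Exact transpose of :meth:`gather`."""
        vals = np.ascontiguousarray(warped.reshape(-1), dtype=np.float32)
        fx, fy, fz = self._frac
        sx, sy, _ = self._strides
        acc = np.zeros(int(np.prod(self._pad_shape)), dtype=np.float32)
        _scatter_kernel(vals, self._base, fx, fy, fz, self._valid,
                        sx, sy, acc)
        return acc.reshape(self._pad_shape)[1:-1, 1:-1, 1:-1].copy()


def rotate_warp(volume: VoxelVolume, orbit: cg.DetectorOrbit, view: int,
                spec: cg.CollimatorSpec, pixel_pitch: float | None = None):
    """Warp a volume into the detector-aligned frame of one view.

    Returns ``(warped, op)`` where ``warped`` has shape (nu, nv, nd) and
    ``op`` carries the geometry (depth planes, detector axes, adjoint).
    A parallel collimator at gantry angle 0 reduces to the identity
    resampling of the grid (up to the depth-slab crop).
    """
    op = ViewOperator(spec, orbit, view, volume, pixel_pitch)
    return op.gather(np.ascontiguousarray(volume.data, dtype=np.float32)), op
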