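"""Digital phantoms: NEMA IEC image-quality phantom and a synthetic
liver/tumor/lung torso for the quantitative reconstruction study.

All phantoms are generated analytically on a voxel grid — no random
numbers are involved, so generation is exactly reproducible.  Activity is
painted with antialiased (fractional-coverage) organ boundaries and then
rescaled so the total activity matches the request to better than 0.01%.

The liver phantom is a parametric anthropomorphic stand-in: an elliptical
torso with two low-density lungs, a right-lateral liver (~1.6 L at the
default 128x128x90 grid with 4.7 mm voxels) carrying a spherical tumor at
a 5:1 uptake ratio, and a uniform lung shunt.  Organ shapes scale with
the grid extent so that scaled-down studies remain self-similar, while
the tumor radius stays absolute (default 20 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .collimators import DetectorOrbit
from .volumes import VoxelVolume, centered_grid

LABELS = {"air": 0, "body": 1, "liver": 2, "tumor": 3, "lung": 4, "sphere": 5}

DENSITY_AIR = 0.0012
DENSITY_LUNG = 0.26
DENSITY_SOFT = 1.0

# NEMA IEC 2007 sphere set, diameters in mm, mounted on a 114.4 mm circle.
NEMA_SPHERE_DIAMETERS = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
NEMA_SPHERE_RING_RADIUS = 57.2

DEFAULT_GRID = (128, 128, 90)
DEFAULT_VOXEL_MM = 4.7


@dataclass
class PhantomBundle:
    """Co-registered activity, density and label volumes plus body contour."""

    activity: VoxelVolume
    density: VoxelVolume
    labels: VoxelVolume
    body_contour: list = field(default_factory=list)  # per-slice (k, points)

    def mask(self, name: str):
        return self.labels.data == LABELS[name]


def _grids(shape, voxel_size):
    vol = centered_grid(shape, voxel_size)
    idx = np.indices(shape).astype(np.float32)
    coords = vol.origin[:, None, None, None] + idx * voxel_size
    return vol, coords  # coords: (3, nx, ny, nz) world mm


def _sphere_fraction(coords, center, radius, voxel_size):
    """Antialiased coverage fraction of a sphere, per voxel."""
    d = np.sqrt(((coords - np.asarray(center, dtype=np.float32)
                  [:, None, None, None]) ** 2).sum(axis=0))
    return np.clip((radius - d) / voxel_size + 0.5, 0.0, 1.0)


def _ellipsoid_fraction(coords, center, half_axes, voxel_size):
    c = np.asarray(center, dtype=np.float32)[:, None, None, None]
    a = np.asarray(half_axes, dtype=np.float32)
    r_eq = float(np.cbrt(a.prod()))  # equivalent radius for the edge ramp
    q = np.sqrt((((coords - c) / a[:, None, None, None]) ** 2).sum(axis=0))
    return np.clip((1.0 - q) * r_eq / voxel_size + 0.5, 0.0, 1.0)


def _finalize(activity, total_activity):
    s = activity.sum()
    if s > 0 and total_activity is not None:
        activity *= total_activity / s
    return activity


def make_nema_phantom(grid_shape=(128, 128, 64), voxel_size=DEFAULT_VOXEL_MM,
                      sphere_to_background_ratio=10.0,
                      total_activity_bq=100e6) -> PhantomBundle:
    """IEC NEMA 2007 image-quality phantom.

    A water-filled body shell (elliptical cross-section, 300 x 230 mm)
    with the six standard spheres at the given uptake ratio over a
    uniform background; air outside the shell.
    """
    if sphere_to_background_ratio <= 0:
        raise ValueError("sphere-to-background ratio must be positive")
    vol, coords = _grids(grid_shape, voxel_size)
    extent = np.array(grid_shape) * voxel_size
    body_half = np.array([150.0, 115.0, 90.0])
    if np.any(extent / 2.0 < body_half + voxel_size):
        raise ValueError("grid too small to contain the NEMA shell")
    # Body: elliptical cylinder of interior length 180 mm.
    xy = np.sqrt((coords[0] / body_half[0]) ** 2
                 + (coords[1] / body_half[1]) ** 2)
    inside_xy = np.clip((1.0 - xy) * 130.0 / voxel_size + 0.5, 0.0, 1.0)
    inside_z = np.clip((body_half[2] - np.abs(coords[2])) / voxel_size + 0.5,
                       0.0, 1.0)
    body = inside_xy * inside_z

    activity = body.copy()
    labels = np.where(body > 0.5, LABELS["body"], LABELS["air"]).astype(np.int16)
    for i, dia in enumerate(NEMA_SPHERE_DIAMETERS):
        ang = np.deg2rad(60.0 * i)
        center = (NEMA_SPHERE_RING_RADIUS * np.cos(ang),
                  NEMA_SPHERE_RING_RADIUS * np.sin(ang), 0.0)
        frac = _sphere_fraction(coords, center, dia / 2.0, voxel_size)
        activity += frac * (sphere_to_background_ratio - 1.0)
        labels[frac > 0.5] = LABELS["sphere"]

    density = np.where(body > 0.5, DENSITY_SOFT, DENSITY_AIR).astype(np.float32)
    bundle = PhantomBundle(
        activity=vol.like(_finalize(activity, total_activity_bq),
                          "activity_Bq"),
        density=vol.like(density, "density"),
        labels=vol.like(labels, "label"),
    )
    bundle.body_contour = _body_contour(bundle.labels)
    return bundle


def make_liver_phantom(grid_shape=DEFAULT_GRID, voxel_size=DEFAULT_VOXEL_MM,
                       total_activity_bq=100e6, tumor_radius_mm=20.0,
                       tumor_uptake_ratio=5.0, lung_shunt_fraction=0.05
                       ) -> PhantomBundle:
    """Synthetic liver/tumor/lung torso phantom.

    Activity split: the lungs receive ``lsf * total`` uniformly; the liver
    receives the remainder with a tumor-to-parenchyma concentration ratio
    of ``tumor_uptake_ratio``.  The tumor sits in the anterior-right liver
    lobe, near the rotation center, inside every collimator's converging
    field of view at the default orbit.
    """
    if not 0.0 <= lung_shunt_fraction < 1.0:
        raise ValueError("lung shunt fraction must be in [0, 1)")
    vol, coords = _grids(grid_shape, voxel_size)
    ex, ey, ez = np.array(grid_shape) * voxel_size

    body_half = (0.42 * ex, 0.28 * ey, 0.5 * ez - voxel_size)
    liver_c = (0.16 * ex, -0.02 * ey, -0.06 * ez)
    liver_half = (0.165 * ex, 0.090 * ey, 0.165 * ez)
    # left (cross-midline) lobe: thins out toward the patient's left,
    # carrying liver tissue far from the rotation center
    lobe_c = (liver_c[0] - 1.95 * liver_half[0], 0.04 * ey,
              liver_c[2] + 0.35 * liver_half[2])
    lobe_half = (0.110 * ex, 0.065 * ey, 0.085 * ez)
    lung_half = (0.125 * ex, 0.125 * ey, 0.20 * ez)
    lung_cs = ((0.17 * ex, 0.0, 0.22 * ez), (-0.17 * ex, 0.0, 0.22 * ez))
    tumor_c = (liver_c[0] + 0.25 * liver_half[0], liver_c[1],
               liver_c[2] + 0.10 * liver_half[2])

    # Tumor containment: sample the tumor surface against the liver
    # ellipsoid functional.
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(256)
    zs = 1.0 - 2.0 * (k + 0.5) / 256
    rs = np.sqrt(1.0 - zs**2)
    dirs = np.column_stack([rs * np.cos(golden * k),
                            rs * np.sin(golden * k), zs])
    surf = np.asarray(tumor_c) + tumor_radius_mm * dirs
    q = (((surf - np.asarray(liver_c)) / np.asarray(liver_half)) ** 2)
    if np.any(q.sum(axis=1) > 1.0):
        raise ValueError("tumor does not fit inside the liver")

    body = _ellipsoid_fraction(coords, (0, 0, 0),
                               (body_half[0], body_half[1], 10 * ez),
                               voxel_size)
    zcap = np.clip((body_half[2] - np.abs(coords[2])) / voxel_size + 0.5,
                   0.0, 1.0)
    body *= zcap
    liver = np.maximum(
        _ellipsoid_fraction(coords, liver_c, liver_half, voxel_size),
        _ellipsoid_fraction(coords, lobe_c, lobe_half, voxel_size))
    liver *= body
    # Lung and tumor are painted crisply so that organ concentrations
    # (the 5:1 uptake ratio, the uniform shunt) hold voxel-exactly.
    tumor = _sphere_fraction(coords, tumor_c, tumor_radius_mm,
                             voxel_size) > 0.5
    lung_f = np.zeros_like(body)
    for c in lung_cs:
        lung_f = np.maximum(lung_f, _ellipsoid_fraction(
            coords, c, lung_half, voxel_size))
    lung = (lung_f > 0.5) & (liver <= 0.5) & (body > 0.5)
    liver[lung] = 0.0

    labels = np.where(body > 0.5, LABELS["body"], LABELS["air"]).astype(np.int16)
    labels[liver > 0.5] = LABELS["liver"]
    labels[lung] = LABELS["lung"]
    labels[tumor] = LABELS["tumor"]

    density = (DENSITY_AIR + (DENSITY_SOFT - DENSITY_AIR) * body
               ).astype(np.float32)
    density[lung] = DENSITY_LUNG

    # Activity: uniform lung shunt + liver with hot tumor.
    lung_sum = lung.sum()
    act_lung = (lung / lung_sum * lung_shunt_fraction * total_activity_bq
                if lung_sum > 0 else 0.0 * lung)
    liver_weights = liver * np.where(tumor, tumor_uptake_ratio, 1.0)
    act_liver = liver_weights / liver_weights.sum() \
        * (1.0 - lung_shunt_fraction) * total_activity_bq
    activity = (act_lung + act_liver).astype(np.float32)
    activity = _finalize(activity, total_activity_bq)

    bundle = PhantomBundle(
        activity=vol.like(activity, "activity_Bq"),
        density=vol.like(density, "density"),
        labels=vol.like(labels, "label"),
    )
    bundle.body_contour = _body_contour(bundle.labels)
    return bundle


def _body_contour(labels: VoxelVolume) -> list:
    """Per-slice body outline points (world mm) for orbit planning."""
    try:
        from skimage import measure
    except ImportError:  # pragma: no cover - contour is a convenience
        measure = None
    out = []
    body = labels.data > 0
    for k in range(labels.shape[2]):
        sl = body[:, :, k]
        if not sl.any():
            continue
        if measure is None:
            ij = np.argwhere(sl)
        else:
            cs = measure.find_contours(sl.astype(float), 0.5)
            if not cs:
                continue
            ij = np.concatenate(cs, axis=0)
        pts = labels.origin[:2] + ij * labels.voxel_size
        out.append((k, pts))
    return out


def plan_orbit(bundle: PhantomBundle, n_views: int = 120,
               time_per_view_s: float = 20.0, clearance_mm: float = 10.0,
               face_standoff_mm: float = 24.05,
               center_on: str = "liver") -> DetectorOrbit:
    """Body-contour orbit: the collimator face stays ``clearance`` from the
    body surface at every angle, rotating about the liver centroid.

    Radii are measured to the crystal plane, which sits one hole length
    (``face_standoff_mm``) behind the collimator face.
    """
    if n_views < 2:
        raise ValueError("need at least two views")
    labels = bundle.labels
    body = labels.data > 0
    if not body.any():
        raise ValueError("phantom has no body voxels")
    edge = np.array(labels.shape) - 1
    bidx = np.argwhere(body)
    if bidx[:, :2].min() <= 0 or np.any(bidx[:, :2].max(axis=0) >=
                                        edge[:2]):
        raise ValueError("body extends to the transverse grid edge")

    if center_on == "liver" and (labels.data == LABELS["liver"]).any():
        organ = (labels.data == LABELS["liver"]) | \
            (labels.data == LABELS["tumor"])
    else:
        organ = body
    center = labels.world_coords(np.argwhere(organ).mean(axis=0))

    # Surface points suffice for the support function of the body.
    from scipy.ndimage import binary_erosion
    surf = body & ~binary_erosion(body)
    pts = labels.world_coords(np.argwhere(surf)) - center
    angles = np.arange(n_views) * 360.0 / n_views
    radii = np.empty(n_views)
    half_vox = labels.voxel_size / 2.0
    for i, a in enumerate(angles):
        phi = np.deg2rad(a)
        d = np.array([np.cos(phi), np.sin(phi)])
        radii[i] = (pts[:, :2] @ d).max() + half_vox + clearance_mm \
            + face_standoff_mm
    return DetectorOrbit(angles_deg=angles, radii_mm=radii,
                         time_per_view_s=time_per_view_s, center_mm=center)
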