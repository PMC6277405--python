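"""Collimator models: focal geometry, regions, sensitivity and PSF bank.

Three collimator families share LEHR hole parameters and crystal size:

* parallel — holes normal to the detector everywhere,
* cone-beam — all holes converge to a focal point at distance F (here
  50 or 100 cm) in front of the collimator,
* multifocal — a centered focusing zone (half the crystal area, F = 50 cm)
  surrounded by a diverging outer zone whose virtual focus lies behind the
  detector, restoring the parallel-hole field of view.

All geometry reduces to a per-axis *tilt field* t(u): the accepted ray
through detector coordinate u reaches the object point x = u + z * t(u)
at depth z (z measured from the collimator face into the patient).
Converging zone: t = -u/F.  Diverging zone: t = (u - s*w)/|Fd| with s the
side sign and w the crystal half-width; the default diverging focal
length |Fd| = F * (w/w_f - 1) makes the edge hole exactly vertical, so
the multifocal field of view equals the parallel-hole one at every
distance.

Internal units are millimetres; constructors accept the customary cm for
focal lengths and crystal extents.

Depth convention: z is the distance from the *crystal plane* into the
patient.  The collimator slab occupies the first hole length of it, so
the collimator face sits at z = hole_length; orbit radii are measured to
the crystal plane and include that standoff.  Anchoring the focal
mapping at the crystal absorbs the deterministic lateral displacement of
photons traversing tilted holes into the geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import inf

import numpy as np

from .volumes import VoxelVolume

# LEHR hole parameters (mm) and Siemens Symbia-class crystal (mm).
LEHR_HOLE_LENGTH = 24.05
LEHR_HOLE_DIAMETER = 1.11
LEHR_SEPTAL_THICKNESS = 0.16
CRYSTAL_EXTENT_MM = (533.0, 387.0)
FOCUS_EXTENT_MM = (267.0, 194.0)
INTRINSIC_FWHM_MM = 3.8
# Linear attenuation of lead at 140 keV (per cm), used for the septal
# penetration correction of the effective hole length, and of NaI(Tl)
# for the crystal stopping power.
MU_LEAD_140 = 27.1
MU_NAI_140 = 2.22
CRYSTAL_THICKNESS_MM = 9.5

KINDS = ("parallel", "conebeam", "multifocal")
MULTIFOCAL_REGIONS = ("focus_xy", "focus_x_diverge_y",
                      "diverge_x_focus_y", "diverge_xy")
_REGION_AXIS_KIND = {
    "single": None,  # resolved per collimator kind
    "focus_xy": ("focus", "focus"),
    "focus_x_diverge_y": ("focus", "diverge"),
    "diverge_x_focus_y": ("diverge", "focus"),
    "diverge_xy": ("diverge", "diverge"),
}
_HEX_OPEN_FRACTION = np.pi / (2.0 * np.sqrt(3.0))


@dataclass(frozen=True)
class CollimatorSpec:
    """Geometric description of one collimator (all lengths in mm)."""

    kind: str
    focal_length: float  # inf for parallel
    hole_length: float = LEHR_HOLE_LENGTH
    hole_diameter: float = LEHR_HOLE_DIAMETER
    septal_thickness: float = LEHR_SEPTAL_THICKNESS
    crystal_extent: tuple = CRYSTAL_EXTENT_MM
    focus_extent: tuple = FOCUS_EXTENT_MM  # multifocal only
    diverge_focal_length: float = 0.0  # signed; negative = behind detector
    intrinsic_fwhm: float = INTRINSIC_FWHM_MM
    crystal_attenuation: float = MU_NAI_140  # per cm at the photopeak

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown collimator kind {self.kind!r}")
        if self.hole_length <= 0 or self.hole_diameter <= 0:
            raise ValueError("hole dimensions must be positive")
        if self.septal_thickness < 0:
            raise ValueError("septal thickness must be non-negative")
        if self.kind != "parallel" and not self.focal_length > 0:
            raise ValueError("focal length must be positive")
        if self.kind == "multifocal":
            fx, fy = self.focus_extent
            cx, cy = self.crystal_extent
            if not (fx < cx and fy < cy):
                raise ValueError("focus_extent must lie strictly inside "
                                 "crystal_extent")

    @property
    def effective_hole_length(self) -> float:
        """Septal-penetration-corrected hole length L - 2/mu (mm)."""
        return self.hole_length - 2.0 / MU_LEAD_140 * 10.0

    @property
    def parallel_sensitivity(self) -> float:
        """Analytic parallel-hole geometric sensitivity (detected/emitted).

        Derived by integrating the circular-aperture overlap transmission
        over the acceptance cone of a hexagonally packed hole array:
        g = f_open * (d / (4 L_eff))^2 with f_open the hex open fraction.
        """
        d, t = self.hole_diameter, self.septal_thickness
        f_open = _HEX_OPEN_FRACTION * (d / (d + t)) ** 2
        return f_open * (d / self.effective_hole_length) ** 2 / 16.0

    def axis_kind(self, region: str, axis: int) -> str:
        """Hole behaviour ('parallel'/'focus'/'diverge') along one axis."""
        if region == "single":
            return "parallel" if self.kind == "parallel" else "focus"
        if self.kind != "multifocal":
            raise ValueError(f"region {region!r} invalid for {self.kind}")
        return _REGION_AXIS_KIND[region][axis]

    @property
    def regions(self) -> tuple:
        return MULTIFOCAL_REGIONS if self.kind == "multifocal" else ("single",)


def make_collimator(kind: str, focal_length_cm: float | None = None,
                    **overrides) -> CollimatorSpec:
    """Build a collimator with LEHR defaults unless overridden.

    ``focal_length_cm`` is required for cone-beam and multifocal kinds
    (50 or 100 for the cone beams, 50 for the multifocal focusing zone).
    """
    if kind not in KINDS:
        raise ValueError(f"unknown collimator kind {kind!r}")
    if kind == "parallel":
        focal = inf
    else:
        if focal_length_cm is None:
            raise ValueError(f"{kind} collimator requires a focal length")
        if focal_length_cm <= 0:
            raise ValueError("focal length must be positive")
        focal = focal_length_cm * 10.0
    spec = CollimatorSpec(kind=kind, focal_length=focal, **overrides)
    if kind == "multifocal" and spec.diverge_focal_length == 0.0:
        # Calibrated so the outermost hole is vertical: FOV equals the
        # parallel-hole FOV at every source distance.
        w = spec.crystal_extent[0] / 2.0
        wf = spec.focus_extent[0] / 2.0
        spec = replace(spec, diverge_focal_length=-focal * (w / wf - 1.0))
    return spec


# ---------------------------------------------------------------------------
# Per-axis geometry: tilt fields, mappings, magnification
# ---------------------------------------------------------------------------

def _axis_half_extents(spec: CollimatorSpec, axis: int):
    w = spec.crystal_extent[axis] / 2.0
    wf = spec.focus_extent[axis] / 2.0 if spec.kind == "multifocal" else w
    return w, wf


def axis_tilt(spec: CollimatorSpec, axis: int, u_mm):
    """Tangent of the hole-axis tilt along one axis at detector coord u."""
    u = np.asarray(u_mm, dtype=float)
    if spec.kind == "parallel":
        return np.zeros_like(u)
    w, wf = _axis_half_extents(spec, axis)
    tilt = -u / spec.focal_length
    if spec.kind == "multifocal":
        fd = abs(spec.diverge_focal_length)
        s = np.sign(u)
        div = (u - s * w) / fd
        tilt = np.where(np.abs(u) <= wf, tilt, div)
    return tilt


def detector_to_object(spec: CollimatorSpec, axis: int, u_mm, z_mm):
    """Object coordinate at depth z seen through detector coordinate u."""
    u = np.asarray(u_mm, dtype=float)
    return u + np.asarray(z_mm, dtype=float) * axis_tilt(spec, axis, u)


def object_to_detector(spec: CollimatorSpec, axis: int, x_mm, z_mm):
    """Detector coordinate receiving the object point x at depth z."""
    x = np.asarray(x_mm, dtype=float)
    z = np.asarray(z_mm, dtype=float)
    if spec.kind == "parallel":
        return np.broadcast_arrays(x, z)[0].copy()
    f = spec.focal_length
    u_conv = x * f / (f - z)
    if spec.kind == "conebeam":
        return u_conv
    w, wf = _axis_half_extents(spec, axis)
    fd = abs(spec.diverge_focal_length)
    s = np.sign(x)
    u_div = (x + z * s * w / fd) / (1.0 + z / fd)
    return np.where(np.abs(u_conv) <= wf, u_conv, u_div)


def axis_magnification(spec: CollimatorSpec, kind: str, z_mm):
    """In-plane scale factor M(z) for one axis behaviour."""
    z = np.asarray(z_mm, dtype=float)
    if kind == "parallel":
        return np.ones_like(z)
    if kind == "focus":
        f = spec.focal_length
        if np.any(z >= f):
            raise ValueError("source at or beyond the focal point")
        return f / (f - z)
    if kind == "diverge":
        fd = abs(spec.diverge_focal_length)
        return fd / (fd + z)
    raise ValueError(f"unknown axis kind {kind!r}")


def magnification(spec: CollimatorSpec, region: str, z_mm):
    """Magnification mapping object to detector coordinates at depth z.

    Scalar for parallel/cone-beam; an (Mx, My) pair for multifocal
    regions (anisotropic).
    """
    if spec.kind != "multifocal":
        kind = "parallel" if spec.kind == "parallel" else "focus"
        m = axis_magnification(spec, kind, z_mm)
        return float(m) if np.isscalar(z_mm) else m
    mx = axis_magnification(spec, spec.axis_kind(region, 0), z_mm)
    my = axis_magnification(spec, spec.axis_kind(region, 1), z_mm)
    if np.isscalar(z_mm):
        return float(mx), float(my)
    return mx, my


def jacobian_sensitivity(spec: CollimatorSpec, u_mm, v_mm):
    """Flat-detector Jacobian 1/cos^2(theta) at detector position (u, v).

    theta is the inclination of the hole axis reaching that position,
    derived from the per-axis tilt fields of the pixel's region.
    """
    tx = axis_tilt(spec, 0, u_mm)
    ty = axis_tilt(spec, 1, v_mm)
    return 1.0 + tx**2 + ty**2


def sec_theta(spec: CollimatorSpec, u_mm, v_mm):
    """Path-length obliquity factor 1/cos(theta) of the accepted ray."""
    return np.sqrt(jacobian_sensitivity(spec, u_mm, v_mm))


# Gaussian sigma of the circular-aperture overlap response, as a fraction
# of its cutoff radius rho1 = d * z / L_eff (second-moment matched).
APERTURE_SIGMA_FACTOR = 1.0 / (2.0 * np.sqrt(2.0))


def geometric_fwhm(spec: CollimatorSpec, z_mm):
    """Classic geometric collimator resolution FWHM (mm) at distance z.

    The textbook width scale d (L_eff + z) / L_eff; the fast projector's
    Gaussian kernels use the moment-matched :func:`aperture_sigma`
    instead, which is ~20% narrower for circular holes.
    """
    le = spec.effective_hole_length
    return spec.hole_diameter * (le + np.asarray(z_mm, dtype=float)) / le


def aperture_sigma(spec: CollimatorSpec, z_mm):
    """Gaussian-equivalent sigma (mm) of the hole-model response at depth z.

    z is measured from the crystal plane; the response of a source closer
    than one hole length degenerates to the aperture disk itself.
    """
    z = np.maximum(np.asarray(z_mm, dtype=float), spec.hole_length)
    return APERTURE_SIGMA_FACTOR * spec.hole_diameter * z \
        / spec.effective_hole_length


def psf_sigmas(spec: CollimatorSpec, region: str, z_mm, axis_kinds=None):
    """Detector-frame Gaussian sigmas (mm) of the region PSF at depth z.

    The geometric response is magnified onto the detector and combined in
    quadrature with the intrinsic camera resolution.
    """
    if axis_kinds is None:
        axis_kinds = (spec.axis_kind(region, 0), spec.axis_kind(region, 1))
    sg = aperture_sigma(spec, z_mm)
    s_int = spec.intrinsic_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    out = []
    for ax, kind in enumerate(axis_kinds):
        m = axis_magnification(spec, kind, z_mm)
        out.append(np.sqrt((m * sg) ** 2 + s_int**2))
    return tuple(out)


def region_sensitivity_factor(spec: CollimatorSpec, region: str) -> float:
    """Acceptance-plane correction to the region sensitivity.

    The solid-angle amplification of focused holes is set at the
    collimator *face*, one hole length in front of the crystal plane the
    mapping is anchored at; the ratio of the two magnifications is the
    constant (F - L)/F per converging axis ((|Fd| + L)/|Fd| per
    diverging axis).
    """
    factor = 1.0
    for axis in range(2):
        kind = spec.axis_kind(region, axis)
        if kind == "focus":
            factor *= (spec.focal_length - spec.hole_length) \
                / spec.focal_length
        elif kind == "diverge":
            fd = abs(spec.diverge_focal_length)
            factor *= (fd + spec.hole_length) / fd
    return factor


def mean_region_jacobian(spec: CollimatorSpec, region: str,
                         pixel_pitch: float) -> float:
    """Mean 1/cos^2(theta) factor over the pixels of one region."""
    umap, vmap = detector_axes(spec, pixel_pitch)
    uu, vv = np.meshgrid(umap, vmap, indexing="ij")
    jac = jacobian_sensitivity(spec, uu, vv)
    mask = region_id_map(spec, pixel_pitch) == spec.regions.index(region)
    if not mask.any():
        return float(jac.mean())
    return float(jac[mask].mean())


def psf_kernel(spec: CollimatorSpec, region: str, z_mm: float,
               pixel_pitch: float):
    """Explicit 2D detection kernel and its sensitivity scalar.

    Separable Gaussian sampled on the projection pixel grid, normalized
    so its sum equals the region geometric sensitivity: the analytic
    parallel-hole sensitivity times the region's acceptance-plane
    factor.  One kernel per region per depth plane — no intra-region
    shift variance.
    """
    if z_mm < 0:
        raise ValueError("z must be non-negative")
    if pixel_pitch <= 0:
        raise ValueError("pixel pitch must be positive")
    sx, sy = psf_sigmas(spec, region, z_mm)
    half = int(np.ceil(4.0 * max(sx, sy) / pixel_pitch)) + 1
    n = 2 * half + 1
    if n * pixel_pitch > 4 * max(spec.crystal_extent):
        raise ValueError("kernel support exceeds the detector")
    x = (np.arange(n) - half) * pixel_pitch
    gx = np.exp(-0.5 * (x / sx) ** 2)
    gy = np.exp(-0.5 * (x / sy) ** 2)
    kernel = np.outer(gx / gx.sum(), gy / gy.sum())
    sens = spec.parallel_sensitivity * region_sensitivity_factor(spec,
                                                                 region)
    return kernel * sens, sens


# ---------------------------------------------------------------------------
# Detector pixelation, region map, blending
# ---------------------------------------------------------------------------

def detector_shape(spec: CollimatorSpec, pixel_pitch: float):
    return (int(round(spec.crystal_extent[0] / pixel_pitch)),
            int(round(spec.crystal_extent[1] / pixel_pitch)))


def detector_axes(spec: CollimatorSpec, pixel_pitch: float):
    """Pixel-center coordinates (mm) along u and v."""
    nu, nv = detector_shape(spec, pixel_pitch)
    u = (np.arange(nu) - (nu - 1) / 2.0) * pixel_pitch
    v = (np.arange(nv) - (nv - 1) / 2.0) * pixel_pitch
    return u, v


def region_id_map(spec: CollimatorSpec, pixel_pitch: float):
    """Region index per detector pixel (into ``spec.regions``)."""
    nu, nv = detector_shape(spec, pixel_pitch)
    if spec.kind != "multifocal":
        return np.zeros((nu, nv), dtype=np.int8)
    u, v = detector_axes(spec, pixel_pitch)
    infx = np.abs(u)[:, None] <= spec.focus_extent[0] / 2.0
    infy = np.abs(v)[None, :] <= spec.focus_extent[1] / 2.0
    rid = np.empty((nu, nv), dtype=np.int8)
    rid[infx & infy] = 0
    rid[infx & ~infy] = 1
    rid[~infx & infy] = 2
    rid[~infx & ~infy] = 3
    return rid


def blend_weights(spec: CollimatorSpec, pixel_pitch: float):
    """Per-region cross-fade weights over the detector, summing to one.

    Along each axis the focus/diverge boundary is blended linearly over a
    band exactly two pixels wide, per the region-averaging rule.
    """
    nu, nv = detector_shape(spec, pixel_pitch)
    if spec.kind != "multifocal":
        return {"single": np.ones((nu, nv))}
    u, v = detector_axes(spec, pixel_pitch)

    def focus_weight(coord, half_extent):
        # 1 well inside the focus zone, 0 well outside, linear over 2 px.
        return np.clip((half_extent - np.abs(coord)) / (2.0 * pixel_pitch)
                       + 0.5, 0.0, 1.0)

    wx = focus_weight(u, spec.focus_extent[0] / 2.0)[:, None]
    wy = focus_weight(v, spec.focus_extent[1] / 2.0)[None, :]
    return {
        "focus_xy": wx * wy,
        "focus_x_diverge_y": wx * (1.0 - wy),
        "diverge_x_focus_y": (1.0 - wx) * wy,
        "diverge_xy": (1.0 - wx) * (1.0 - wy),
    }


def blend_mask(spec: CollimatorSpec, pixel_pitch: float):
    """Pixels inside the two-pixel averaging border between regions."""
    weights = blend_weights(spec, pixel_pitch)
    stacked = np.stack(list(weights.values()))
    return ~np.any(stacked >= 1.0, axis=0) if len(weights) > 1 \
        else np.zeros(stacked.shape[1:], dtype=bool)


class PSFBank:
    """Precomputed per-region, per-depth kernels and sensitivities."""

    def __init__(self, spec: CollimatorSpec, pixel_pitch: float,
                 z_planes_mm: np.ndarray):
        self.spec = spec
        self.pixel_pitch = pixel_pitch
        self.z_planes_mm = np.asarray(z_planes_mm, dtype=float)
        self.sigmas_px = {}
        self.sensitivity = {}
        for region in spec.regions:
            kinds = (spec.axis_kind(region, 0), spec.axis_kind(region, 1))
            sx, sy = psf_sigmas(spec, region, self.z_planes_mm,
                                axis_kinds=kinds)
            self.sigmas_px[region] = (sx / pixel_pitch, sy / pixel_pitch)
            self.sensitivity[region] = spec.parallel_sensitivity


# ---------------------------------------------------------------------------
# Orbits and field-of-view
# ---------------------------------------------------------------------------

@dataclass
class DetectorOrbit:
    """Non-circular body-contour orbit around the liver centroid."""

    angles_deg: np.ndarray       # (n_views,), strictly increasing over 360
    radii_mm: np.ndarray         # detector face to rotation center, per view
    time_per_view_s: float
    center_mm: np.ndarray        # rotation center (liver centroid), world mm

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.radii_mm = np.asarray(self.radii_mm, dtype=float)
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        if len(self.angles_deg) != len(self.radii_mm):
            raise ValueError("angles and radii must have equal length")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("view angles must be strictly increasing")

    @property
    def n_views(self) -> int:
        return len(self.angles_deg)

    def view_frame(self, view: int):
        """Unit vectors (radial r_hat, transverse u_hat) of one view.

        The detector face lies at ``center + radius * r_hat`` with inward
        normal ``-r_hat``; u is the transverse detector axis and v is the
        world z axis.
        """
        phi = np.deg2rad(self.angles_deg[view])
        r_hat = np.array([np.cos(phi), np.sin(phi), 0.0])
        u_hat = np.array([-np.sin(phi), np.cos(phi), 0.0])
        return r_hat, u_hat


def fov_fraction_map(spec: CollimatorSpec, orbit: DetectorOrbit,
                     grid: VoxelVolume) -> VoxelVolume:
    """Fraction of views in which each voxel projects inside the crystal.

    The artifact-free field of view is conventionally the region with
    fraction > 0.5 (seen by more than half of the projections).
    """
    shape = grid.shape
    idx = np.indices(shape).reshape(3, -1).T
    world = grid.world_coords(idx)
    rel = world - orbit.center_mm
    half_u = spec.crystal_extent[0] / 2.0
    half_v = spec.crystal_extent[1] / 2.0
    count = np.zeros(world.shape[0], dtype=np.int32)
    for view in range(orbit.n_views):
        r_hat, u_hat = orbit.view_frame(view)
        z = orbit.radii_mm[view] - rel @ r_hat
        x = rel @ u_hat
        y = rel[:, 2]
        ok = z > 0
        if np.isfinite(spec.focal_length):
            ok &= z < 0.98 * spec.focal_length
        zc = np.clip(z, 0.0, 0.98 * spec.focal_length
                     if np.isfinite(spec.focal_length) else None)
        u = object_to_detector(spec, 0, x, zc)
        v = object_to_detector(spec, 1, y, zc)
        ok &= (np.abs(u) <= half_u) & (np.abs(v) <= half_v)
        count += ok
    frac = (count / orbit.n_views).reshape(shape).astype(np.float32)
    return grid.like(frac, semantics="fraction")


# ---------------------------------------------------------------------------
# Serialization (structured key/value text)
# ---------------------------------------------------------------------------

def spec_to_text(spec: CollimatorSpec) -> str:
    lines = [f"kind: {spec.kind}"]
    for name in ("focal_length", "hole_length", "hole_diameter",
                 "septal_thickness", "diverge_focal_length",
                 "intrinsic_fwhm", "crystal_attenuation"):
        lines.append(f"{name}: {getattr(spec, name)!r}")
    lines.append(f"crystal_extent: {spec.crystal_extent[0]!r} "
                 f"{spec.crystal_extent[1]!r}")
    lines.append(f"focus_extent: {spec.focus_extent[0]!r} "
                 f"{spec.focus_extent[1]!r}")
    return "\n".join(lines) + "\n"


def spec_from_text(text: str) -> CollimatorSpec:
    fields: dict = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        key = key.strip()
        parts = value.split()
        if key == "kind":
            fields[key] = parts[0]
        elif key in ("crystal_extent", "focus_extent"):
            fields[key] = (float(parts[0]), float(parts[1]))
        else:
            fields[key] = float(parts[0])
    return CollimatorSpec(**fields)
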