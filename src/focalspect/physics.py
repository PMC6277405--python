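"""Photon interaction physics for 99m-Tc imaging.

Covers the 50-160 keV range relevant to the 140 keV photopeak: linear
attenuation of body materials, Compton kinematics with Klein-Nishina
sampling, detector energy windows, and exact (Siddon-type) line integrals
of attenuation through a voxelized density map.

Attenuation model
-----------------
The dominant interaction in soft tissue at 140 keV is incoherent (Compton)
scattering; photoelectric absorption is a small correction and coherent
scattering is neglected.  The water table packaged here is therefore built
from first principles: the Compton component is the Klein-Nishina total
cross-section times the electron density of water, and the photoelectric
component is a steep power law anchored at 140 keV.  Lung and air scale
with mass density relative to water (the phantoms carry a density map in
units of g/cm^3, water = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

# Classical electron radius squared, in barn (1 barn = 1e-24 cm^2).
_R_E2_BARN = 0.0794098
# Electron rest energy, keV.
_MEC2_KEV = 511.0
# Electron density of water, electrons per cm^3.
_NE_WATER = 3.343e23
# Photoelectric linear attenuation of water at 140 keV (per cm) and the
# power-law exponent of its energy dependence in the 50-160 keV range.
_MU_PHOTO_140 = 0.0035
_PHOTO_EXPONENT = 3.0

EMISSION_KEV = 140.0


def klein_nishina_total(energy_kev):
    """Total Klein-Nishina cross-section per electron, in barn."""
    a = np.asarray(energy_kev, dtype=float) / _MEC2_KEV
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log1p(2 * a) / a)
    t2 = np.log1p(2 * a) / (2 * a)
    t3 = (1 + 3 * a) / (1 + 2 * a) ** 2
    return 2 * np.pi * _R_E2_BARN * (t1 + t2 - t3)


def klein_nishina_differential(energy_kev, cos_theta):
    """d(sigma)/d(Omega) per electron in barn/sr at scattering angle theta."""
    a = np.asarray(energy_kev, dtype=float) / _MEC2_KEV
    c = np.asarray(cos_theta, dtype=float)
    ratio = 1.0 / (1.0 + a * (1.0 - c))  # E'/E
    return 0.5 * _R_E2_BARN * ratio**2 * (ratio + 1.0 / ratio - (1.0 - c**2))


def compton_scatter_energy(energy_kev, theta):
    """Photon energy after Compton scattering through angle ``theta`` (rad)."""
    e = np.asarray(energy_kev, dtype=float)
    return e / (1.0 + (e / _MEC2_KEV) * (1.0 - np.cos(theta)))


def mu_water(energy_kev):
    """Linear attenuation of water (per cm), coherent scatter excluded."""
    e = np.asarray(energy_kev, dtype=float)
    compton = _NE_WATER * klein_nishina_total(e) * 1e-24
    photo = _MU_PHOTO_140 * (EMISSION_KEV / e) ** _PHOTO_EXPONENT
    return compton + photo


def mu_compton_water(energy_kev):
    """Compton component of the water attenuation coefficient (per cm)."""
    e = np.asarray(energy_kev, dtype=float)
    return _NE_WATER * klein_nishina_total(e) * 1e-24


# Reference densities, g/cm^3.
MATERIAL_DENSITIES = {"air": 0.0012, "lung": 0.26, "soft_tissue": 1.0, "water": 1.0}


@dataclass(frozen=True)
class Material:
    """A body material with tabulated attenuation, 50-160 keV."""

    name: str
    density: float
    energies_kev: np.ndarray = field(repr=False)
    mu_total: np.ndarray = field(repr=False)  # per cm
    mu_compton: np.ndarray = field(repr=False)  # per cm

    def mu(self, energy_kev):
        return np.interp(energy_kev, self.energies_kev, self.mu_total)

    def mu_c(self, energy_kev):
        return np.interp(energy_kev, self.energies_kev, self.mu_compton)


def make_material(name: str) -> Material:
    if name not in MATERIAL_DENSITIES:
        raise ValueError(f"unknown material {name!r}")
    rho = MATERIAL_DENSITIES[name]
    e = np.arange(50.0, 161.0, 5.0)
    return Material(
        name=name,
        density=rho,
        energies_kev=e,
        mu_total=rho * mu_water(e),
        mu_compton=rho * mu_compton_water(e),
    )


def write_material_table(path, materials=("air", "lung", "water")) -> None:
    """Write the packaged attenuation tables as documented columns.

    Columns: energy_keV, then per material ``mu_total_<name>`` and
    ``mu_compton_<name>`` in 1/cm.
    """
    mats = [make_material(m) for m in materials]
    e = mats[0].energies_kev
    header = ["energy_keV"]
    cols = [e]
    for m in mats:
        header += [f"mu_total_{m.name}", f"mu_compton_{m.name}"]
        cols += [m.mu_total, m.mu_compton]
    np.savetxt(path, np.column_stack(cols), header=" ".join(header), fmt="%.6g")


@dataclass(frozen=True)
class EnergyWindow:
    """Detector energy window defined by center and relative width."""

    center_kev: float
    relative_width: float

    @property
    def low(self) -> float:
        return self.center_kev * (1.0 - self.relative_width / 2.0)

    @property
    def high(self) -> float:
        return self.center_kev * (1.0 + self.relative_width / 2.0)


PHOTOPEAK_WINDOW = EnergyWindow(140.0, 0.15)  # [129.5, 150.5] keV
SCATTER_WINDOW = EnergyWindow(110.0, 0.20)  # [99, 121] keV

# Default NaI(Tl) energy resolution, FWHM fraction at 140 keV.
DEFAULT_ENERGY_RESOLUTION = 0.099
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def window_detection_prob(energy_kev, window: EnergyWindow,
                          resolution_fwhm_140=DEFAULT_ENERGY_RESOLUTION):
    """Probability that a photon of true energy E is recorded in ``window``.

    Gaussian energy blur with absolute FWHM growing like sqrt(E), anchored
    at the fractional resolution stated for 140 keV.  ``resolution`` of zero
    degenerates to a sharp indicator of the window bounds.
    """
    e = np.asarray(energy_kev, dtype=float)
    if resolution_fwhm_140 <= 0.0:
        return ((e >= window.low) & (e <= window.high)).astype(float)
    sigma = resolution_fwhm_140 * 140.0 * _FWHM_TO_SIGMA * np.sqrt(e / 140.0)
    return ndtr((window.high - e) / sigma) - ndtr((window.low - e) / sigma)


class ComptonSampler:
    """Klein-Nishina polar-angle sampler using a tabulated inverse CDF.

    For each tabulated energy the CDF of cos(theta) is integrated and
    inverted onto a regular quantile grid, so sampling is a constant-time
    bilinear lookup in (energy, quantile).  Deterministic given the
    generator state.
    """

    def __init__(self, e_min=20.0, e_max=160.0, n_energy=60, n_quantile=512):
        self.energies = np.linspace(e_min, e_max, n_energy)
        cos_grid = np.linspace(-1.0, 1.0, 2048)
        quantiles = np.linspace(0.0, 1.0, n_quantile)
        inv = np.empty((n_energy, n_quantile))
        for i, e in enumerate(self.energies):
            pdf = klein_nishina_differential(e, cos_grid)
            cdf = np.concatenate([[0.0], np.cumsum(
                0.5 * (pdf[1:] + pdf[:-1]) * np.diff(cos_grid))])
            inv[i] = np.interp(quantiles, cdf / cdf[-1], cos_grid)
        self._inv = inv
        self._nq = n_quantile

    def sample(self, energy_kev, rng):
        """Draw scattering angles for photons at ``energy_kev``.

        Returns ``(theta, e_out)`` arrays matching the input shape.
        """
        e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
        u = rng.random(e.shape)
        ie = np.clip(np.searchsorted(self.energies, e) - 1, 0,
                     len(self.energies) - 2)
        fe = np.clip((e - self.energies[ie])
                     / (self.energies[ie + 1] - self.energies[ie]), 0.0, 1.0)
        q = u * (self._nq - 1)
        iq = np.minimum(q.astype(int), self._nq - 2)
        fq = q - iq
        def look(rows):
            return (1 - fq) * self._inv[rows, iq] \
                + fq * self._inv[rows, iq + 1]
        cos_t = np.clip((1 - fe) * look(ie) + fe * look(ie + 1), -1.0, 1.0)
        theta = np.arccos(cos_t)
        return theta, compton_scatter_energy(e, theta)


def sample_compton(energy_kev, rng, sampler: ComptonSampler | None = None):
    """Sample (theta, E', weight) for Compton scattering at ``energy_kev``.

    The polar angle follows the Klein-Nishina differential cross-section;
    the statistical weight is 1 (analog sampling).
    """
    if sampler is None:
        sampler = _default_sampler()
    theta, e_out = sampler.sample(energy_kev, rng)
    return theta, e_out, np.ones_like(theta)


_SAMPLER_CACHE: list[ComptonSampler] = []


def _default_sampler() -> ComptonSampler:
    if not _SAMPLER_CACHE:
        _SAMPLER_CACHE.append(ComptonSampler())
    return _SAMPLER_CACHE[0]


def line_attenuation(density, voxel_size_mm, origin_mm, p0_mm, p1_mm,
                     energy_kev=EMISSION_KEV):
    """Transmission exp(-integral of mu dl) between two world points.

    Exact voxel-by-voxel (Siddon-type) traversal of the density grid;
    ``density`` is relative to water (g/cm^3).  Deterministic; a
    zero-length ray returns 1.
    """
    p0 = np.asarray(p0_mm, dtype=float)
    p1 = np.asarray(p1_mm, dtype=float)
    d = p1 - p0
    length = float(np.linalg.norm(d))
    if length == 0.0:
        return 1.0
    mu_w = float(mu_water(energy_kev))  # per cm
    # Work in fractional voxel coordinates of voxel *edges*: voxel i spans
    # [i - 0.5, i + 0.5) because origin is the center of voxel 0.
    a0 = (p0 - np.asarray(origin_mm, dtype=float)) / voxel_size_mm + 0.5
    a1 = (p1 - np.asarray(origin_mm, dtype=float)) / voxel_size_mm + 0.5
    dv = a1 - a0
    shape = np.array(density.shape)
    # Entry/exit parameters of the grid box [0, shape] along the segment.
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = np.where(dv != 0, (0.0 - a0) / dv, -np.inf)
        t_hi = np.where(dv != 0, (shape - a0) / dv, np.inf)
    t_min = np.minimum(t_lo, t_hi)
    t_max = np.maximum(t_lo, t_hi)
    # Axes with no motion: inside slab or never inside.
    for ax in range(3):
        if dv[ax] == 0.0:
            inside = 0.0 <= a0[ax] < shape[ax]
            t_min[ax] = -np.inf if inside else np.inf
            t_max[ax] = np.inf if inside else -np.inf
    t_enter = max(t_min.max(), 0.0)
    t_exit = min(t_max.min(), 1.0)
    if t_exit <= t_enter:
        return 1.0
    # All crossing parameters of voxel boundary planes in (t_enter, t_exit).
    ts = [np.array([t_enter, t_exit])]
    for ax in range(3):
        if dv[ax] != 0.0:
            planes = np.arange(0, shape[ax] + 1, dtype=float)
            t = (planes - a0[ax]) / dv[ax]
            ts.append(t[(t > t_enter) & (t < t_exit)])
    t_all = np.unique(np.concatenate(ts))
    t_mid = 0.5 * (t_all[1:] + t_all[:-1])
    seg_len_cm = np.diff(t_all) * length / 10.0
    idx = np.floor(a0[None, :] + t_mid[:, None] * dv[None, :]).astype(int)
    ok = np.all((idx >= 0) & (idx < shape[None, :]), axis=1)
    rho = np.zeros(len(t_mid))
    rho[ok] = density[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    return float(np.exp(-mu_w * np.sum(rho * seg_len_cm)))
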