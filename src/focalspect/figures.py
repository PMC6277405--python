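"""Scaled-down reproductions of the study figures.

Each entry runs a reduced-size version of one experiment (small grid,
fewer views/histories) and writes a PNG plus the underlying numbers as
CSV.  These are demonstration plots, not the acceptance-scale runs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import collimators as cg
from . import metrics as mt
from . import phantoms as phf
from . import projector as prj
from . import recon as rc
from .oracle import mc_oracle_project

GRID = (48, 48, 32)
VOXEL = 7.0
N_VIEWS = 24
COLLIMATORS = {
    "parallel": ("parallel", None),
    "conebeam50": ("conebeam", 50.0),
    "conebeam100": ("conebeam", 100.0),
    "multifocal": ("multifocal", 50.0),
}


def _plt():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def _liver(seed=0):
    bundle = phf.make_liver_phantom(GRID, VOXEL, tumor_radius_mm=15.0)
    orbit = phf.plan_orbit(bundle, N_VIEWS, 20.0)
    return bundle, orbit


def reproduce(name: str, outdir: Path, seed: int = 0) -> Path:
    fn = {"psf": _fig_psf, "nema": _fig_nema, "recovery": _fig_recovery,
          "truncation": _fig_truncation, "profiles": _fig_profiles,
          "noise": _fig_noise}[name]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return fn(outdir, seed)


def _fig_psf(outdir, seed):
    """On-axis vs offset PSF for the cone-beam (50 cm) collimator."""
    plt = _plt()
    spec = cg.make_collimator("conebeam", 50.0)
    orbit = cg.DetectorOrbit([0.0, 180.0], [300.0, 300.0], 1.0,
                             np.zeros(3))
    rng = np.random.default_rng(seed)
    rows = []
    fig, ax = plt.subplots()
    for dx, label in ((0.0, "origin"), (100.0, "dx = 10 cm")):
        res = mc_oracle_project(np.array([50.0, dx, 0.0]), spec, orbit, 0,
                                2_000_000, rng,
                                apply_jacobian_correction=True)
        prof = res.image.sum(axis=1)
        u_nom = float(cg.object_to_detector(spec, 0, dx, 250.0))
        ax.plot(res.u_mm - u_nom, prof / prof.max(), label=label)
        rows.append((label, float((prof * res.u_mm).sum() / prof.sum())))
    ax.set_xlabel("detector offset from mapped position (mm)")
    ax.set_ylabel("normalized PSF")
    ax.legend()
    _save_csv(outdir / "psf.csv", ["source", "centroid_mm"], rows)
    path = outdir / "psf.png"
    fig.savefig(path, dpi=120)
    return path


def _fig_nema(outdir, seed):
    """Fast projector vs MC oracle profiles on a small NEMA phantom."""
    plt = _plt()
    bundle = phf.make_nema_phantom((40, 40, 32), 9.0)
    orbit = phf.plan_orbit(bundle, 8, 20.0, center_on="body")
    rng = np.random.default_rng(seed)
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, (name, (kind, f)) in zip(axes.ravel(), COLLIMATORS.items()):
        spec = cg.make_collimator(kind, f)
        pr = prj.CFDProjector(spec, orbit, bundle.density,
                              pixel_pitch=9.0)
        fast = pr.forward(bundle.activity.data, 0, time_s=20.0)
        orc = mc_oracle_project(bundle, spec, orbit, 0, 2_000_000, rng,
                                pixel_pitch=9.0)
        row = fast.shape[1] // 2
        scale = 20.0 * bundle.activity.data.sum()
        ax.plot(fast[:, row], label="fast")
        ax.plot(orc.image[:, row] * scale, ":", label="oracle")
        ax.set_title(name)
        ax.legend()
    path = outdir / "nema.png"
    fig.savefig(path, dpi=120)
    return path


def _sim_and_fit(bundle, orbit, spec, mode, seed, k=0.5, **kw):
    opts = prj.ProjectorOptions(n_scatter_histories=60_000, seed=seed)
    ps = prj.add_poisson(prj.project(bundle, spec, orbit, opts), seed + 1)
    st = rc.ReconSettings(scatter_mode=mode, dew_k=k, rng_seed=seed,
                          mc_histories_per_iter=40_000, **kw)
    return rc.OSEMModel(ps, bundle.density, st).fit(), ps


def _fig_recovery(outdir, seed):
    """Tumor recovery per scatter-correction mode (parallel hole)."""
    plt = _plt()
    bundle, orbit = _liver(seed)
    spec = cg.make_collimator("parallel")
    vois = mt.build_vois(bundle, cg.make_collimator("conebeam", 50.0),
                         orbit)
    rows = []
    for mode, k in (("mc", 0.5), ("dew", 0.5), ("none", 0.5)):
        res, _ = _sim_and_fit(bundle, orbit, spec, mode, seed, k,
                              save_every_iteration=True)
        rows.append((mode, [res.iterations[i].data[vois.tumor].sum()
                            / bundle.activity.data[vois.tumor].sum() * 100
                            for i in sorted(res.iterations)]))
    fig, ax = plt.subplots()
    for mode, curve in rows:
        ax.plot(range(1, len(curve) + 1), curve, marker="o", label=mode)
    ax.set_xlabel("iteration")
    ax.set_ylabel("tumor activity recovery (%)")
    ax.legend()
    _save_csv(outdir / "recovery.csv", ["mode", "recovery_by_iter"],
              [(m, " ".join(f"{v:.1f}" for v in c)) for m, c in rows])
    path = outdir / "recovery.png"
    fig.savefig(path, dpi=120)
    return path


def _fig_truncation(outdir, seed):
    """Finite vs unbounded detector recovery, cone-beam 50 cm."""
    plt = _plt()
    bundle, orbit = _liver(seed)
    spec = cg.make_collimator("conebeam", 50.0)
    vois = mt.build_vois(bundle, spec, orbit)
    res_t, _ = _sim_and_fit(bundle, orbit, spec, "mc", seed,
                            save_every_iteration=True)
    big = rc.infinite_crystal_spec(spec, bundle, orbit)
    res_u, _ = _sim_and_fit(bundle, orbit, big, "mc", seed,
                            save_every_iteration=True)
    fig, ax = plt.subplots()
    for res, label in ((res_t, "with truncation"),
                       (res_u, "without truncation")):
        curve = [res.iterations[i].data[vois.tumor].sum()
                 / bundle.activity.data[vois.tumor].sum() * 100
                 for i in sorted(res.iterations)]
        ax.plot(range(1, len(curve) + 1), curve, marker="o", label=label)
    ax.set_xlabel("iteration")
    ax.set_ylabel("tumor activity recovery (%)")
    ax.legend()
    path = outdir / "truncation.png"
    fig.savefig(path, dpi=120)
    return path


def _fig_profiles(outdir, seed):
    """Recovery profiles through the tumor per scatter mode."""
    plt = _plt()
    bundle, orbit = _liver(seed)
    spec = cg.make_collimator("parallel")
    center = bundle.labels.world_coords(
        np.argwhere(bundle.mask("tumor")).mean(axis=0))
    half = np.array([80.0, 0.0, 0.0])
    fig, ax = plt.subplots()
    d, p = mt.recovery_profile(bundle.activity, center - half,
                               center + half)
    ax.plot(d, p, "k", label="phantom")
    for mode in ("mc", "dew", "none"):
        res, _ = _sim_and_fit(bundle, orbit, spec, mode, seed)
        d, p = mt.recovery_profile(res.activity, center - half,
                                   center + half)
        ax.plot(d, p, label=mode)
    ax.set_xlabel("position along profile (mm)")
    ax.set_ylabel("activity, normalized to maximum")
    ax.legend()
    path = outdir / "profiles.png"
    fig.savefig(path, dpi=120)
    return path


def _fig_noise(outdir, seed):
    """Noise vs time per view, per collimator (2 noise realizations)."""
    plt = _plt()
    bundle, _ = _liver(seed)
    times = [5.0, 10.0, 20.0]
    vois = mt.build_vois(bundle, cg.make_collimator("conebeam", 50.0),
                         phf.plan_orbit(bundle, N_VIEWS, 20.0))
    fig, ax = plt.subplots()
    for name, (kind, f) in COLLIMATORS.items():
        spec = cg.make_collimator(kind, f)
        noise = []
        for t in times:
            orbit = phf.plan_orbit(bundle, N_VIEWS, t)
            reals = []
            for r in range(2):
                res, _ = _sim_and_fit(bundle, orbit, spec, "none",
                                      seed + r)
                reals.append(res.activity)
            noise.append(mt.noise_level(reals, vois.background_liver))
        ax.plot(times, noise, marker="o", label=name)
    ax.set_xlabel("time per view (s)")
    ax.set_ylabel("noise (normalized to mean)")
    ax.legend()
    path = outdir / "noise.png"
    fig.savefig(path, dpi=120)
    return path


def _save_csv(path, header, rows):
    lines = [",".join(header)]
    lines += [",".join(str(c) for c in row) for row in rows]
    Path(path).write_text("\n".join(lines) + "\n")
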