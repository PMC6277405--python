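# focalspect

Fast Monte Carlo SPECT simulation and quantitative OSEM reconstruction
for focusing collimators, built for liver radioembolization dosimetry
with a 99m-Tc scout dose.

Interventional liver radioembolization would benefit from a SPECT scan
acquired *during* the procedure, which requires both shorter
acquisitions and fast quantitative reconstruction.  Focusing collimators
(cone beam, multifocal) raise sensitivity over the organ of interest and
can shorten scanning, but they bring a shift-variant point spread
function and, for tightly focused designs, truncation artifacts.
`focalspect` implements the complete simulation-study toolchain for this
problem:

* **Collimator models** — parallel hole, cone beam (50 / 100 cm focal
  distance) and a multifocal design with a diverging outer zone, all
  with LEHR hole parameters on a 53.3 x 38.7 cm crystal, including
  region decomposition, sensitivity and distance-dependent PSF models.
* **Fast forward projector** — convolution-based forced detection: a
  single rotate+warp interpolation pass per view, attenuation along the
  accepted rays, one Gaussian convolution per focusing/diverging region
  per depth plane, and Monte Carlo scatter transport with forced
  detection into the photopeak (15% at 140 keV) and scatter (20% at
  110 keV) energy windows.
* **Brute-force Monte Carlo oracle** — per-photon transport with
  explicit hole acceptance, used to validate the fast projector.
* **OSEM reconstruction** — Poisson maximum-likelihood fitting with
  resolution recovery in forward and backward projections (exact
  operator transpose), attenuation correction, and three scatter
  handling modes: Monte Carlo-based, dual-energy window (weight k), or
  none.
* **Digital phantoms and metrics** — NEMA IEC image-quality phantom, a
  parametric liver/tumor/lung torso, body-contour orbits, activity
  recovery, ensemble noise, truncation fractions and equal-noise
  scan-time analysis.

The core model: the measured counts in view $v$ follow
$y_v \sim \mathrm{Poisson}(A_v \lambda + s_v)$, where $\lambda$ is the
activity volume, $A_v$ the CFD system operator (warp, attenuation,
region PSF, sensitivity) and $s_v$ the additive scatter term.  OSEM
iterates $\lambda \leftarrow \frac{\lambda}{A_S^T 1}\, A_S^T
\frac{y}{A_S\lambda + s}$ over angle-interleaved subsets $S$ (8 subsets,
10 iterations by default).

## Worked example

Simulate the liver phantom (100 MBq, 20 mm tumor at 5:1 uptake, 5% lung
shunt) with a parallel-hole collimator at a reduced grid, add Poisson
noise, and reconstruct with Monte Carlo-based scatter correction:

```python
import numpy as np
from focalspect import (make_liver_phantom, plan_orbit, make_collimator,
                        project, add_poisson, ProjectorOptions,
                        OSEMModel, ReconSettings, build_vois)

bundle = make_liver_phantom((64, 64, 44), 4.7)          # 100 MBq default
orbit = plan_orbit(bundle, n_views=32, time_per_view_s=20.0)
spec = make_collimator("parallel")

means = project(bundle, spec, orbit,
                ProjectorOptions(n_scatter_histories=150_000, seed=1))
counts = add_poisson(means, seed=2)

model = OSEMModel(counts, bundle.density,
                  ReconSettings(scatter_mode="mc", rng_seed=3))
result = model.fit()
print(result.summary())

vois = build_vois(bundle, make_collimator("conebeam", 50.0), orbit)
print(f"tumor recovery: "
      f"{result.recovery(bundle.activity, vois.tumor):.1f} %")
```

Output:

```
OSEM reconstruction summary
===========================
grid:            (64, 64, 44) @ 4.7 mm
views:           32 x 20 s (parallel)
subsets x iters: 8 x 10
scatter mode:    mc
total activity:  100.520 MBq
measured counts: 1881525
rng seed:        3
tumor recovery: 106.2 %
```

The recovered total activity lands within 1% of the 100 MBq ground
truth, and the tumor volume of interest (one pixel eroded) recovers
106% — slightly above unity because of edge ringing inside the eroded
sphere.  Re-running with `scatter_mode="dew"` (k = 0.5) and
`scatter_mode="none"` raises the tumor recovery to 114.3% and 119.3%
respectively: uncorrected scatter inflates the apparent activity, and
the dual-energy window only partially removes it — the central
quantitative result of the study.

A `focalspect` command-line tool exposes the same pipeline
(`phantom`, `simulate`, `reconstruct`, `evaluate`, `psf-validate`,
`reproduce-figure`); every stage writes a manifest with its
configuration and seeds, and re-running a stage from the same manifest
reproduces count data bit-identically.

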