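# Methods

`focalspect` simulates and reconstructs liver SPECT acquisitions of a
99m-Tc tracer with four collimator designs — parallel hole, cone beam
(50 cm and 100 cm focal distance) and a multifocal collimator — and
measures how collimator choice, scatter correction and truncation affect
quantitative activity recovery and noise.  This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
studies do and do not demonstrate.

## Collimator geometry

All collimators share LEHR hole parameters (24.05 mm hole length,
1.11 mm hole diameter, 0.16 mm septal thickness) and a 53.3 x 38.7 cm
crystal.  The multifocal collimator focuses over a centered zone of
26.7 x 19.4 cm (half the crystal area) with a 50 cm focal distance and
diverges outside it.

The geometry is expressed as a per-axis *tilt field* t(u): the accepted
ray through detector coordinate u meets the object at
`x = u + z * t(u)`.  Converging zones have `t = -u/F`; diverging zones
`t = (u - s*w)/|Fd|` with `s` the side sign and `w` the crystal
half-width.  The diverging focal length is not a free parameter here: it
is fixed to `|Fd| = F (w/w_f - 1)` (about 49.8 cm for the default
geometry), which makes the outermost hole exactly vertical, so the
multifocal field of view equals the parallel-hole one at every source
distance — the defining property of this design.  The transition between
zones is abrupt in the hole model and cross-faded linearly over a
two-pixel band in the fast projector.

Depths and focal lengths are measured from the **crystal plane**; the
collimator face sits one hole length closer to the patient and orbit
radii include that standoff.  Anchoring the focal mapping at the crystal
absorbs the deterministic lateral displacement of photons traversing
tilted holes (up to two pixels at the crystal edge) into the geometry,
leaving only the small oblique crystal-depth asymmetry (~1 mm) as a
genuine PSF shift.

### Sensitivity and the flat-detector factor

The hole model is a statistical acceptance: the transmission of a
circular-aperture bundle versus incidence angle relative to the local
hole axis, with a hexagonal open fraction and a septal-penetration
corrected hole length `L_eff = L - 2/mu_lead`.  Integrating it gives the
parallel-hole sensitivity `g = f_open (d / 4 L_eff)^2`, about 1.0e-4
for the LEHR geometry.  For focusing zones the point sensitivity is
`g * Mx * My` with the per-axis magnification taken at the collimator
face; relative to the crystal-anchored magnification used by the warp
this is a constant `(F - L)/F` per converging axis, applied as a
per-region factor.

Off-axis, hole diameter and septal pitch grow in proportion to the hole
lengthening, so the angular acceptance is tilt-invariant; integrating
the model over directions shows the detected *total* from an off-axis
point is flat apart from a ~2% rise from oblique crystal absorption.
The classical flat-detector factor 1/cos^2(theta) is therefore a
bookkeeping device of spherical-PSF convolution formalisms and is *not*
multiplied into this projector, whose per-plane focal mapping is linear
and needs no density correction.  `jacobian_sensitivity()` remains
available as the geometric quantity.  The in-repo Monte Carlo oracle
agrees with the resulting sensitivity model to 1-2% on- and off-axis
for all four collimators.

### PSF width

The aperture-overlap response has a second-moment width of
`sigma_geo = d z / (2 sqrt(2) L_eff)` (crystal-plane z), roughly 20%
narrower than a Gaussian carrying the textbook FWHM `d (L_eff + z) /
L_eff`.  The fast projector's Gaussian kernels use the moment-matched
width, magnified per axis onto the detector and combined in quadrature
with the 3.8 mm intrinsic camera resolution.  One kernel per region per
depth plane — intra-region shift variance is deliberately not modeled
(the oracle study shows the mapped centroid shift stays below one
4.7 mm pixel even 10 cm off-axis), which is what makes the projector
fast.

## Photon physics

Water attenuation is computed from the Klein-Nishina total cross-section
times the electron density plus a small photoelectric power law anchored
at 140 keV (coherent scatter neglected); lung (0.26 g/cm3) and air scale
by density.  Compton angles are sampled from a tabulated inverse CDF of
the Klein-Nishina differential cross-section.  Detector energy response
is Gaussian with 9.9% FWHM at 140 keV scaling as sqrt(E) — the typical
NaI(Tl) value, configurable; it controls how much small-angle scatter
lands in the 15% photopeak window and therefore shifts the optimal
dual-energy-window weight.  Photoelectric events terminate histories
(implicit capture by the Compton branch probability); scatter orders are
capped at 3 by default.  Crystal absorption uses a 9.5 mm NaI(Tl) slab
with an E^-2.5 effective attenuation scaling for scattered energies.

## Fast projector (convolution-based forced detection)

Per view, the activity and density grids are rotate+warped into the
detector-aligned frame in a **single trilinear pass** — rotation and the
per-plane focal scaling are combined in one set of sample coordinates,
and the depth planes are anchored to the grid center so axis-aligned
views resample without depth smoothing.  Attenuation becomes a running
sum along the (now axis-aligned) accepted rays with a per-pixel
obliquity factor; each depth plane is then convolved with its region
kernel and the planes are summed.  The back-projection is the exact
matrix transpose of this operator (verified to float precision for all
four collimators), which OSEM resolution recovery relies on.

Scatter uses Monte Carlo transport (Woodcock delta tracking on the
density map) with forced detection: at every interaction the photon
deposits, per view and energy window, a weight proportional to the
Klein-Nishina probability of scattering toward that view's accepted
direction times the window detection probability; the deposited
"effective scatter source" volumes then ride through the same warp +
PSF machinery, with the attenuation exponent rescaled to the window's
center energy.  Projections of the 110 keV scatter window include the
energy-blur leakage of unscattered photopeak photons.

The Monte Carlo **oracle** is the slow validation path: per-photon
importance-cone emission, deterministic ray attenuation, explicit hole
acceptance at the face, oblique crystal interaction depth, post-hoc
intrinsic blur.  It shares the hole-acceptance physics but none of the
convolution shortcuts; on a down-scaled NEMA phantom the fast projector
agrees with it within 3-sigma statistical bands on more than 99% of
detector pixels for all four collimators.

## Reconstruction

OSEM is a Poisson maximum-likelihood fit: 8 subsets (angle-interleaved)
by 10 iterations by default, initialized uniformly inside the body
support, with the estimate frozen at initialization outside the union
field of view.  Scatter handling:

* **mc** — the scatter term is re-simulated each iteration from the
  current activity estimate through the density map (default 1e5
  histories per iteration, smoothed with the same two-pixel Gaussian as
  the DEW term to suppress Monte Carlo noise);
* **dew** — k times the two-pixel-FWHM-smoothed scatter-window counts,
  constant over iterations.  The "two pixels" smoothing width is
  interpreted as FWHM (the sigma reading is configurable);
* **none** — no scatter term.

The optimal k search reconstructs on a grid of k values bracketing the
true photopeak-scatter to scatter-window count ratio (taken from the
simulation metadata) and minimizes the mean squared error against the
phantom over the liver; if the minimum falls on the grid boundary the
grid can optionally be extended, mirroring the procedure of simulating
additional k values around the first estimate.

The truncation-free reference reconstructs projections regenerated with
a crystal large enough to contain every body voxel's projection in
every view (an effectively unbounded detector).

## Phantoms and orbits

The NEMA IEC 2007 image-quality phantom uses the standard six-sphere
set (10-37 mm) at a configurable uptake ratio in a 300 x 230 mm water
shell (the cold lung insert is omitted; it does not participate in any
profile or sensitivity check here).

The liver phantom is a parametric anthropomorphic stand-in: an
elliptical torso, two 0.26 g/cm3 lungs (~3.9 L), and a liver built from
a main right-lobe ellipsoid plus a cross-midline left lobe (~1.9 L at
the default 128 x 128 x 90 grid of 4.7 mm voxels) whose tip reaches
about 20 cm from the liver centroid.  The left lobe is what makes
cone-beam-50 coverage partial, as in real anatomy: at the default orbit
the artifact-free volume (seen by more than half the views) is 93% of
the liver and 28% of the lung, and the 100 cm cone beam sees the entire
liver.  A 20 mm-radius spherical tumor sits in the anterior-right lobe
near the rotation center (inside every collimator's converging zone) at
a 5:1 uptake concentration; the lungs carry a 5% shunt fraction of the
100 MBq total.  Organ shapes scale with the grid extent so scaled-down
studies stay self-similar; the tumor radius stays absolute.  Tumor and
lung are painted crisply so organ concentrations are voxel-exact; other
boundaries are antialiased.  Generation involves no randomness.

Orbits follow the body contour: per gantry angle the collimator face
sits 1 cm outside the body's support in that direction, rotating about
the liver centroid; 120 views over 360 degrees and 20 s per view are
the defaults (a common clinical protocol; the view count is a
configuration choice).

## Metric definitions

Activity recovery is the reconstructed over true activity in a VOI, in
percent.  The tumor VOI is the tumor label eroded by one pixel
(6-connected, one pass).  The background-liver VOI is the cone-beam-50
"hot region": liver voxels above the 50th percentile of that
collimator's geometric-sensitivity map, minus the tumor; the lung VOI
is built the same way.  Noise is the across-realization per-voxel SD
averaged over the VOI, normalized by the VOI mean (an in-VOI spatial-SD
variant is available).  Equal-noise scan times interpolate noise-vs-time
curves either with a monotone PCHIP (dense, well-sampled curves) or a
least-squares power law n = a t^b — the robust choice for small
ensembles, since with three noise realizations the sampled curves
wiggle by a few percent.

## Problem sizes used by the packaged studies

The full clinical-scale configuration (128 x 128 x 90 at 4.7 mm, 120
views, ten noise realizations) is available through the API and CLI.
The packaged validation studies run reduced versions, chosen as the
smallest configurations that leave the measured effects well clear of
their discretization and Monte Carlo noise floors:

* PSF shift-variance: 1e7 oracle histories per source position.
* Projector fidelity: 32^3 NEMA grid at 10 mm, 1.5e6 oracle histories
  per collimator.
* Recovery ladder and optimal k: 64 x 64 x 44 at 4.7 mm, 32 views,
  1.5e5 scatter histories (the acceptance script uses 96 x 96 x 64,
  40 views).
* Truncation: 48 x 48 x 32 at 6 mm, 24 views.
* Scan-time analysis: full-size body on a 64 x 64 x 40 grid of 9.4 mm
  voxels (so source-to-collimator distances, diverging-zone coverage
  and cone-beam truncation are realistic), 16 views, four view
  durations, three noise realizations per point.

## Equal-noise scan times: what the stand-in can and cannot show

The strict ordering of equal-noise times — cone beam 50 < multifocal <
cone beam 100 < parallel — follows from the collimator sensitivities
and is reproduced robustly.  The *absolute* time fractions are not: the
hole model (confirmed by the oracle and by published count ratios for
this geometry) gives an in-FOV local sensitivity gain of roughly 4x for
the 50 cm cone beam over the liver, and with ensemble noise close to
count-limited the matched-noise time then falls near one quarter of the
reference rather than the two-thirds reported for physical systems,
whose reconstruction noise contains sizable non-count-limited
components (scatter-estimate Monte Carlo noise, convergence-rate and
streak effects).  The packaged scan-time study therefore demonstrates
the ordering and the direction of the effect, not clinical time
fractions.

## Known limitations

* The anatomy is a parametric stand-in; absolute truncation fractions
  and count totals depend on it, so anatomy-tied results should be read
  as qualitative reproductions with tolerance bands rather than exact
  matches.
* Reconstructions invert the same forward model that generated the
  projections (no model mismatch); the studies therefore isolate
  collimator/correction effects but do not bound errors from detector
  physics absent in the model (dead time, pile-up, gain variations).
* Septal penetration imaging, bremsstrahlung isotopes (90-Y, 166-Ho),
  respiratory motion and half-cone collimators are out of scope.
* The fast kernel ignores intra-region PSF shape variation (hole growth
  and crystal obliquity are in the oracle only); this is the documented
  acceleration trade-off, sub-pixel for this geometry.
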