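# Methods

This note records the models, numerical choices and known limitations behind
`voxdose`, in the spirit of a methods appendix: what is computed, under which
assumptions, and what the synthetic validation does and does not demonstrate.

## Volumes and coordinates

A `Volume3D` is a node-centered scalar grid: `values[i, j, k]` lives at world
position `origin + orientation @ (index * spacing)`, world frame = DICOM
patient coordinates (LPS), units mm.  NIfTI files are RAS; the adapter applies
the explicit diag(−1, −1, 1) flip on both read and write.  Every reader
applies stored rescale factors (DICOM RescaleSlope/Intercept, NIfTI
scl_slope/scl_inter) so in-memory values are physical; every writer chooses a
slope covering the full dynamic range (16-bit for DICOM).  This is deliberate
defensive design: misread scale factors during DICOM→NIfTI conversion can
silently multiply counts by large factors, which destroys quantification while
leaving images visually plausible.  The round-trip contracts (values within
quantization, totals within 0.1%) are enforced by tests.  A raw NIfTI
`scl_slope` of 0 is treated as 1 with a logged warning; the format's NaN
"no-scaling" marker passes silently.

Resampling (`resample_to_grid`, `reslice`) marks out-of-field voxels in a
validity mask rather than silently zero-filling.  Interpolators: `nearest`,
`trilinear` (default everywhere, including registration), and `cubic` for
accuracy-critical measurement.  Measured on the blurred phantom (10-mm FWHM,
4-mm voxels), a forward-plus-inverse double reslice leaves ~1.1% RMS of max
with trilinear and ~0.1% with cubic; trilinear additionally smooths
sub-resolution features (cold-sphere contrast of the smallest insert drops by
up to ~13% per reslice).  QC-stability analyses therefore use cubic reslice;
the dosimetry pipeline keeps trilinear, whose smoothing is negligible relative
to the 10-mm system resolution of the structures that carry dose.

## Rigid registration

6-DOF transform p′ = R(p − c) + c + t, rotations applied z→y→x about fixed
axes (degrees), rotation center = volume center.  The cost is the mean squared
intensity difference over in-field voxels between the reference and the
target resampled through the candidate transform; out-of-field voxels are
excluded via the mask (zero-filling would reward shrinking overlap).

Both volumes are pre-smoothed with a 7-mm FWHM Gaussian before the cost is
evaluated (configurable, `smoothing_fwhm_mm=0` disables).  This is a
deliberate design choice: with Poisson-noisy volumes, trilinear interpolation
at non-grid offsets *averages* noise, so the raw MSE acquires a spurious dip
away from the true alignment; on a nearly rotation-symmetric object (the
phantom without its fiducial) this displaces the optimum by ~0.8° about the
symmetry axis.  Smoothing correlates the noise over > 1 voxel and suppresses
the artifact; 7 mm matches both the comparator configuration and the
intrinsic resolution.

Optimization is quasi-Newton (BFGS, hand-rolled) on the 6-vector
(tx, ty, tz, rx, ry, rz) with mm and degrees treated 1:1, central-difference
gradients (step 0.05 mm/deg), an Armijo backtracking line search (first trial
step scaled to 1 mm/deg, then doubling expansion while the cost drops), and
an optional coarse search over bed-axis rotations (±15° in 5° steps, on by
default — the rod sectors create rotational local minima).  Stopping rules:
gradient max-norm < 1e-4, parameter-step max-norm < 1e-5, or 100 iterations;
because the tolerances are dimensionless the objective is normalized by its
value at the optimizer's start point.  The returned `final_cost` never
exceeds the cost at identity when the coarse search is on.

The NCC cost (negated Pearson correlation over a 4-mm sample grid after 7-mm
smoothing) is intensity-affine invariant and serves as a cross-check cost,
not the default.

Fiducial handling: `set_origin_on_fiducial` finds the marker as the hottest
connected component outside the main object.  The main object is the largest
component above 50% of max (dilated 2 voxels); candidate thresholds descend
from 90% to 15% of max and the first threshold yielding a component fully
outside that footprint wins.  The descent generalizes a fixed 90%-of-max rule
to blurred markers, whose peak falls well below 90% of the phantom maximum
(partial volume: a 3-mL sphere under a 10-mm PSF peaks near 70%).  Ties break
by larger component, then lowest linear index, with a warning.

## Registration quality and phantom QC

* **%RMSE** = 100·RMSE/Σr, RMSE the root of the mean squared voxel difference
  over the 3-D volume (per-slice values available to match the 2-D
  formulation).  Normalizing by total counts makes the metric invariant under
  joint intensity scaling and numerically small (the denominator is a sum
  over ~10⁵–10⁶ voxels); typical values here are 10⁻⁵–10⁻³ percent.
  Alternative normalizations are deliberately not part of default reports.
* **Uniformity**: IAEA/NEMA-style integral uniformity 100·(max−min)/(max+min)
  per slice after 3×3 in-slice mean smoothing, over a centered circular ROI
  (default 70% of the cylinder radius, eroded 2 voxels), averaged over the
  slices of the uniform compartment.
* **Contrast**: per cold sphere, max and mean variants
  100·(B−min)/B and 100·(B−mean)/B against the mean B of a user-defined
  uniform background region; the sphere minimum is located automatically
  within the sphere mask.
* **Resolution**: a line profile across a rod sector, fitted as baseline plus
  k signed Gaussians (k from peak detection: deviation > 3× the MAD-estimated
  noise, minimum separation one rod pitch); FWHM = 2√(2 ln 2)·σ in mm.  If the
  joint fit fails, each component is refit in a local window; per-rod failure
  flags are returned, never an exception.
* **qc_compare** reports paired deltas and relative changes computed against
  max(|before|, 0.1): a noiseless uniform region has uniformity ≈ 0, where an
  unfloored relative change would be meaningless noise.  No hypothesis
  testing is performed.

QC comparisons across registration place the ROIs in each image's own frame
(rotating the sphere centers and profile line by the ground-truth transform
for unregistered studies): voxel-center classification of sub-resolution
spheres differs between rotated and unrotated voxelizations by up to ~25% in
apparent contrast, which would otherwise masquerade as registration damage.

## Kinetics

Per voxel (or region), the decay segment runs from the activity maximum
(inclusive).  The biexponential A(t) = A₁e^(−λ₁t) + A₂e^(−λ₂t) is fitted on
peak-shifted time for conditioning and converted back to absolute-time
amplitudes; the tail integral from t_peak to infinity is
A₁/λ₁·e^(−λ₁t_peak) + A₂/λ₂·e^(−λ₂t_peak).  The uptake period is integrated by
the trapezoidal rule with A(0) = 0 (`ramp_from_zero`; `flat_from_first`
optional).  TIA maps are in MBq·s.

Numerics: initialization by exponential peeling (slow component from the last
two points); the production fit is Levenberg–Marquardt on log-parameters
(amplitudes a = eᵘ, rates λ = λ_lo + eᵘ) with an analytic Jacobian, falling
back to a bounded trust-region fit, then to mono-exponential, then to
physical-decay extrapolation from the last point (model recorded on the
`DecayFit`).  Decay-rate bounds are [1e-5, 10]/h; when the radionuclide
half-life is supplied the lower bound is the physical decay constant —
effective clearance cannot be slower than physical decay, and without this
bound a few noisy voxels fit λ → 0 and inflate their tail integrals by two
orders of magnitude.  Voxels whose fits pin at the physical bound are counted
and a warning is logged when they exceed 5% (the data asked for
slower-than-physical decay).

With four time points (the clinical sampling this package targets) the
biexponential is at the identifiability edge: the *integral* is the
contracted, tested output; individual (A₁, A₂) splits of a mono-exponential
truth are not unique and are not asserted.

`tia_map` converts counts to MBq via the calibration factor, skips voxels
whose peak is below a relative noise floor (default 1% of the series max —
fitting pure background noise is meaningless), and deduplicates identical
time-activity vectors before fitting (piecewise-uniform synthetic data
collapses to a handful of fits).  The map is homogeneous: scaling the input
by k scales the output by k.

## Dosimetry

Dose(v) = Σ_s TIA(s)·K_{medium(s)}(v−s): sources are split by the *source*
voxel's tissue (bone = CT ≥ 300 HU, inclusive threshold), each group is
convolved with its medium's kernel by FFT with zero padding (no wraparound),
and the results are summed.  Kernel spacing must match the TIA grid exactly —
mismatches raise rather than silently resampling.  FFT round-off (relative
~1e-15) is clipped to zero; energy conservation Σdose = ΣTIA·ΣK holds to
1e-9 for sources whose kernel support is not clipped by the volume boundary.
A spatial-domain direct convolution implemented independently in the test
suite is the oracle (agreement to 1e-10 relative).

The shipped kernels are **analytic toys**: the mean beta energy per decay
deposited in the source voxel mass (self-dose) plus an exponential radial
fall-off with 1/r² weighting and a medium-dependent attenuation length
(bone denser and more attenuating than soft tissue).  They have the right
scale and qualitative shape for Lu-177 / I-131 / Y-90 but are not transport
calculations; provenance strings mark them "not for clinical use".  The JSON
kernel file contract (radionuclide, spacing, medium, provenance, array) is
the injection point for Monte-Carlo-derived tables.

VOI extraction: within the organ region (mask, or hill-climb from a seed
point), the VOI is the 26-connected component containing the dose maximum
among voxels ≥ cutoff·max (default 40%, inclusive).  Mean/max dose and
volume are reported.  Pearson correlation and Bland–Altman limits of
agreement (mean difference ± 1.96 SD, differences a−b) are provided for
method comparison; plotting is left to the caller.

## Synthetic data: what it emulates, and what it does not

The phantom generator voxelizes analytic geometry by voxel-center membership
(no anti-aliasing): a noiseless, PSF-free simulation is *exactly* the
geometric truth, and rotated studies are generated by pulling grid
coordinates back through the inverse transform — registration ground truth
carries no interpolation error.  Partial volume enters only through the
simulated acquisition: isotropic Gaussian PSF (default 10-mm FWHM, typical of
reconstructed SPECT), scaling to a total expected count (default 6·10⁷,
matching 120 views at 5·10⁵ counts per view), and Poisson sampling with an
explicit seed.

Default phantom geometry is a 21.6-cm-bore, 17.4-cm-tall cylinder whose
fillable volume net of inserts is ≈ 6.1 L, filled at 740/6100 MBq/mL (≈ 740
MBq total); six cold spheres (9.5–31.8 mm diameter) on a 60-mm ring, six
60°-sectors of cold rods (4.8–12.7 mm, triangular lattice at twice-diameter
pitch), an acrylic shell (+120 HU) and air outside; the optional 3-mL
fiducial sits just outside the shell.  Sphere and rod diameters are typical
commercial insert sets and fully configurable.  Default grid 128³ at 4.0-mm
isotropic spacing (the transverse matrix of a 128×128 acquisition; the
reconstructed voxel size is scanner-dependent and configurable).  "Clockwise
rotation about the bed axis" is implemented as positive Euler rz about +z
through the volume center; the sign convention is fixed by tests.

The patient-like study places spherical organs (two 24-mm-radius kidneys and
a liver) in a soft-tissue cylinder with a bone rod (+800 HU), each organ
following a linear uptake ramp to the first time point followed by
A₁e^(−λ₁t)+A₂e^(−λ₂t) (kidney defaults A₁ = 25 MBq, λ₁ = 0.05/h, A₂ = 5 MBq,
λ₂ = 0.0045/h — an effective slow phase marginally faster than 6.6-day
physical decay), sampled at 1.5/5/24/240 h.  Counts are activity divided by
the calibration factor (default 10⁻⁵ MBq/count ≈ 10⁵ counts/MBq, a plausible
system sensitivity × acquisition time), optionally Poisson-sampled.  No
additional PSF is applied by default: the series emulates already
resolution-limited reconstructed images, and since the pipeline applies no
recovery-coefficient correction, the dosimetry validation isolates
integration and convolution accuracy from partial-volume bias.

What passing these tests shows: the registration recovers known rigid motion
to a fraction of a degree/voxel at clinical count levels; the integration and
convolution machinery is numerically correct against closed forms and oracles;
the full pipeline reproduces a known dose to ~1% (noiseless) and a few
percent (Poisson).  What it does not show: accuracy under scatter, attenuation
errors, reconstruction artifacts, organ motion/deformation (the model is
rigid by construction), partial-volume recovery, or with physically accurate
S-value kernels — all of which require physical acquisitions or transport
simulation.

## Validation problem sizes

The scripted validation (`scripts/acceptance.py`, mirrored by the acceptance
test suite) runs the rotation experiment on a 72³ grid at 4-mm spacing — the
full-size phantom plus external marker at the default voxel size, with the
grid trimmed to the phantom's footprint — with 3 replicates × {0°, 5°, 10°} ×
{with, without fiducial} = 18 studies at 6·10⁷ counts each, and the patient
pipeline on a 48³ grid with 10 Poisson replicates.  These sizes are the
package's chosen desk-scale validation conditions; all are configurable.

## Known limitations

* Rigid-only registration; organ motion and deformation are out of scope.
* Toy dose kernels; no Monte-Carlo transport, no organ-mass scaling.
* No recovery-coefficient / partial-volume correction in the pipeline.
* Four-point kinetics leaves biexponential parameters under-determined
  (integral contracted instead); uptake is modelled as a linear ramp.
* DICOM support targets uncompressed, single-frame, spatially consistent
  series (secondary-capture-style output); compressed transfer syntaxes are
  whatever the I/O layer provides.
* The %RMSE normalization (total counts) is one of several in use; values are
  comparable only under a fixed convention.
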