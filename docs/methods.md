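# Methods

## The quantity

The striatal-to-reference ratio (SRR) is the mean tracer intensity inside a
striatal volume of interest divided by the mean inside a cerebral-cortical
reference VOI; the specific uptake ratio is SUR = SRR − 1.  Only ratios are
ever computed, so image intensities are treated as arbitrary units and no
calibration to activity concentration is attempted.  Orientation is fixed
throughout the diagnostics: striatal DAT loss lowers the SRR, so a subject
is called diseased when SRR ≤ cutoff.

## Transform model and registration

Spatial normalization maps a template-world point `x` to native world as
`φ(x) = A(x + u(x))`, with `A` a 12-parameter affine (translations,
rotations, scales, shears about the template centre) and `u` a displacement
field expanded in separable low-frequency DCT-II cosine bases over the
template grid, with mm-valued coefficients.  Both stages minimize the sum of
squared differences between the template and the source image smoothed by
8-mm FWHM, resampled trilinearly, and globally intensity-scaled (the scale
is re-estimated in closed form at every cost evaluation).  The affine starts
from all-zero parameters and is solved with a trust-region least-squares
iteration; the nonlinear stage runs a fixed number of Gauss–Newton steps
(default 16) with backtracking only as a divergence guard.  Registration is
fully deterministic — there are no stochastic steps.

Choices the underlying normalization recipe leaves open, fixed here:

- **Basis cutoff.** Frequencies with spatial period below `basis_cutoff_mm`
  (default 25 mm) are excluded; the per-axis order is additionally capped
  (default 5, i.e. shortest period ≈ 74 mm on a 186-mm field of view), which
  keeps the normal equations small while comfortably spanning the smooth
  deformations the phantom generator produces.
- **Regularization.** "Unit regularization" is implemented as a
  bending-energy penalty, diagonal in coefficient space for the separable
  cosine basis: each coefficient is penalized by `(|ω|²)²` with
  `ω_d = π k_d / L_d`, scaled by the sample count and mean squared template
  intensity so the weight is dimensionless and sample-density invariant.
  Stronger weights empirically yield monotonically smaller bending energy.
- **Sampling.** The cost is evaluated on template voxels above 2% of the
  template maximum at stride 2 — a 1/8 subsample that leaves the recovery
  tolerances unchanged on the phantoms while keeping one registration at
  64³ to a few seconds on one CPU.
- **Degenerate inputs.** Constant images are rejected; singular normal
  equations are ridge-stabilized with a logged warning; hitting the affine
  evaluation cap returns the best-so-far transform flagged as unconverged.

The registration target must be comparably smooth to the internally
smoothed source (the classical perfusion-SPECT template is itself very
smooth).  The synthetic workflows therefore use a template carrying both the
PSF blur and an additional 8-mm smoothing; with a sharp template the SSD
is dominated by the blur mismatch and pose parameters become poorly
identified.

## Inversion and VOI pull-back

The affine factor inverts in closed form.  The displacement is inverted by
fixed-point iteration `y ← A⁻¹x − u(y)` on a dense native grid, with `u`
interpolated trilinearly from its template-grid synthesis; iteration stops
when updates fall below 0.01 voxel (cap 50).  The roundtrip residual
`‖φ(ψ(x)) − x‖` is stored per voxel in native-voxel units; transforms whose
forward map folds (non-positive Jacobian determinant anywhere on the
template grid) are rejected outright.  Template VOIs are pulled back by
evaluating the 0/1 mask at each native voxel's template coordinate with
trilinear interpolation and thresholding at 0.5 — sub-voxel boundary
placement that commutes exactly with integer-voxel translations
(nearest-neighbour sampling was rejected as less reproducible).

## Template and VOIs

The normal template is the voxel-wise mean of spatially normalized control
scans, each optionally scaled to unit mean over the reference brain region
first (the scaling is an addition; averaging raw intensities is available
via a flag).  Striatal VOIs are voxels at or above 60% (inclusive) of the
template maximum, split into 26-connected components; the two largest are
assigned left/right by the world-space x sign of their centroids (RAS), and
a single midline-spanning component is split at the mid-sagittal plane.
Caudate and putamen remain merged per side.  The cortical reference VOI is
the union of requested labels of an integer label volume (any atlas, or the
phantom's ribbon ground truth), restricted to an inclusive axial slice
range, minus any striatal voxels.  The label set and slice range are
configuration, not constants.

## Phantom generator

`make_phantom` evaluates a piecewise-constant analytic anatomy — brain
ellipsoid (default semi-axes 65×80×60 mm), cortical ribbon (12 mm,
intensity 1), two striatal ellipsoids (12×20×12 mm at (±26, 10, 2) mm,
intensity = contrast × ribbon), a near-zero CSF/skull gap (6 mm) and a scalp
shell (5 mm, intensity 0.6, included because scalp uptake is substantial in
TRODAT imaging and the registration target needs it) — at the *pulled-back*
coordinates of each voxel, i.e. after applying the inverse pose (6 rigid + 6
affine parameters) and a seeded smooth cosine warp.  The perturbation
therefore introduces no interpolation error, and a noiseless unblurred
phantom's striatum/ribbon ratio equals the requested contrast exactly.  A
Gaussian PSF (default 8 mm FWHM, the scale of reconstructed SPECT
resolution) and noise (Gaussian with sd proportional to local intensity,
default 5%; image-space SPECT noise is not Poisson) are applied afterwards.

What the phantom does *not* emulate: real anatomy (the geometry is
schematic; the algorithms under test depend on topology and contrast, not
anatomical detail), projection-domain physics, scatter, attenuation
artefacts, or inter-subject anatomical variability beyond affine pose and a
smooth warp.  Passing phantom tests therefore demonstrates correctness of
the registration/inversion/ratio machinery, not clinical performance on
patient scans.  With the brain interior and ribbon at equal intensity, the
60%-of-maximum striatal VOI extends somewhat beyond the anatomical striatum,
so threshold-derived VOIs dilute the measured SRR below the true anatomical
contrast; accuracy statements against ground truth use VOIs eroded to the
anatomical core, where the end-to-end pipeline recovers the contrast to
within 3% and is invariant to pose to within 5%.

## Cohort simulator

`draw_srr_cohort` draws per-subject SRRs from Gaussian subgroup
distributions.  The default layout mirrors the emulated study population:
PD split by clinical duration at 2/5/10 years with n = 118/100/87/60 and
SRR 1.55±0.17, 1.48±0.19, 1.43±0.16, 1.35±0.17; healthy controls n = 28 at
2.02±0.20; essential tremor n = 33 at 1.89±0.23.  Normality is the minimal
assumption given only means and SDs; within-subgroup clinical duration is
drawn uniformly inside each subgroup's range (the within-subgroup
distribution is otherwise unknown), and symptomatic side is drawn at random
for PD subjects.  Under this surrogate the replicate-averaged Mann–Whitney
AUCs and the PD sensitivity at cutoff 1.73 reproduce the reference
diagnostic performance to about 0.01 AUC / 1 percentage point; specificity
at that cutoff is *not* reproduced (the Gaussian non-PD mixture yields
≈ 84% where ≈ 90% is expected), indicating the real non-PD SRR distribution
departs from normality — a documented limitation of the surrogate, not a
target.

## Diagnostics

The AUC is the tie-adjusted Mann–Whitney probability
P(control > diseased) + P(tie)/2, computed from average ranks; the threshold
sweep over unique scores provides sensitivity/specificity per candidate
cutoff.  The optimal cutoff maximizes the Youden index (an
accuracy-maximizing criterion is available), with ties broken toward the
higher cutoff, favouring sensitivity for a lower-is-diseased marker.
McNemar's paired χ² uses the continuity correction clamped at zero,
`χ² = max(0, |b−c|−1)² / (b+c)`, with χ² = 0, p = 1 when no discordant
pairs exist.  The two-sample comparison of summary statistics uses Welch's
t (unequal variances and group sizes), via the standard scipy routine.

## Duration model

Bin `k` (k = 1..15) holds clinical durations in `(k−1, k]`, with exact
zeros in bin 1; bins with fewer than 10 subjects are dropped.  The bin
abscissa is the integer year index, not the within-bin mean duration — the
simplest consistent reading of yearly grouping.  The fit is unweighted
ordinary least squares of the bin means on `(x², x, 1)`; R² is computed over
bin means.  The preclinical estimate solves `a·x² + b·x + c = healthy mean`
and takes the negative root nearest zero (the presymptomatic period precedes
onset); a healthy mean below the onset value, a complex root, or two
non-negative roots are rejected as ill-posed, and a healthy mean exactly at
the onset value returns zero years.

## Problem sizes and numerical tolerances

Image tests run at the generator default of 64³ voxels of 2.9 mm.  The
test suite registers on the order of a dozen phantom pairs and runs the
end-to-end inverse-VOI pipeline on several subjects; statistical
reproductions average 200 cohort replicates (seeded, a few seconds total).
Key tolerances: affine self-registration within 0.1 voxel; translation
recovery within 0.2 voxel and in-plane rotation within 0.5°; warp recovery
to ≤ 20% residual SSD in the registration's own (smoothed) matching domain;
inverse roundtrip ≤ 0.2 voxel on ≥ 99% of brain voxels; end-to-end SRR
within 3% of truth and ≤ 5% pose sensitivity; AUC identical to the
exhaustive pair-count oracle to 1e-12; quadratic recovery exact (1e-10) at
zero noise.

## Known limitations

- Single-modality registration only; no CT/MRI anatomical assistance.
- The warp inversion assumes a diffeomorphic (non-folding) estimate; folding
  raises rather than being repaired.
- The cohort surrogate reproduces rank-based diagnostics well but not
  distribution-tail quantities (specificity at a fixed cutoff).
- The conventional-vs-inverse method gap seen on patient data cannot be
  reproduced from summary statistics; the conventional pipeline is exercised
  for agreement and plumbing, not for its published performance deficit.
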