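# Methods

This note documents the models and estimators `dtiqa` implements, the
choices made where the design was genuinely open, what the synthetic phantom
does and does not emulate, and the package's known limitations.

## Diffusion model and tensor estimation

Normalised signals S_m,j = DWI_j / b0 follow the single-tensor
Stejskal–Tanner model S_j = exp(−b ĝ_jᵀ D ĝ_j). Fitting is ordinary
(unweighted) least squares on ln S_m,j over the six unique tensor elements.
On normalised data an intercept column would be exactly collinear with the
three diagonal design columns (per row they sum to −b), so the design has
six unknowns; at least seven gradient directions are still required. The
design condition number is checked and a degenerate gradient table is an
error.

Non-positive or non-finite signals cannot enter the log; each offending
entry is replaced by half the smallest positive value of its own J-vector.
This clamp is shared by the ordinary fit, the bootstrap refits and the SIMEX
refits, so all Monte-Carlo paths exercise the production code path.

FA is computed from eigenvalues clamped at zero and then clipped to [0, 1];
MD is the plain eigenvalue mean (trace/3), retaining negative noise
excursions. FA of the zero tensor is defined as 0. The principal
eigenvector's sign is fixed by making its largest-magnitude component
positive (ties to the lower index), which makes **e1** maps reproducible
under eigenvalue degeneracy. Eigenvalues in the Monte-Carlo hot paths come
from a closed-form trigonometric solver for symmetric 3×3 matrices
(vectorised over voxels × replicates); it is verified against LAPACK in the
test suite at 1e-8.

Robust iterative fitting with per-point outlier rejection is deliberately
out of scope. In its place the report counts, per DWI, the in-mask voxels
whose residual on the intensity scale exceeds 3σ̂
(|S_m − S_f|·b0 > 3σ̂, threshold configurable); this residual count is this
package's own definition and is labelled as such.

## Goodness of fit

The pixel chi-squared normalises each squared residual by the measured
signal itself, χ²_pix = Σ_j ((S_m,j − S_f,j)/S_m,j)², which maps both poor
fits and high noise to large values. The slice statistic sums the same
per-term quantity over the K in-mask voxels of one axial slice of one DWI
and rescales by J/K so a J-term and a K-term sum stay on one scale:
χ²_slice(z, j) = (J/K) Σ_k ((S_m,jk − S_f,jk)/S_m,jk)². Neither statistic
divides by J (they are not reduced chi-squareds); the fixed display range
[0, 0.2] with saturation at 0.2 depends on this convention and the two must
not be changed independently. The denominator is floored at 1e-6 to avoid
division blow-ups at signal voids while preserving "high noise → large χ²".
Slices with no in-mask voxels are missing values and render blank.

The χ²_pix histogram is displayed with an automatic magnification window
[95th percentile, max] around the upper tail: the bulk of voxels form the
signal lobe near zero, so the tail isolates the noise lobe. The percentile
is a parameter; the window is monotone in it.

Voxels in genuinely low-signal tissue (e.g. CSF-like regions at b = 700,
where the normalised signal is ~0.1) can produce very large single-voxel
terms under noise; this is faithful behaviour of the statistic (the same
pattern appears at low-signal brain regions in real data) and slice-level
values there should be read accordingly.

## Noise estimation and subsampling

For each labelled region and each DWI volume the population standard
deviation of the un-normalised intensities is computed (the b0 is excluded);
the median over DWIs gives one estimate per region; the second-smallest
regional value is σ̂. The regional SD mixes true noise with anatomical
variability, so the smallest values approach the noise floor; skipping the
very smallest guards against a single artifact-suppressed region. On
homogeneous-region phantoms σ̂ lands within [0.8, 1.5]× the true σ.

Bootstrap and SIMEX run only on a voxel subsample: a uniform draw of 4% of
the in-mask voxels (default), topped up per region until every region has
min(50, region size) sampled voxels. On clinical-size grids the floor is
inactive and the fraction stays in the few-percent range; on the small
phantom grids used here the floor dominates and drives the effective
fraction to tens of percent, mirroring the small-dataset regime.

## Wild bootstrap (σ_FA)

From one fit, residual magnitudes ε_j = |S_m,j − S_f,j| are shuffled across
gradients, given independent random signs, added to the fitted signals and
refit; the sample SD of the resulting FA population (1000 replicates by
default, ddof = 1) estimates σ_FA. The shuffle-plus-sign scheme is
implemented exactly as stated even though canonical wild bootstrap omits
the permutation, and no leverage or heteroscedasticity corrections are
applied to the residuals. Two consequences, quantified in the tests: OLS
residuals under-represent the noise by ≈ √(1 − 6/J), and resampling
normalised signals cannot see b0-noise variability (a uniform log offset
lies in the design column space), so σ_FA runs some 15–20% below the full
repeated-acquisition SD when the b0 is a 5-average (the common protocol)
and more when it is single-shot. Replicates whose synthetic signals have no
positive entry are dropped; voxels losing >10% of replicates are flagged.

## SIMEX (B_FA)

Un-normalised DWIs and the b0 are further corrupted with stacked Rician
noise — magnitude of (signal + N(0, ωσ̂²)) + i·N(0, ωσ̂²), independently per
volume — at ω = 2, 4, 6, 8 with 2000/4000/6000/8000 replicates by default.
The mean refitted FA per level, together with the measured FA anchored at
ω = 0, is fit by an unweighted quadratic in ω and extrapolated to ω = −1,
where the total variance σ̂² + ωσ̂² vanishes; B_FA = FA_measured −
FA_extrapolated. Including the ω = 0 point is standard SIMEX practice and
anchors the quadratic; the fit is unweighted (replicate counts differ per
ω, but the trend means are all tight relative to the curvature). σ̂ = 0
short-circuits to zero bias with a flag.

Operating range: with the quadratic extrapolant and these ω levels, SIMEX
tracks the brute-force empirical bias to ~1e-3 for b0-SNR ≳ 15 and degrades
as the added noise pushes the FA trend onto its saturation plateau; at
b0-SNR 5 the trend is flat by ω = 2 and the extrapolation recovers only a
small fraction of the (large, ~0.24) true bias. This is a property of the
simulation–extrapolation idea itself, not of the implementation, and the
test suite pins both regimes.

## Power

Power of the two-sided two-sample t-test with per-group size n, common SD
s = σ_FA, and bias difference ΔB at effect size ES:

    power = 1 − F_nct(t_crit; 2n−2, δ) + F_nct(−t_crit; 2n−2, δ),
    δ = (ES + ΔB) / (s·√(2/n)),

with t_crit the central-t (1 − α/2) quantile, α = 0.05 by default. The
noncentral-t form satisfies every required property exactly — reduction to
the textbook equation at ΔB = 0, power α at the minimum ES = −ΔB, symmetry
about the minimum — and is verified against a simulated-rejection oracle; a
shifted-central-t approximation was rejected as less exact. δ = 0 is
evaluated through the central t for exactness at the minimum, and deep-tail
NaNs from the noncentral CDF are repaired via the nc → −nc symmetry.
Regional curves take per-voxel power with that voxel's (σ_FA, B_FA), with
ΔB ∈ {0, B_FA} (worst case: the comparison group is assumed unbiased), and
record the per-effect-size median over the region's sampled voxels for
n ∈ {5, 15, 30} on a 101-point ES grid over [−0.1, 0.1]. s = 0 voxels are
excluded as degenerate.

## Regional features, PCA and outliers

Per region, Tukey boxplot statistics plus mean and population SD are
computed for MD and FA over all in-mask voxels and for σ_FA and B_FA over
the sampled voxels, for both the full 25-region set and a pooled 14-region
set. "Mean and SD" are of the underlying per-voxel values, not of the five
boxplot numbers — the simplest reading consistent with
14 × 4 × 2 = 112 features. The 25→14 pooling is a configuration mapping
(region name → label list); the phantom's scheme of 11 bilateral pairs + 3
midline regions supplies the default, and users with real label dictionaries
supply their own. The canonical feature order is region-major over sorted
region names, then metric (MD, FA, σ_FA, B_FA), then (mean, SD).

Cohort embedding: columns are z-scored (constant columns dropped and
recorded; NaN cells imputed with column means and counted), then SVD-based
PCA; component signs are fixed by making each loading's largest-magnitude
entry positive. Outlier flagging is per protocol group (≥ 4 members): each
score component is reduced to a robust z (distance from the group median
over 1.4826·MAD, with an SD fallback when the MAD is zero) and the Euclidean
norm across components is flagged above 3.5. The 3.5 robust-z threshold is
this package's calibration choice; homogeneous groups stay unflagged at it
and a planted 3×-noise member is caught.

## The phantom: what it emulates, what it does not

The generator builds an ellipsoidal "brain" tiled into 25 regions (rank-based
equal-count axial bands per hemisphere plus a midline column), assigns each
region an axially symmetric tensor — FA 0.1–0.9 and MD 0.6–1.2 ×10⁻³ mm²/s
across the bilateral pairs with rotating principal directions, isotropic
mid-line regions up to CSF-like 3.0 ×10⁻³ — and simulates intensities
through the forward model at b0_intensity 1000 with independent Rician
noise (default σ = 40, i.e. SNR 25, a typical clinical 3T operating point).
Gradient tables come from seeded electrostatic repulsion with antipodal
symmetry; protocol pieces (table, tensors) are seed-invariant so different
phantom seeds redraw only the noise. Artifacts are injected after the
noise: per-gradient dropout, per-slice intensity offsets, synthetic motion
rows. Cohorts draw fresh per-member seeds and can scale individual members'
noise to plant known outliers.

Not emulated: real anatomy and partial-volume mixing, EPI/eddy-current
distortion, spatially correlated or multi-coil noise, motion as an actual
image transformation (motion parameters are metadata only), and
between-region tensor continuity. Passing tests therefore demonstrate the
estimators' correctness and calibration under the stated noise model, not
robustness to geometric artifacts of real acquisitions.

## Problem sizes and numerical details

Library defaults follow the full method (bootstrap 1000 replicates; SIMEX
2000–8000 per ω). The pipeline's fast configuration — bootstrap 100, SIMEX
200 per ω — together with phantom grids of 24³–32³ and the 50-voxel
per-region sampling floor are the package's scaled-down study sizes for the
test suite and the acceptance script; both complete in a few minutes on one
CPU. All estimators are vectorised over voxels × replicates with memory
chunking (≈ 8M elements per batch). Every stage's randomness derives from
one master seed split per stage; reruns are bit-identical.

## Known limitations

- Single-shell, single-tensor only; multi-b-value series are rejected at
  load.
- Registration, brain extraction and segmentation are inputs, not steps;
  "stored input volumes" are unregistered, and gradient rotation after
  motion correction is supported only via pre-rotated bvec files.
- σ_FA is expected to under-read the full repeated-acquisition SD (see the
  wild-bootstrap section); B_FA is unreliable below b0-SNR ≈ 10.
- The report's visual design is functional, not a reproduction of any
  particular layout; content presence, alignment of the per-DWI abscissa
  and the colour conventions (χ² saturation at 0.2, e1 RGB = RL/AP/FH,
  FA scale [0, 1]) are the contract.
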