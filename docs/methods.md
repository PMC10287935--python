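# Methods

This note documents the models, defaults and numerical choices behind each
stage of the package, what the synthetic-data generators do and do not
emulate, and the problem sizes used in the shipped verification suite.

## Imaging geometry and units

All image operations work in voxels on (z, y, x) arrays; physical-unit
outputs are converted with a user-supplied voxel size. The default
`SceneSpec` mirrors the cluster acquisitions this package targets: a
512 x 512 px field, 21 z-planes at 250 nm steps. The xy pixel size of such
setups is instrument-specific and is **not** assumed anywhere: it defaults
to 100 nm (a typical EM-CCD + 1.6x optovar scale) and is overridable in
every function that reports micrometres.

## Segmentation

Cells are segmented on the maximum-intensity z-projection: Gaussian smooth
(σ = 2.5 px) → Otsu threshold (256 bins over the observed range) → hole
filling → removal of features under 200 px (no principled value exists;
exposed as `min_area`) → watershed split seeded by local maxima at least
40 px apart. Among equal-intensity maxima closer than the separation limit,
the one with smaller (y, x) wins — a tie-break chosen purely for
determinism. Per cell, the nucleus is the largest connected component above
an Otsu threshold computed on the brightest 75% of the cell's nonzero
projected intensities. Degenerate inputs (constant images, too-small cells)
produce empty masks with QC flags rather than errors: flags replace the
manual mask curation step of interactive workflows so that batch runs stay
auditable.

## Spot detection and fitting

Detection band-passes the stack with a difference of Gaussians (narrow
σ_xy = 1.245 px / σ_z = 0.795 pl minus wide 2.075 px / 1.325 pl; the smaller
value of each pair is taken as the narrow blur) and keeps strict
26-connected local maxima above an absolute threshold. No universal
threshold exists — it is a required per-channel setting, with
`threshold_from_sd` providing k x the MAD-based robust SD of the response
(k = 10 for bead fields, lower for cellular channels).

Fitting happens in an 11 x 11 x 7 ROI (clipped at stack borders) in two
stages:

1. **Iterative moment analysis.** The tilted background is least-squares
   fit to the voxels on the six ROI faces and subtracted; the
   background-subtracted ROI is multiplied by a Gaussian window of PSF size
   (σ_xy = 1.66 px, σ_z = 1.06 pl) centered on the current position, and the
   position is updated by intensity centroiding. Iteration stops when the
   move drops below `move_tol` (default 1e-3 voxel — "no significant
   improvement" made concrete), the position drifts more than 3 voxels from
   the candidate, or 20 iterations pass. I and the widths then come from
   second central moments. Because the ROI is finite, the raw second moment
   saturates below the true variance; the width is recovered by inverting
   the truncated-normal variance relation s² = σ²(1 − 2cφ(c)/(2Φ(c) − 1)),
   c = L/σ, with Brent's method per axis, and I is divided by the Gaussian
   mass inside the ROI. The inversion is one of several possible
   finite-domain corrections; it is exact for a centered spot and smooth in
   its inputs.
2. **Weighted log-residual optimisation.** L-BFGS-B (analytic gradient,
   ftol 1e-14) minimises Σ w (log model − log data)² with w a Gaussian of
   twice the PSF size (σ_xy = 3.32 px, σ_z = 2.12 pl) centered on the
   moment-analysis position, so a brighter neighbour inside the ROI cannot
   capture the fit. Model and data are clamped at 1 count before the logs
   (EM-CCD baselines near zero would otherwise explode the residuals).
   Bounds keep the fit physical: center inside the ROI, σ ∈ [0.3, 10]
   voxels, I ≥ 0; the four background coefficients are free.

Goodness of fit is the adjusted R², reported three ways: the full model
against the ROI (10 parameters), the Gaussian term against the
background-subtracted ROI (6), and the plane against voxels outside the
2σ ellipsoid of the center (4). The peak/background data partition is a
definition choice; nothing in the downstream filters is sensitive to its
exact radius.

Filters, in order: fits that moved > 3 voxels from their candidate;
duplicates closer than 0.1 x the PSF size under the PSF-normalised distance
√(Δx²/σ_xy² + Δy²/σ_xy² + Δz²/σ_z²) (first in input order wins); fits
outside the cell mask; fits with peak adjusted R² ≤ −1. PSF-normalised
rather than isotropic distance is used for deduplication because the z PSF
is wider than a z-step; with the 0.1 factor both conventions reject only
near-coincident fits. Filtering is idempotent.

## σ → diameter calibration

The empirical relation d = ((σ^β − σ₀^β)/α)^{1/β} is fit as σ(d) by
unweighted nonlinear least squares (residuals in σ — the measured quantity;
the alternative of residuals in d is not distinguishable from published
parameter values), with 1-SD uncertainties from the Jacobian. σ₀ transfers
between objectives by the NA ratio (σ₀ scales inversely with NA). Cluster
diameter ranges are reported from the 1.5x-IQR whisker bounds of the σ
sample (quartiles by linear interpolation), with the lower bound clipped to
σ₀ where the whisker falls below the point-source width.

## Channel registration and colocalization

Beads imaged in both channels are localized with the standard pipeline at a
10x SD threshold, paired by mutual nearest neighbours in xy within a 10 px
gate (the gate is ours; unpaired detections otherwise corrupt the affine),
filtered component-wise by the 1.5x-IQR rule, and least squares gives the
2D affine mapping cluster-channel coordinates into the reference channel.
The z correction is a single focus offset: the IQR-filtered mean of paired
z differences. Affine estimation from fitted bead centroids (rather than
intensity-based registration of the projections) is used because it is
fully determined by the bead correspondences and carries an interpretable
residual.

Per reference-bearing cell — the reference label being the in-nucleus spot
with maximal I_p, ties broken by input order — the NND is the minimal 3D
(or 2D, xy-only after registration; z is excluded entirely in 2D mode)
distance to any cluster in that cell. Cells whose reference has no cluster
keep a missing NND but stay in the denominator, so the 0.1-μm-binned
histogram bars sum to the fraction of reference-bearing cells with at least
one cluster. Overlap fractions use a 0.4 μm threshold by default; per-bin
and per-fraction errors come from 1000 bootstrap resamples over cells (not
spots — cells are the independent unit), and condition differences use the
two-sided Fisher exact test.

## Cluster statistics

Counts per cell are histogrammed with cell-level bootstrap SEMs; metric
distributions are summarised by quartiles and 1.5x-IQR whiskers. Conditions
are compared by Kruskal–Wallis followed by two-sided pairwise Mann–Whitney
U (exact enumeration for tie-free samples with both n ≤ 20, otherwise the
normal approximation with tie and continuity corrections). Raw pairwise
p-values are reported by default, matching common practice for these
comparisons; Holm adjustment is available but off.

## Burst kinetics

Movies are drift-corrected by registering each frame's max projection to
the first by subpixel phase cross-correlation. The shift is a
translation-only affine: stage drift has no rotation/scale component, and a
full 6-parameter fit on near-identical frames adds variance without
reducing residuals.

Tracking measures one TS per cell per frame on the background-subtracted
max projection by iterative 2D Gaussian-mask photometry (mask of PSF width;
with unit-integral Gaussian weights W, Σ W·D / Σ W² estimates the spot's 2D
integrated intensity). Detection is hierarchical: a fresh candidate above
8x the background SD; failing that, a re-fit within 5 px of the last
detected position above 6x; failing that, readout at the previous position
(positional hold). A cell with no detection in any frame is flagged
inactive. Manual steps of interactive workflows are replaced by automatic
rules: trace endpoint = last on frame (+ configurable tail), exclusions via
QC flags, active = at least one on-run.

The background SD per cell is estimated from Gaussian-mask intensities at
four points at a fixed radius (default 5 px — not a critical choice, any
radius clear of the PSF works) around the TS in every frame, pooled and fit
by a maximum-likelihood Lorentzian (Cauchy); heavy-tailed contamination
from neighbouring structures motivates the Lorentzian over a plain SD. The
Cauchy scale γ converts to a Gaussian-equivalent SD by quantile (IQR)
matching, σ = 2γ/1.349. FWHM matching (σ = 2γ/2.3548) is also available but
is strongly biased on truly Gaussian backgrounds — the ML Cauchy scale on
normal data is only ≈0.6σ, so FWHM matching returns ≈0.5σ, while quantile
matching returns 0.88–0.92σ and is exact on genuinely Cauchy backgrounds.

Binarization thresholds at 6x the background SD, then merges on-runs
separated by exactly one off frame and removes remaining single-frame
on-runs — in that order. Bridging before removal is the only order under
which both clean-up behaviours hold simultaneously (two single-frame
detections one frame apart become one burst; an isolated single-frame
excursion is dropped), and it guarantees the output contains no length-1
on-run and no enclosed length-1 gap. Burst durations are on-run lengths x
the 15 s frame interval; runs touching the final analyzed frame are
included by default (`drop_right_censored=True` excludes them), inter-burst
times are enclosed off-gaps, induction time is the first on frame, burst
intensity the mean intensity over on frames. Kinetic means carry
1000-repeat bootstrap-over-cells errors; active fractions carry Poisson
(√n) errors. Conditions are compared by a two-sample bootstrap test: both
samples are shifted to the pooled mean (imposing the null), resampled, and
the achieved significance level is the fraction of replicates whose
absolute difference reaches the observed one.

## Synthetic data: what it does and does not emulate

The generators render exactly the models the analysis assumes: Gaussian
spots on tilted planes, smooth ellipsoidal cells with brighter nuclei,
bead fields related by an affine + z offset, and telegraph-model
(two-state, exponential switching) transcription traces in which
transcripts initiate as a Poisson process while on and reside at the TS for
a fixed dwell time — the simplest choice that produces plateau-shaped
bursts for the binarizer to recover. Camera noise is Gaussian read noise
plus Poisson shot noise with configurable gain. Gaussian evaluation is
truncated at 5σ where speed matters (mass lost < 1e-5); noiseless renders
are exact evaluations of the stated models.

Deliberately not emulated: real PSF structure (no pupil/aberration model),
photobleaching, illumination gradients, cell motility and division, and
autofluorescence texture. Tests passing on this data therefore demonstrate
correctness of the algorithms under their own model assumptions — recovery
of known parameters, agreement with brute-force oracles, calibrated error
rates — not robustness to every artefact of real acquisitions; threshold
settings in particular must still be chosen per dataset.

## Verification problem sizes

The shipped suite checks, among others: exact parameter recovery on 200
noiseless spots (worst-case relative error ~1e-6, asserted < 1%); fitted σ
CV < 5% across a 10x intensity span; registration recovery to < 0.05 px /
0.05 plane from 20 beads with one 10 px outlier; NND and overlap agreement
with exhaustive pairwise computation on 50 random scenes and Fisher p
against hypergeometric enumeration over all 2x2 tables with margins ≤ 15;
binarization against brute force on all 2046 binary sequences of length
≤ 10; burst kinetics from 500 one-hour traces at k_on = k_off = 1/120 s⁻¹
against an independently simulated discretized expectation (4000 traces);
and 1000-trial null calibration of the Mann–Whitney and bootstrap-ASL tests
at α = 0.05. These sizes keep the whole suite around a minute while leaving
Monte-Carlo margins comfortably inside the asserted tolerances.

## Known limitations

- The moment-analysis domain correction assumes the spot is roughly
  centered in its ROI; spots within ~2 voxels of a stack border are fit on
  clipped ROIs and their initial σ estimate degrades (the optimisation
  stage usually recovers).
- The duplicate filter keeps the first fit in input (detection-response)
  order; a different ordering convention would keep a different member of a
  near-coincident pair.
- Tracking assumes at most one TS per cell, as appropriate for a single
  tagged locus.
- The telegraph simulator's fixed transcript dwell time is a simplification;
  exponential dwell would smear burst edges further.
- No multiple-testing correction is applied by default to pairwise
  Mann–Whitney p-values (Holm is available via `holm_correct`).
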