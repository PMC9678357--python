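# Methods

`plastimap` implements the two computational arms of a longitudinal
motor-learning plasticity study in mice — voxelwise morphometry with
trajectory model selection, and quantitative 3D reconstruction of
myelinated axons from confocal stacks — plus the supporting densitometry
and behavior scoring, all driven by synthetic-data generators that emulate
the study's data structure.

## Trajectory model selection

All arms share one question: does a measured quantity change over the
14-day training window linearly, asymptotically (rise then stabilize), or
quadratically (rise then renormalize)?  The candidate bases over the
horizon T = 14 days, all anchored at f(0) = 0 and bounded by |f| ≤ 1:

| shape      | f(t)            | interpretation                      |
|------------|-----------------|-------------------------------------|
| linear     | t/T             | steady circuit formation            |
| asymptotic | 1 − (1 − t/T)²  | expansion followed by stabilization |
| quadratic  | 4·t(T − t)/T²   | expansion followed by renormalization |

The study describes the shapes only qualitatively; these closed forms
match the verbal descriptions (quadratic rise with zero slope at T for the
asymptote; symmetric rise–return peaking at T/2 for the quadratic) and
keep all three 2-parameter-comparable inside a common fixed-effects
design.  Decreasing time courses are the negatives of these bases; in the
voxelwise arm they are handled by the sign of the fitted interaction
rather than by separate fits.

Fits are ranked by the small-sample Akaike criterion
AICc = −2·logLik + 2k + 2k(k+1)/(n−k−1), with k counting every estimated
parameter including variance components.  For two models with AICc
difference D (worse minus better), the probability that the better model
is correct is e^{D/2}/(1 + e^{D/2}); D = 2 corresponds to ≈73.1%, and a
comparison is called decisive when D > 2.  Ties in AICc break toward the
simpler model.

## Voxelwise longitudinal mixed models

The morphometry substrate is a panel of smoothed, modulated tissue-volume
maps (one 3D volume per subject per session, 0.08 mm isotropic) for a
trained and a control group scanned at experimental days
{0, 2, 6, 8, 10, 14}.  Per voxel and per candidate shape the model

y_ij = β₀ + β₁·TIV_i + β₂·group_i + β₃·f(t_j) + β₄·group_i·f(t_j)
       + u₀ᵢ + u₁ᵢ·f(t_j) + ε_ij

is fit by maximum likelihood, with subject random intercepts and random
slopes on f(t) (unstructured 2×2 covariance) and TIV centered.  ML rather
than REML keeps likelihoods comparable across mean structures for AIC
maps.  A group main effect is included even though only TIV and time are
strictly required, protecting the interaction test against baseline
offsets.  k = 9 (five fixed effects, three covariance parameters, the
residual variance).  Missing sessions simply drop out of the subject's
likelihood contribution (unbalanced panel).

**Fitting.**  The likelihood is profiled: given the scaled random-effect
covariance D (log-Cholesky parameterized, 3 parameters), the GLS fixed
effects and the ML residual variance are closed-form via the Woodbury
identity on the 2×2 random-effect block, so each voxel is a smooth
3-parameter Nelder–Mead problem (xatol 1e−4, fatol 1e−7, warm-started
from the neighboring voxel during map sweeps).  This makes whole-grid
sweeps tractable on one core; the implementation is validated in the test
suite against brute-force maximization of the full marginal likelihood
(agreement to 1e−4 in −2·logLik) and against statsmodels MixedLM.

**Inference.**  β₄ is tested two-sidedly with a Wald statistic referred
to a t distribution with n_subjects − 2 degrees of freedom: the
interaction contrasts mean slopes between two groups of subjects, so
subjects — not observations — carry its information, and with ML variance
estimates the normal reference is measurably anti-conservative on panels
of tens of subjects.  Benjamini–Hochberg step-up FDR is applied across
in-mask voxels per shape (classic BH, no dependence correction);
significant voxels are split by the sign of β₄.  Degenerate voxels
(zero-variance response, or zero-residual fits whose ML likelihood
diverges — these return their exact OLS coefficients) and non-converged
voxels are logged to a QC table and excluded from the maps.

**Preferred-model maps.**  A voxel is labeled with a shape only when that
shape's AIC plus a margin (default 10) is below every competitor's;
otherwise it stays unlabeled.  Cluster sizes convert to volumes as
count × voxel³, reported to two decimals.

**VOI trajectories.**  Per subject and session, the mean over a volume of
interest is normalized by the same-session control-group mean.  Single
trajectories are fit per shape by OLS (y = a + b·f(t)); with the ML
variance the Gaussian log-likelihood gives a per-subject AICc with k = 3.
With exactly 4 observations the AICc correction is undefined (n = k + 1),
so per-subject AICc values need ≥ 5 sessions; fewer than 4 raises an
insufficient-data error outright.  Lower asymptotic AICc means a more
asymptotic-like trajectory; pairing it with behavioral learning rates
gives the rate-versus-plateau correlation.

**Utilities.**  Tissue-probability masks threshold at p ≥ 0.2; Gaussian
smoothing is specified by FWHM (default five voxel sizes) with
σ = FWHM/(2√(2 ln 2)) and reflective boundaries, preserving total tissue
amount.

## Fiber reconstruction and quantification

One probe is an 8-bit confocal z-stack with voxels 0.18 × 0.18 µm
in-plane and 0.48 µm between optical sections.  The pipeline:

1. **Edge-preserving smoothing** — Perona–Malik anisotropic diffusion
   (exponential conduction, κ = 30 on the 8-bit scale) with total
   diffusion time 25 advanced in five nominal steps of 5, each subdivided
   into explicitly stable substeps (dt ≤ 1/6 on the 3D 6-neighbor
   stencil); then a Gaussian with σ = 1 voxel truncated to a 5×5×5
   kernel.  The commercial-tool "time stop 25, step size 5" setting is
   mapped onto this open, reproducible definition with the same total
   diffusion time.
2. **Binarization** — single Otsu threshold over the 256-bin histogram.
3. **Skeletonization** — topology-preserving 3D thinning to a one-voxel
   centerline, converted to a 26-connectivity graph in µm (anisotropic
   spacing applied), cut into simple segments at junctions and endpoints.
   Terminal side-branches shorter than 1 µm (a configurable prune) are
   removed as thinning artifacts.
4. **Nodes and radii** — each segment is re-parameterized by arc length
   with nodes every 0.5 µm.  The node radius is the anisotropic Euclidean
   distance transform of the foreground at the node minus half the
   in-plane voxel pitch: the EDT measures to the nearest background voxel
   *center* while the myelin boundary lies about half a voxel closer (an
   isolated one-voxel line therefore reads half the in-plane pitch).
   Radii at branch points take the distance-map value as-is.
5. **Labeled depth** — antibody penetration limits staining, so the
   per-slice 99th-percentile intensity of the *raw* stack (the 75/255
   cutoff refers to acquisition-scale values) defines the well-labeled
   depth Thref: the contiguous run of supra-threshold sections from the
   better-labeled face (islands beyond the first gap do not count).
   Probes with Thref ≤ 2 µm are excluded.
6. **Metrics** — over the quantification volume
   V = probe_area × (Thref + 0.5 µm), the 0.5 µm correcting for
   structures bordering the probe limits: length density (µm of
   centerline whose piece midpoint lies in the labeled depth, per µm³),
   mean diameter (2 × mean node radius over in-depth nodes), and
   volumetric fraction (Σ π r² Δl / V, capped at 1).  The uncorrected
   volume is reported alongside.

Known behaviors: thinning erodes roughly a micrometre from each fiber
end, biasing length density slightly low for short fibers; where two
tubes blur into one cross-section the skeleton carries a single
centerline, and dense plate-like merges can add spurious mesh branches.
The thinning's ordered border sub-iterations make the skeleton only
approximately equivariant under axis permutation (metrics agree to a few
percent, verified in tests).

## Densitometry

Sections are segmented within an ROI polygon into three intensity classes
(background, autofluorescence, specific myelin signal) by exact two-
threshold multi-Otsu on the 256-bin histogram.  The specific signal is
the top class — the only monotone choice — with pixels strictly above the
upper threshold; its mean intensity is the section's immunoreactivity and
its area fraction is reported alongside, so either convention for
"specific signal" can be checked.  The per-subject value is the
unweighted mean over that subject's sections.

## Behavior

A session is 30 single-pellet trials.  Success is the percent of
completed trials with a valid retrieval (trials with abnormal behavior
never count); accuracy divides valid successes by the total attempts
pooled over successful trials (ratio of sums — robust to single-trial
outliers; the mean-of-ratios alternative is computed alongside);
first-attempt success requires exactly one attempt.  The learning rate is
the OLS slope of success% on ln(day), day index starting at 1.

## Synthetic data

Each generator emits its ground truth and is byte-deterministic given its
config.

* **Longitudinal panels** — a smooth positive baseline field (~0.5 on the
  modulated-probability scale) plus per-subject random intercepts
  (σ = 0.02) and slopes (σ = 0.01) on f(t), Gaussian voxel noise
  (σ = 0.01, a few percent of baseline, consistent with the VOI
  trajectories' spread), and a group effect of a few percent of baseline
  confined to an effect region (default a central 5³ block of a 20³
  grid).  TIVs are drawn from N(450, 25²) mm³.  Optional reversed
  censoring emulates the study's per-session accrual.  Gaussian noise on
  modulated values is an assumption — real VBM noise is spatially
  correlated and non-Gaussian — so passing recovery tests demonstrate
  the statistics, not scanner realism.
* **Fiber phantoms** — smooth fiber paths wander in the section plane
  while their depth undulates gently (amplitude 0.8 µm) around centers
  stratified from the cut surface down through the labeled depth: every
  optical section sees fibers, while two fibers share a depth only at
  isolated crossings, so their tubes rarely merge.  Tubes of radius
  0.45 µm (diameter 0.9 µm, typical of intracortical myelinated axons)
  are rasterized at the acquisition anisotropy; intensity follows a
  plateau-then-logistic depth decay (default 8 µm, emulating antibody
  penetration), a Gaussian PSF (σ = 0.25 µm axial, 0.1 µm lateral,
  realistic for a 1.4 NA objective) and Poisson noise.  The default
  field (20 × 20 µm, 5 fibers) gives a length density of ~0.07 µm/µm³,
  in the range of cortical neuropil.  The phantoms do not emulate
  nonspecific background structures, vignetting, or true myelin
  ultrastructure.
* **Sections** — three-class mixtures (means 20/90/200, the specific
  class ~10% of area) with blob texture from thresholded Gaussian random
  fields.
* **Behavior** — daily success probability
  p(d) = p₀ + (p_max − p₀)(1 − e^{−rate·d}) with defaults p₀ = 0.08,
  p_max = 0.5, rate = 0.35 — reaching ≈49% at day 12, matching typical
  trained performance — 30 Bernoulli trials per day, geometric attempts
  on successes, and a 2% abnormal-trial rate.

## Problem sizes and numerical choices

The packaged recovery checks run at deliberately modest sizes chosen to
exercise every code path: the voxelwise phantom uses a 20³ grid with 20
subjects per group and a 5³ effect region at 5:1 signal-to-noise (~24k
mixed-model fits); FDR calibration averages 50 null replicates on a 4³
grid with 10 subjects per group; fiber recovery uses twenty
24 × 112 × 112 phantoms.  Optimizer tolerances and tie-break rules are
stated above; degenerate inputs (constant stacks, empty masks, empty
skeletons, all-invalid sessions) raise typed errors or return flagged
results rather than propagating NaNs silently.

## Limitations

The package does not perform segmentation, registration, template
construction, or bias correction (inputs are already-segmented modulated
maps), nor deconvolution or colocalization on the microscopy side.  The
trajectory bases are fixed shapes, not free-parameter nonlinear fits; the
per-voxel AIC margin and the ΔAICc > 2 rule are conventions, not
significance tests.  Fiber metrics inherit the biases of thinning-based
reconstruction noted above; on real, densely myelinated tissue the
absolute length density is best interpreted comparatively across
conditions rather than as an unbiased stereological estimate.
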