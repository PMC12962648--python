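# Methods

This note documents the models, the synthetic data they are tested on,
the numerical choices, and what the tests do and do not establish.

## Diffusion signal model and tensor fitting

Each voxel's diffusion-weighted signal is modeled as
`S(b,g) = S0 exp(−b gᵀDg)` with a symmetric tensor `D` (mm²/s). Fitting
is log-linear least squares in two passes: ordinary least squares on
`ln S` initializes, then a weighted pass uses the squared predicted
signal as weights — the standard variance model for log-transformed
magnitude data, and a good compromise between robustness and the full
nonlinear fit. The log is floored at `1e−6·S0` per voxel; voxels with
nonpositive b0 signal are flagged (`fit_ok = False`) rather than
raising, so single bad voxels never abort a subject.

FA and MD are computed from eigenvalues clamped at zero. The axis
diffusivities `Dxx, Dyy, Dzz` are read from the **raw tensor diagonal**,
not from eigenvalues: the ALPS index is defined on image-axis
diffusivities, and clamping would bias ratios near isotropy.

A caution that the test suite encodes: a gradient table is only as good
as its geometry. The golden-spiral direction generator used for
synthetic schemes is well conditioned for n ≥ 7 but degenerate at
exactly n = 6; the minimal-encoding oracle test therefore uses the
classic `(±1, ±1, 0)/√2` six-direction set.

## ALPS index

With projection fibers along z and association fibers along y, both
adjacent to the lateral-ventricle body, the perivascular spaces run
along x and

`ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)`

over 4-mm spherical ROIs (voxel centers within 2 mm of the ROI center).
Each hemisphere's index uses only its own ROI pair. ROI categories come
from label overlap with the tumor segmentation — one shared voxel
suffices — with priority necrosis > enhancing > FLAIR-hyperintense >
none (iNAWM); the hemisphere opposite the tumor is cNAWM. Necrosis
overlap excludes the hemisphere from group comparisons; any
tumor-overlap category removes that hemisphere's value from survival
columns. Bilateral tumors are an error at categorization and an
exclusion at the cohort filter. A nonpositive ALPS denominator flags
the measurement invalid instead of raising; downstream stages drop it.

Reference-subject selection (for ROI placement on real data) picks the
FA map with the smallest sum of squared differences to a template, ties
broken by lowest subject id. Registration chains and manual ROI
correction are out of scope; ROIs are supplied in subject space.

## Free-water fraction

Two compartments: tissue tensor `D_t` and isotropic free water with
`d_iso = 3.0e−3 mm²/s` (body-temperature free water — conventional, not
measured here):

`S = S0 [ (1−f) exp(−b gᵀD_t g) + f exp(−b d_iso) ]`.

From a single shell this model is ill-posed: along a one-parameter
manifold, raising `f` while softening `D_t` leaves the signal almost
unchanged. The implementation therefore leans on three regularizers:

1. **Initialization as prior.** `f_init` comes from the
   direction-averaged shell attenuation against a tissue-diffusivity
   prior `λ_t = 0.6e−3 mm²/s`:
   `f_init = clamp((e^{−bλ_t} − Ā)/(e^{−bλ_t} − e^{−b d_iso}))`. On
   mixtures of prior-like tissue and free water this is nearly unbiased.
2. **Spatial smoothness.** A discrete-Laplacian (Tikhonov) penalty
   `reg_weight·Σ(f_v − f_w)²` over 6-neighbor pairs (default
   `reg_weight = 0.5`, chosen so the penalty and per-voxel data term are
   comparable at SNR ~30; the large-`reg_weight` limit provably flattens
   `f`, which a test asserts). This is a deliberate simplification of
   the gradient-descent-on-manifold scheme in the FW literature — same
   qualitative role, far easier to verify.
3. **Proximal anchor.** The f-subproblem additionally carries
   `init_weight·Σ(f − f_init)²` (default 1.0). Without it, alternation
   under noise ratchets `f` along the flat manifold by a small
   curvature bias each iteration (~+0.005/iteration at SNR 30) with no
   stationary point in useful time; the anchor pins the flat direction
   to the best data-driven point estimate. This is the package's own
   design choice and the reason the fit reports *regularized-mean*
   recovery.

Minimization alternates (a) a tissue-tensor fit on the FW-corrected
attenuation — log-space WLS followed by two Gauss-Newton steps in
linear space, so the substep actually minimizes the stated
sum-of-squares objective; eigenvalues are projected to `[0, d_iso]` —
and (b) projected Jacobi sweeps on the quadratic f-subproblem, with `f`
clipped to `[0.01, 0.99]` after every sweep so both compartments stay
identifiable. Convergence: max |Δf| < 1e−3 or 30 outer iterations;
a sustained >1%-per-iteration loss increase marks divergence
(sub-percent plateau jitter from the approximate substeps is normal and
is not flagged).

What the tests show: mean `f` over a region tracks the planted fraction
(bias ≈ +0.01 on fiber-like tissue at SNR 30, perfect rank ordering
across planted levels), and the pure-tissue / pure-water limits are
exact. What they do not show: voxel-exact recovery, or accuracy when
the true tissue diffusivity sits far from the `λ_t` prior — with
isotropic tissue at MD 0.8e−3 the estimate inflates by ~0.15. This is
intrinsic to single-shell FW estimation, not a defect this package can
remove; multi-shell estimation is explicitly out of scope. Within a
cohort the bias is shared, so rankings, correlations, and
threshold-based stratification remain meaningful.

## ComBat harmonization

Per feature `v`, subject `j` of site `i`:
`y_ijv = α_v + X_j β_v + γ_iv + δ_iv ε_ijv`, covariates `X = (age, sex)`.
Fitting standardizes by the covariate-adjusted grand mean and pooled
variance, estimates per-site location/scale on that scale, and — with
≥2 features — shrinks them by parametric empirical Bayes (normal prior
on γ, inverse-gamma on δ, moment-matched, fixed-point iteration). With
one feature or `parametric=False` the raw estimates are used and
`eb_used` is False. ALPS, FW and the ROI FA/MD covariates are
harmonized jointly so the EB prior sees several features; sites default
to dataset-level batches. A reference-batch mode and the non-parametric
variant are omitted.

All variances use the maximum-likelihood (1/n) convention. This makes
harmonization **exactly idempotent** in the covariate-free,
no-shrinkage case (re-fitting on harmonized data is a numerical no-op
to <1e−8), which the tests pin down. With covariates or EB shrinkage,
re-application perturbs values at the `O(n^{−1/2})` estimation-noise
level — expected, also tested. Against Bioconductor `sva::ComBat`
(which uses n−1 denominators), harmonized values agree to ~1% of a
feature SD at n≈70/site; a test runs that comparison through Rscript.

Properties worth knowing: removing genuine site variance *increases*
covariate-biomarker correlations (that is the point of harmonization),
so "correlation preserved" only holds when no site effect was present;
and pooled moments are preserved only under null site effects.

## Survival toolkit

Kaplan–Meier with Greenwood variance; the median is the first time the
curve reaches 0.5, with the plateau-midpoint (linear) convention when
it hits 0.5 exactly; months are days/30.44. The two-group log-rank test
is the classic O−E statistic with hypergeometric variance (1 df),
vectorized so a cutpoint scan costs milliseconds; its HR and CI come
from a univariate Cox fit on the group indicator.

Cox proportional hazards is fit by Newton–Raphson with step-halving on
the partial likelihood; Efron tie handling by default, Breslow
available (they agree exactly without ties — tested). Continuous
covariates (more than two distinct values) are z-scored by default so
HRs read per SD; the biomarker HRs in this problem (~0.6–1.5) are only
plausible per-SD given ALPS/FW natural ranges. Monotone likelihood
(perfect separation) is detected as a per-SD |β| exceeding 15 and
raised as an error; non-convergence after 100 iterations likewise.
Cross-checks against lifelines agree to ~1e−6 on coefficients.

ANOVA across ROI categories with Tukey HSD uses scipy
(`f_oneway`, `tukey_hsd`); at two groups Tukey reduces to the pooled
t-test (tested to 1e−6). Median dichotomization sends ties to "low"
(`value > median` is "high") — the same strict-`>` convention used by
every threshold operation in the package, so scans and fixed-threshold
application can never disagree on a boundary subject.

## Cutpoint machinery

Thresholds run from `ceil(min/step)·step` to `floor(max/step)·step`
(steps 0.01 for ALPS, 0.001 for FW). At each, the cohort is split at
`value > threshold`, log-rank p and HR recorded; thresholds whose
smaller group falls below `min_group_frac` (default 0.1 — a guard
against degenerate 1-vs-(n−1) splits; set 0 to scan literally
everything) are kept in the table but marked inadmissible. The optimum
is the lowest p, ties by largest |log HR|, then lowest threshold —
deterministic, and tested against a brute-force re-evaluation of the
rule. No multiplicity correction is applied across the scan; the
resulting type-I inflation of min-p selection is a documented property
of the procedure. Validation applies a frozen threshold to an
independent cohort (warning if outside the observed range; empty group
is an error). Joint stratification: favorable = high ALPS & low FW
(FW's favorable side is ≤ threshold), adverse = low ALPS & high FW,
discordant pools the mixed patterns; three pairwise log-rank tests.

## Synthetic data: what it emulates, what it does not

**Phantom.** Axis-aligned boxes on a 1-mm grid: per-hemisphere
projection (principal axis z) and association (axis y) fiber slabs with
eigenvalues (1.4, 0.3, 0.3)e−3 mm²/s, a central CSF block, isotropic
background tissue at 0.65e−3 mm²/s (a tissue-compartment value chosen
so that, with typical planted FW fractions, apparent NAWM MD lands in
the in-vivo 0.75–0.85e−3 range). A perivascular elevation raises Dxx in
both fiber systems, fixing ground-truth ALPS = Dxx/λ⊥ analytically; per
hemisphere specs allow different planted ALPS ipsi/contralaterally.
Tumors are nested cubes (FLAIR-hyperintense ⊃ enhancing ⊃ necrotic
core) positioned so that exactly the requested label reaches the
ipsilateral projection ROI, never the contralateral ROIs; tumor tissue
is isotropic with elevated MD and FW. Coordinates: 0-based indices,
world = index × voxel size, no rotations.

**DWI.** The bi-tensor forward signal with Rician magnitude noise,
`snr = S0/σ` defined on b0 (Gaussian available for debugging);
identical seeds give bit-identical volumes. Scanner artifacts (eddy
currents, motion, Gibbs ringing) are deliberately absent — their
correction belongs to preprocessing pipelines that are out of scope —
so passing tests say nothing about robustness to them.

**Cohorts.** Site-stratified tables with ALPS ~ N(1.40, 0.15), FW ~
N(0.21, 0.06), age ~ N(63, 11), ~62% male, enhancing volume ~ lognormal
with mean ≈ 15 ml — the scale of published GBM cohorts. Survival times
follow a Weibull proportional-hazards model (shape 1.2, scale 612 days,
putting the null median near 15 months) with per-SD log-HRs −0.3
(ALPS) and +0.3 (FW) by default; censoring is independent uniform with
its maximum bisected to hit the target censoring fraction (default 0.2
— the real cohorts' fraction is unpublished, so it is an explicit free
parameter). Site effects are additive shifts plus multiplicative
scalings about the shifted site mean. Pre-distortion values are kept in
`*_true` columns so recovery is always checkable. Eligibility columns
(bilateral ~3%, half-normal midline shift with ~5% exceeding the 5-mm
cut, ROI categories at the published cohort proportions) exercise the
filters.

**Imaging cohorts.** `simulate_imaging_cohort` writes per-subject
NIfTI/bval/bvec realizing a cohort table: planted per-hemisphere ALPS,
FW in the contralateral background tissue, tumor overlap matching the
drawn ROI category, and per-site acquisition schemes (b=1000 with 31
directions vs b=2000 with 56). Grids default to 24³ voxels — big enough
for 4-mm ROIs, two hemispheres and a tumor, small enough that a
40-subject cohort processes in about a minute; measured ALPS correlates
with planted at r ≈ 0.998 at SNR 40.

## Eligibility filtering and orchestration

Filters: bilateral tumor, midline shift **strictly** greater than 5 mm
(5.0 mm is retained), and tumor-overlap hemispheres leaving the iNAWM
survival column for their category column (`alps_flair`, `alps_enh`,
`alps_necrosis`). Per-subject processing failures are quarantined and
logged in the run manifest, mirroring how poor-quality scans are
excluded rather than crashing a study. Discovery and validation cohorts
are explicit config fields. Harmonization is fit jointly across sites
on complete cases and applied to all rows; per-cohort analyses follow.
All CSVs are written with a fixed float format, so identical configs
and seeds give byte-identical outputs.

## Problem sizes in the verification suite

Tests and the acceptance script use 16³–32³ phantoms, cohorts of
200–600 subjects, 200-replicate power/recovery loops and a
1000-replicate null calibration — sizes at which every stage's expected
behavior is statistically resolvable on one core in a few minutes.

## Known limitations

- Single-shell FW estimation is prior-anchored; absolute FW levels are
  calibrated only near the tissue prior (see above).
- The ALPS ROI placement on real data requires externally supplied ROI
  masks; no atlas registration is included.
- No proportional-hazards diagnostics, time-varying covariates, or
  competing risks.
- The cutpoint scan's min-p selection is reported uncorrected, by
  design; treat discovered thresholds as hypotheses until externally
  validated.
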