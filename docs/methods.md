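# Methods

`fixelpipe` re-implements, as a tested library and CLI, the statistical
core of a fixel-based longitudinal white-matter analysis of a multiple
sclerosis (MS) cohort: fibre-specific metrics, connectivity-enhanced
fixel-wise inference, tract-of-interest group models, normative cognitive
phenotyping and nested cross-validated clinical prediction. Image
reconstruction (diffusion preprocessing, spherical deconvolution, FOD
template registration, tractography, lesion segmentation) is out of scope:
a synthetic fixel template and cohort generator with known ground truth
stand in for those upstream stages, so every downstream operation can be
verified without any imaging data.

## Fibre-specific metrics

A *fixel* is one fibre population within a voxel (at most three per voxel
here). Per fixel and subject the pipeline handles:

- **FD (fibre density)** — microstructural input, proportional to the
  intra-axonal volume of the fixel's population. Unitless, >= 0.
- **FC (fibre cross-section)** — macrostructural change of the bundle's
  cross-sectional area induced by the subject-to-template warp. For local
  Jacobian `J` and unit fibre direction `v` the module's normative
  definition is the closed form

      FC = det(J) / ||J v||

  i.e. volume scaling divided by length scaling along the fibre, which for
  affine maps is exactly the scaling of the area of the cross-section
  perpendicular to the deformed axis. The definition is antipodally
  symmetric (`v` and `-v` equivalent) and is verified in the tests against
  an independent geometric oracle: a dense ring of disc points
  perpendicular to `v` is mapped through `J`, projected onto the plane
  perpendicular to `J v`, and its polygon area integrated. (The *projection*
  matters: the unprojected image of the disc is an oblique section whose
  area exceeds the physical cross-section for shearing warps.)
- **logFC** — natural log of FC; all statistics on FC use the log scale,
  percentage-difference displays use raw FC.
- **FDC = FD x FC** — combined micro/macro measure (uses raw FC).

Tract aggregation averages each metric over the fixels of one of 20
JHU-style tract labels (bilateral ATR, CST, cingulate and hippocampal
cingulum, IFOF, ILF, SLF, temporal SLF, uncinate; forceps major/minor).
Lesion masking is voxel-level: a lesioned voxel removes all its fixels
before averaging, and a tract losing every fixel is omitted with an
explicit warning rather than silently. Whether the emulated analysis
averaged FC or logFC within tracts before statistics is not determinable;
both are supported and logFC is the default.

## Synthetic cohort generator

The generator defines the study conditions; its defaults emulate the
printed cohort structure of the emulated study:

- Groups: 95 HC, 239 RRMS, 52 SPMS, 36 PPMS (327 patients) at baseline;
  follow-up retention 233/327 patients and 61/95 controls; visit interval
  4.81 ± 0.85 y (patients), 5.43 ± 1.07 y (controls). Ages 45.7 ± 10.35
  (HC) and group means chosen so the patient mean is ~48.3; sex and
  education fractions follow the printed table; treatments are drawn with
  the printed frequencies (72/16/22/6/211).
- Baseline damage: per-tract HC mean FD ~ 0.5 (the source reports no
  per-tract HC means, so 0.5 ± 0.05 across tracts is an explicitly
  arbitrary order-of-magnitude choice) multiplied by `(1 - deficit)` per
  phenotype and tract. Base FD deficits 6% (RRMS), 6.5% (PPMS), 12% (SPMS)
  and FC deficits 3%/3.5%/7%, modulated by per-tract weights that put FD
  damage mostly in the cingulum and SLF and FC damage in CST, cingulum and
  SLF — reproducing the reported spatial pattern and the ordering
  SPMS worst, PPMS ~ RRMS.
- Longitudinal change: annual fractional slopes (FD: 0 / -0.15% / -0.4% /
  -0.5% per year for HC/RRMS/PPMS/SPMS; FC smaller), applied over each
  subject's drawn interval.
- Warps: per-fixel Jacobians are constructed as `J = s I + (1 - s) v v^T`
  with `s = sqrt(FC)`, so the intended FC is realized *exactly* in closed
  form — enabling machine-precision recovery tests.
- Noise: a subject-level multiplicative factor (between-subject SD 5% for
  FD, 4% for FC) shared across tracts, plus per-fixel measurement noise
  (additive SD 0.02 for FD, 2% multiplicative for FC). With both set to 0
  the configured deficits are recovered to 1e-6.
- Lesions: per-patient Poisson voxel counts (means 25/45/35 for
  RRMS/SPMS/PPMS) placed by tract-weighted multinomial sampling, preferring
  the tracts that carry FD damage. Inside lesioned voxels the subject's FD
  is pulled 60% of the way toward the HC tract mean. This deliberately
  makes lesional tissue carry an *attenuated* group contrast, so masking
  lesions out slightly sharpens tract effect sizes — reproducing the
  reported behaviour that lesion-masked reruns look similar with mildly
  larger effects, i.e. normal-appearing white matter dominates the
  contrast. It is an emulation target, not a claim about lesion biology.
- Cognition: seven domain raw scores = covariate part (age, sex,
  education) + loading x standardized subject mean FDC + N(0, 0.8) noise.
  Loadings average 0.40 across domains. These two values were calibrated
  once against the printed cohort descriptives (patient mean average-Z
  -0.80, plausible CP/MCI/CI split) and then frozen. With domain noise and
  covariate effects at zero, domain scores are an exact affine function of
  mean FDC.
- EDSS (patients only): group intercept + symptom-duration and
  damage-coupled terms + noise, clipped to 0–8 and rounded to 0.5 steps;
  follow-up adds a per-phenotype annual progression. Normalized volumes
  (NBV/NWMV/NCGMV/NDGMV) are drawn per group around the printed means and
  coupled to the damage score so cognitive subgroups reproduce the printed
  volume gradient.

All draws flow from one integer seed through named substreams (template,
covariates, fd, fc, noise, dropout, lesions, cognition, clinical), so
identical (config, seed) pairs give byte-identical cohorts and stages can
be regenerated independently.

The synthetic template is geometric, not anatomical: 20 axis-aligned
bundles on a 20³ grid with engineered 2- and 3-fixel crossing voxels and
within-bundle streamlines. Passing tests therefore demonstrate the
*statistical machinery* (calibration, recovery, ordering, error control) —
not registration quality, FOD fidelity or anatomical validity on real
data.

## Normative cognitive phenotyping

Per-domain regression norms are fitted on healthy controls only (linear
model in age, sex, binary high/low education; residual SD with an (n - p)
denominator), the standard approach for BRB-N-style batteries; the source
describes the correction without formulas, so this is documented as the
module's normative definition. Z-scores are (observed - predicted) /
residual SD, computed per timepoint against that timepoint's HC fit by
default (so learning effects cancel; a flag switches to baseline-HC norms).
Classification uses the two-of-seven rule with inclusive thresholds:
CI if >= 2 domains have Z <= -2, else MCI if >= 2 have Z <= -1.5, else CP.
Missing domains refuse classification by default; a lenient mode classifies
only when the observed domains already satisfy a criterion (a missing
domain can never move a subject toward CP).

## Fixel-wise inference (CFE)

Per-fixel OLS contrasts (t statistics) are enhanced with
connectivity-based fixel enhancement:

    e_i = sum_{h = dh, 2dh, ... <= t_i} dh * h^H * (sum_j c_ij^C 1[t_j >= h])^E

with defaults dh = 0.1, C = 0.5, E = 2, H = 3 (the published defaults of
the CFE method; the emulated study names CFE without parameters).
Connectivity is streamline-derived: `c_ij` = fraction of streamlines
through fixel i that also traverse j (row-normalized, `c_ii = 1`). FWE
correction uses the permutation distribution of the maximum enhanced
statistic with Freedman–Lane residual permutation, respecting nuisance
covariates (age, head size); `p = (1 + b)/(m + 1)` includes the identity
permutation so p > 0. If the requested permutation count reaches the
number of distinct subject permutations the test enumerates exhaustively.
Contrasts default to one-sided (patients < controls); connectivity-weighted
pre-smoothing exists but is off by default since no smoothing parameters
are given for the emulated analysis. Permutations are evaluated in batches
with the enhancement vectorized across permutations, which is what makes
hundreds of calibration replicates affordable on one CPU.

Calibration and sensitivity (verified by the acceptance suite, with
problem sizes chosen to keep the whole run desk-scale): under a pure null
the fraction of replicates with any FWE-significant fixel stays at or
below 7% (600 replicates x 200 fixels x 500 permutations; measured ~5–6%);
an injected one-tract 0.8 SD FD deficit at n = 30 + 30 with 1000
permutations is detected in >= 90% of the tract's fixels.

## Tract-of-interest statistics

Cross-sectional group contrasts use ANCOVA: group indicators + covariates
(age, sex, head scale; education added for cognitive-profile contrasts;
treatment optionally as binary or 5-level dummies), with the group F from
the nested-RSS partial F test and adjusted means evaluated at covariate
means. Post-hoc pairwise contrasts are Bonferroni-corrected; the family
for the across-tract correction is, per metric, the number of tracts in
the analysis, and the family size is recorded in every output row (the
source does not state its family definition). Longitudinal models are
random-intercept LMMs (REML, statsmodels MixedLM) with group, time,
group x time and baseline age + sex; per-phenotype annual slopes combine
the time and interaction terms with large-sample normal inference —
the simplest defensible contract, rather than degrees-of-freedom
corrections. Confounded designs (a group nested in a covariate level)
raise a rank error naming the offending columns; all-cross-sectional input
raises an error advising a cross-sectional model.

## Clinical association and prediction

- **Hierarchical regression** (baseline associations): block 1
  (demographics + symptom duration) forced, block 2 (volumes + lesion
  load) added, block 3 (tract fixel metrics) entered only after a
  univariate Pearson screen at p < 0.05 and then backward-eliminated with
  p-to-remove 0.10 (the common SPSS convention; the source does not state
  it). ΔR² per block quantifies the added value of fixel metrics.
- **Stepwise AIC**: AIC = n ln(RSS/n) + 2k; bidirectional greedy from the
  full candidate set, applying the single add/drop with the largest AIC
  decrease; deterministic tie-break (lexicographic, then prefer drop). The
  final model is single-step locally optimal, and on random instances with
  <= 8 candidates matches exhaustive best-subset AIC in >= 90% of cases.
  Note that AIC retains a pure-noise candidate with probability
  P(chi²₁ > 2) ~ 0.16, so "exact true-model recovery" plateaus near 84% —
  an inherent property of AIC, reflected in the test expectations.
- **Nested CV**: seeded 80/20 train/test split; 10 outer folds on the
  training set; within each outer training set an inner 5-fold loop
  retains a feature only if univariately significant (p < 0.05 by
  default; configurable) in *all* five inner folds; features retained by *all* outer loops form the
  consistent set (strict default; an outer-majority variant exists). A
  stepwise-AIC model over the consistent set is refit on the full training
  set and applied, frozen, to the untouched test set (RMSE, Pearson r). A
  SHA-256 hash of the test rows taken before training is re-verified
  before evaluation; an empty consistent set returns a flagged null model.
  Inner univariate screens are unadjusted by default (option to partial
  out age/sex/education).

## Numerical and design notes

- Core OLS engines (fixel GLM, ANCOVA F, regression reports) are thin
  numpy least-squares implementations so they can be vectorized across
  hundreds of thousands of fixel-permutation fits; they are cross-checked
  against statsmodels OLS in the tests. MixedLM fits fall through several
  optimizers because a boundary random-intercept variance can make one
  optimizer's Hessian singular.
- Zero residual variance in a fixel GLM yields a +/-inf t sentinel with a
  warning (enhancement caps its threshold ladder); perfect fits in the
  regression modules raise instead of returning undefined AIC.
- All coordinates are 0-based; directions antipodally equivalent; TSV
  outputs use '.' decimals and a fixed float format so deterministic
  stages reproduce byte-for-byte under a fixed seed.
- Monte-Carlo test sizes (replicate counts, permutation counts) are scaled
  to desk hardware and chosen so the binomial noise of each estimated rate
  is small relative to the asserted band; the CFE null calibration uses
  600 replicates for this reason.

## Known limitations

- The synthetic template has no anatomy and no inter-bundle streamlines;
  CFE behaviour across crossing regions of real tractograms is exercised
  only in miniature.
- FD is an input; nothing here validates FD estimation from diffusion
  signal, and the generator's lesion contamination model is phenomenological.
- LMM inference uses the normal approximation; small-sample tract analyses
  would need degrees-of-freedom corrections.
- Cohort-specific published regression results (which predictors survive,
  exact R² values) depend on undeposited patient data and are not
  reproduction targets; the pipeline reproduces procedures, calibration
  and ordering patterns, not those coefficients.
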