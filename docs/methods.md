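# Methods

This note records the models implemented in `interofat`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## Behavioural task scoring

**Heartbeat tracking (HTT).** Per-window accuracy is
`1 − |n_real − n_reported| / ((n_real + n_reported)/2)`, the absolute
counting error normalised by the mean of the two counts, averaged over
windows. The absolute value makes over- and under-reporting symmetric;
without it, over-reporting would score above 1, which contradicts an
accuracy reading. Scores are deliberately **not clamped** to [0, 1]
(reporting zero beats gives −1): downstream use dichotomizes at the
cohort median, which is invariant to any monotone rescaling, so clamping
would change nothing except hide the tail. Tracking insight is the
within-subject Pearson r between window confidence (0–10 VAS) and window
accuracy. With the standard six windows this correlation is a low-trial
estimate; scoring flags it as such (`htt_insight_low_trial`) rather than
suppressing it. Windows with two zero counts are unscorable and skipped
with a logged warning; fewer than three scorable windows is an error;
zero variance in either vector yields a missing (NaN) insight value.

**Heartbeat discrimination (HDT).** Accuracy is the fraction of correct
synchrony judgements (26 trials by default). Insight is the type-2 ROC
area relating confidence to correctness, computed by midranks
(Mann–Whitney): `P(conf_correct > conf_incorrect) + ½ P(tie)`. Half
credit for ties is the only convention under which an all-tied
confidence vector gives exactly 0.5; the rank formula equals explicit
pair enumeration, which the tests verify exhaustively on small inputs.
All-correct or all-incorrect subjects have no defined type-2 ROC and
get NaN with a logged reason.

## Metacognitive signal detection

**Staircase.** One-up two-down on the stimulus level (dot-count
difference; larger = easier): one error eases the task one step
immediately, two consecutive correct responses harden it one step. The
rule's asymptotic accuracy is 2^(−1/2) ≈ 0.707. Defaults: start 40,
step 2, floor 1, ceiling 99 — configuration values covering a 1–100 dot
range. The difficulty threshold is the mean presented level, with an
optional burn-in (default 0).

**Type-1 sensitivity.** `d′ = z(HR) − z(FAR)`, `c = −½(z(HR) + z(FAR))`,
with the log-linear correction (add 0.5 to every response cell) applied
only when some cell is zero, keeping the quantiles finite without biasing
well-populated tables.

**meta-d′.** Equal-variance SDT observer: evidence `x ~ N(±meta-d′/2, 1)`,
type-1 criterion held at the observed relative criterion `c′ = c/d′`
(so the meta-level observer answers A/B at the same relative bias as the
first-order one), and `2(K−1)` monotone type-2 criteria splitting each
response side into K rating bins. The fit maximises the multinomial
log-likelihood of the **response-conditional** rating counts
(`P(rating | stimulus, response)`); a pooled (correct/incorrect
collapsed) variant is available behind a flag since the convention is not
universal. Numerics: every rating cell is padded by `1/(2K)` before
likelihood evaluation so sparse tables cannot produce −∞; criteria are
re-parameterised as cumulative `exp` offsets from the type-1 criterion,
which enforces monotone ordering without constrained optimisation;
L-BFGS-B runs from four starts bracketing meta-d′ ∈ [0.1, 1.5·d′].
Non-convergence is returned as a flag with diagnostics, never a silent
number. Metacognitive efficiency is `meta-d′ − d′`: ≈0 for an observer
whose confidence has full access to the first-order evidence, → −d′ as
confidence becomes uninformative. Tests verify the fitted likelihood
against an independent coarse-to-fine grid search (which exploits the
fact that, given meta-d′, the likelihood separates across response
sides) to 10⁻³, and parameter recovery from the generative observer.

## Cohort statistics

Group dichotomization uses the sample median of non-missing values with
midpoint interpolation for even n — the convention that produces
cut-points like 0.195 from instrument data — and labels `1` iff
`value ≥ cutoff`. Missing values propagate. Logistic models are fitted by
IRLS (statsmodels GLM, binomial family); p-values are two-tailed Wald z
to match the coefficient-(SE) presentation, and 95% CIs are
`exp(β ± 1.96·SE)`. Quasi-complete separation is detected by runaway
coefficients (|β| > 15) or non-convergence and flagged, never silently
reported. Univariate screening retains predictors at unadjusted
p ≤ 0.25 and always returns the full per-predictor table. Adjusted
models add age, sex, disease duration, EDSS, anxiety and depression by
default and attach an events-per-predictor caution below 10, because at
cohort sizes near 70 with 7 terms such models are preliminary. Missing
scores drop a subject from that model only (complete case per model).

The logit-linearity check fits a cubic B-spline expansion (4 df, knots at
quantiles) against the linear term and applies an approximate
likelihood-ratio test at α = 0.05; "nonlinear" advises dichotomization at
the median. A smooth-curve visual inspection is not reproducible as a
contract, so an explicit, configurable test stands in its place.

Two-group comparisons are gated: χ² for categorical variables;
otherwise Shapiro–Wilk per group at α = 0.05 (non-normal → Mann–Whitney
U), then the F test of variance equality (equal → Student's t, unequal →
Welch). Groups smaller than 3 fall back to Mann–Whitney with a logged
reason. All tests are two-tailed.

Sample-size arithmetic: dropout adjustment is `ceil(n / (1 − rate))`
(30 per group at 15% → 36). The detectable-difference utility
(`two_sample_t_sample_size`) uses the normal approximation
`n = 2((z_{1−α/2} + z_{power})·σ/Δ)²` and requires α and power as
explicit arguments rather than assuming a conventional power level.

## Voxelwise inference

Per-voxel OLS: `t = c′β̂ / sqrt(σ̂² c′(X′X)⁻¹c)` with df = n − rank(X).
Zero-residual voxels (perfect fit) are capped at ±10⁶ and logged.

TFCE is the discrete sum `Σ_h e(v,h)^E h^H dh` over thresholds
`h = dh, 2dh, …`, where `e(v,h)` is the size of the connected component
containing v at threshold h. Defaults E = 1, H = 2 with 26-connectivity —
the parameterisation suited to thin, sheet-like skeleton data — and
`dh = max(stat)/100`; all are configurable. The production implementation
is an incremental union–find sweep over descending thresholds (numba
compiled) that computes exactly the same discrete sum as per-threshold
component labelling; the test suite holds the two equal to 10⁻⁹
relative tolerance on random maps. Only the positive tail is enhanced;
negative contrasts negate the map, and a two-tailed mode enhances both
tails and takes the voxelwise maximum.

Permutation inference uses Freedman–Lane: the nuisance-only model
(contrast-zero columns) is fitted, its residuals are row-permuted, the
nuisance fit is added back and the full model refitted. The image-wide
maximum TFCE statistic per permutation forms the FWE null and
`p(v) = (1 + #{max* ≥ TFCE(v)}) / (n_perm + 1)`, so p can never
undercut the resolution floor `1/(n_perm+1)`. When n! ≤ n_perm all
permutations are enumerated (with a warning) and the +1 correction is
dropped. Simple whole-row label permutation is available as an option.

The interaction design has columns {1, mean-centred MFIS-Cog, binary
insight level from the median split, their product, mean-centred
covariates}; the interaction contrast targets the product column. A
constant split is a rank-deficiency error. Cluster means are each
subject's mean map value over the significant voxels, exported with
group labels for interaction plots. Skeleton maps are treated as generic
masked 3D volumes — all mask voxels enter the analysis (no lesion/NAWM
distinction, no tract atlas labelling); voxel indices are 0-based in
array order.

## Synthetic generator

The generator is the test-bed for everything above. What it emulates:

- **HTT**: true count = round(bpm × duration/60) over six windows uniform
  on [25, 50] s; reported count = binomial thinning at `p_detect` plus
  Poisson spurious counts; confidence = clip(insight_gain × accuracy × 10
  + Gaussian noise, 0, 10). The linear-in-accuracy coupling is the
  simplest monotone choice whose gain maps one-to-one onto the expected
  confidence–accuracy correlation. Heart rate is fixed per subject: the
  accuracy formula depends only on counts, not beat timing.
- **HDT**: balanced randomized tone types, Bernoulli correctness at
  `hdt_p_correct` (cohort default centred on 55%, SD 21%, the assumed
  discrimination operating point of the design), and a two-component
  location-shift confidence model whose separation is `insight_gain` —
  a construction with a monotone relation between gain and type-2 AUC.
- **2AFC tasks**: evidence `x ~ N(±d′/2, 1)`; response = sign(x − c);
  metacognitive evidence adds `N(0, meta_noise_sd)`; ratings bin
  |x_m − c| at equal-population (sample-quantile) edges, which keeps all
  rating cells populated and the meta-d′ fit stable at small n.
- **Cohort**: covariate marginals loosely matching a relapsing-remitting
  MS cohort in its forties (age ~N(43, 9), 62% female, EDSS ~2 in half
  steps, HADS-A ~4.6); latent high-insight indicator (p = 0.5); log-odds
  of high fatigue = intercept + β_insight·high + Σβ_z·z(covariate), with
  β_insight defaulting to log 0.29 (the planted protective effect) and
  the intercept 0.8 chosen to put the marginal high-fatigue fraction
  near 0.54 so the MFIS-Cog median lands at the 16-point cutoff.
  MFIS-Cog is then drawn consistently with the indicator on either side
  of 16. Per-subject random streams are spawned from the master seed, so
  enlarging a cohort never changes earlier subjects' data.
- **Skeleton maps**: a sheet-like mask from a thresholded smoothed
  Gaussian field (default 15% of a 16×16×8 grid); planted effects
  `γ_fatigue·z(MFIS-Cog) + γ_insight·insight + γ_interaction·z·insight`
  inside a compact central region (~25% of the skeleton); smoothed
  Gaussian noise everywhere on the skeleton, rescaled after smoothing so
  `noise_sd` is the marginal voxel SD. FA-like baseline 0.45, noise SD
  0.02–0.05, effects a few hundredths — the scale of real skeleton FA
  differences.

What it does **not** emulate: ECG/PPG waveforms or cardiac-cycle timing
(trial correctness is modelled directly); stimulus rendering; response
times; anatomical tract geometry, lesion masks or registration error;
non-Gaussian map noise. Passing tests therefore demonstrate that the
analysis chain is correct and calibrated under its own assumptions — not
that those assumptions hold in any particular scanner or cohort.

## Problem sizes and determinism

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to the tolerance being asserted: 10 000–20 000 trials for
trial-level moments and meta-d′ recovery, n = 2000 for odds-ratio
recovery (planted OR 0.29 recovered within 25%), 500 replicates × 200
permutations on a 16×16×8 skeleton for the null FWE calibration
(acceptance band 0.03–0.07 at α = 0.05), and n = 32 subjects with a
strong planted interaction (γ = −0.12 against noise SD 0.02) for
recovery of ≥90% of effect voxels with ≤5% false positives. The
acceptance script uses 400 calibration replicates. Every random quantity
flows from an explicit integer seed through `numpy.random.SeedSequence`;
pipelines are byte-reproducible given their config.

## Known limitations

- The HTT insight correlation from six windows is statistically fragile;
  the package flags it but cannot repair it.
- meta-d′ assumes the equal-variance SDT observer; unequal-variance or
  hierarchical variants are out of scope.
- Wald intervals (not profile or likelihood-ratio) are used throughout
  the logistic ledger; at small n with separation-prone tables they are
  flagged rather than replaced.
- TFCE p-values are only as fine as `1/(n_perm+1)`; the demo config's 200
  permutations bound p from below at ~0.005.
- No imputation: subjects missing a score drop out of that model only.
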