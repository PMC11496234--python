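# Methods

This note documents the statistical machinery, the generative model behind
the synthetic cohort, the numerical choices, and the limits of what the
test suite demonstrates.

## The analysis pipeline

The pipeline reproduces a transdiagnostic subtyping workflow for two-visit
case-control cohorts: derive analysis variables, model the longitudinal
course per outcome, cluster participants on baseline inflammation and
cognition, test that the clusters are real and stable, and characterize
them.

### Preprocessing

* CRP is log10-transformed (CRP is approximately log-normal; the transform
  also linearizes the BMI association). Non-positive values are rejected;
  an optional detection-limit rule maps censored entries `"<L"` to `L/2`
  before the transform (a common laboratory convention).
* Any participant with CRP > 10 mg/L at **either** visit is excluded
  entirely (acute-infection screen; strict inequality, missing CRP never
  triggers exclusion). The operation is idempotent.
* Each cognitive domain is Z-scored against the **HC baseline** mean and
  s.d. (ddof = 1). The same fixed reference is applied to both visits and
  all groups, so follow-up scores live on the baseline scale and change
  scores are interpretable; re-referencing each visit separately would
  absorb genuine change into the reference.
* The cognitive composite is the mean of available domain Z-scores. It
  requires ≥ 5 non-missing baseline domains; we additionally impose the
  same ≥ 5 floor on the follow-up visit itself for a follow-up composite
  (symmetric reliability; the rule is otherwise stated for baseline only).
* The clustering feature matrix holds complete-case baseline rows of
  (log10 CRP, composite), ordered by participant id. By default both
  columns are centered and scaled to unit variance before Euclidean
  distances are formed, because raw log10 CRP spans ≈ 1 unit while the
  composite spans several s.d.; unscaled distances would down-weight
  inflammation. Whether the original workflow scaled is not documented
  anywhere we could see, so the choice is a recorded flag
  (`scale_features` / `--no-feature-scaling`) and the applied centers and
  scales are written to the audit output.

### Random-intercept mixed models (REML)

One model per outcome (nine domains, CRP): fixed effects intercept, time
(0/1 factor), group dummies (BD, SZ; HC reference), time×group, age, sex,
plus BMI for the CRP model; a random intercept per participant. The
covariance is compound-symmetric within participant, so everything profiles
onto the variance ratio λ = σ²_b/σ²_e:

* for fixed λ, β̂ is generalized least squares and σ̂²_e = RSS_W/(n − p)
  in closed form, exploiting the per-participant block structure (no n×n
  matrices are formed);
* the restricted likelihood is maximized by a bounded 1-D search on
  log λ ∈ [−12, 12] with tolerance 1e-9 (scipy Brent-on-bounds). The log
  parameterization keeps both variances positive by construction; the lower
  boundary is reported as σ²_b = 0, the exact OLS limit.
* Inference is normal-approximation Wald (z = β̂/se). No Satterthwaite or
  Kenward–Roger degrees of freedom — a documented limitation; with ~441
  participants the normal reference is adequate, but p-values for small
  cohorts will be slightly liberal.
* Rows missing the outcome or a covariate are dropped listwise per outcome;
  participants retaining a single visit still inform the fixed effects.
* Bonferroni correction is applied across the 10-outcome family by default.
  Whether the original correction family was outcomes, coefficients, or
  both is not recoverable; the family is a configuration option.

The implementation is cross-checked in the tests against statsmodels
MixedLM (coefficients, standard errors, variance components and restricted
log-likelihood agree to ≤ 1e-4 on simulated data) and against closed-form
identities: on balanced complete two-visit data the time effect equals the
mean change score exactly, and its Wald z equals the paired-t statistic.

### Hierarchical clustering

Agglomeration is implemented directly via the Lance–Williams recurrences
for single, complete, average and Ward linkage (the inner loop is
numba-compiled; a nearest-neighbour cache makes a full n = 400 run ≈ 1 ms).
Properties and conventions:

* **Ward dialect.** Default `ward.D2`: the recurrence runs on squared
  Euclidean distances and merge heights are square-rooted back, matching
  the agnes/scipy convention for Euclidean input and equal (verified
  exactly in tests) to the centroid formulation √(2·ΔESS). The `ward.D`
  variant (same recurrence on unsquared dissimilarities) is available
  behind a flag; which dialect the original toolchain used is not
  recoverable, and the choice is recorded in output metadata.
* **Tie-breaking** at equal merge cost: the pair with lexicographically
  lowest current slots, a merged cluster keeping the lower slot of its
  parents — deterministic across platforms. Random continuous data has
  ties with probability zero; the rule matters only for constructed
  fixtures.
* **Agglomerative coefficient** (Kaufman–Rousseeuw): mean over
  observations of 1 − m(i)/h_final, where m(i) is the height of the
  observation's first merge. All-identical data (h_final = 0) yields AC = 0
  with a warning; at n = 2 the AC is 0 by construction.
* **Linkage selection**: highest AC among the four candidates; exact ties
  resolve ward > average > complete > single.
* **Silhouette**: s(i) = (b−a)/max(a,b) with the s = 0 convention for
  singleton clusters (and for degenerate 0/0 cases from duplicated
  points); k is chosen to maximize the mean silhouette over k = 2..8
  (the inspected range is not documented; 2..8 covers every plausible
  patient-subtyping solution at n ≈ 400), ties to the smallest k.
* The merge history exports to the (n−1)×4 merge-table convention
  (negative indices = original observations) and to Newick with
  height-difference branch lengths.

Correctness is established against a brute-force oracle that re-derives
every inter-cluster dissimilarity from the original distance matrix (or,
for Ward, from cluster centroids) at every step, on hundreds of random
instances, and against scipy's linkage on larger instances.

### Cluster existence: the single-Gaussian simulation test

A multivariate Gaussian (sample mean, sample covariance; a diagonal
covariance and a ridge option exist behind flags) is fitted to the feature
matrix; M = 999 synthetic datasets of the same n are drawn and pushed
through the **identical** clustering path — same linkage, same fixed k,
same feature scaling. The null statistic is the mean silhouette and

    p = (1 + #{null ≥ observed}) / (M + 1),

the add-one Monte-Carlo correction, so p ≥ 1/(M+1) > 0 always. Re-selecting
k within each simulated dataset (rather than fixing it at the observed k)
is available behind a flag; fixed k is the default because it tests the
observed solution specifically and is the cheaper, more conservative
reading of the procedure. Type-I calibration (nominal 5% at n = 200,
M = 199, 200 replicates) and power at extreme separation are part of the
acceptance tests.

### Cluster stability: bootstrap Jaccard

B = 100 resamples of size n with replacement; each is reclustered with the
same linkage and k; every **original** cluster is compared with its
most-similar bootstrap cluster by Jaccard similarity computed on the set of
distinct original indices present in the resample (the clusterboot
matching convention, not one-to-one assignment). A cluster with mean
Jaccard > 0.7 is called stable. Resamples with fewer than k distinct
points are redrawn and counted.

### Subgroup profile

Cluster contrasts follow a fixed battery: Welch t with Cohen's d
((n−1)-weighted pooled-s.d. denominator by default, Welch-style available)
for continuous variables per visit; Pearson chi-squared without continuity
correction for sex and diagnosis composition; Bonferroni across the
cross-sectional battery (a per-visit family split is available). Variables
with **sustained** differences — Bonferroni-significant at both visits —
get a longitudinal follow-up: within-subgroup Wilcoxon signed-rank time
effects (exact p for ≤ 25 untied pairs, otherwise normal approximation
with continuity correction; effect size r = |Z|/√n_pairs always from the
normal deviate) and a between-subgroup rank-sum contrast on the change
score ΔY = Y₁ − Y₀. The diagnosis-level battery additionally provides
Kruskal–Wallis (midrank tie correction) and pairwise permutation t tests
(two-sided, Welch statistic, label shuffles, add-one Monte-Carlo p,
n_perm = 10,000 by default, exact enumeration available for small groups).

## The synthetic cohort generator

The generator emulates the structure of a first-treatment SMI cohort with
controls: n = 133 SZ / 88 BD / 220 HC, two visits with the follow-up drawn
uniformly on [250, 550] days (mean 400, inside the 6-month–1.5-year
window), and a latent two-subgroup mixture with subgroup-2 (higher
inflammation – lower cognition) probabilities 0.75 / 0.48 / 0.38 for
SZ / BD / HC.

Cognition for participant i, domain d, visit j:

    Y_idj = offset(diag) + shift_cog·(z_i − p̄_diag) + b_i + practice·1[j=1, d∈P] + e_idj

with diagnosis offsets −1.0 / −0.5 / 0 s.d. (SZ/BD/HC), subgroup-2 shift
−1.0 s.d., practice effect +0.2 s.d. on fine-motor speed, psychomotor
speed, verbal learning and cognitive control at follow-up, person intercept
b_i ~ N(0, 0.3²) and residual e ~ N(0, 0.8²). log10 CRP is person-level
(baseline mean 0.18 ≈ 1.5 mg/L, person s.d. 0.12, visit s.d. 0.08 — the
within-person CRP test-retest correlation is unreported anywhere, so the
visit noise is an explicitly free parameter) with subgroup-2 shift
+0.35 log10 mg/L and a BMI slope of 0.02 per kg/m². Clinical scales (five
PANSS factors, YMRS, GAF-S/F) are generated for SMI rows only as clipped
Gaussians with subgroup-2 worse and improvement at follow-up, except the
disorganized factor, which has zero time effect (the scale reported to
stay flat). Sex, age and BMI are drawn independently of subgroup. Item
missingness is injected completely at random (2% per domain cell, 3% for
CRP), reproducing the ~3–4% complete-case loss between enrolment and the
clustering subsample.

**Centering of the latent shifts.** The subgroup shifts enter as
shift·(z − p̄_diag), centered within diagnosis, so every diagnosis's
marginal mean equals its configured offset exactly. This makes the
structure self-consistent: SZ averages −1 s.d. against HC regardless of
its 75% subgroup-2 load, HC baseline domains have mean 0 / s.d. ≈ 1, and
CRP shows **no** case-control difference even though subgroup membership
is strongly diagnosis-dependent — the mixture redistributes individuals
around the group mean instead of moving it.

**Noise calibration.** The free noise s.d.s were fixed once against two
constraints: per-domain HC baseline s.d. ≈ 1 including the mixture
variance, and end-to-end recoverability of the latent subgroups by the
default pipeline (k* = 2 and adjusted Rand index > 0.5 in ≥ 90% of seeds),
which the package treats as a defining property of the generator. The
composite's implied test-retest reliability, b²/(b² + e²/9) ≈ 0.56, is at
the low end of what cognitive batteries show.

**What the generator does not emulate**, and hence what passing tests do
not establish about clinical data: the two historical test batteries and
their harmonization (a single battery is simulated); medication (DDD) and
untreated-illness duration; informative missingness or dropout (MCAR
only); skew, floor and ceiling effects in clinical scales beyond simple
clipping; and realistic overlap between subgroups — the default
configuration is **more separable** than a typical clinical cohort
(between-cluster Cohen's |d| ≈ 2 on both features), so recovery results
bound what the method can do under favourable conditions, not what it will
do on real data. Real log10 CRP also disperses more (total s.d. ≈ 0.24
here against ≈ 0.4 in unscreened cohorts); the tighter spread reflects an
infection-screened sample and the recoverability constraint above.

## Numerical and reproducibility choices

* Every randomized stage draws from a substream derived from the single
  user seed and a fixed stage key (numpy SeedSequence spawning), so
  changing the number of bootstrap resamples cannot perturb the null test,
  and every result object records its seed. Reports are byte-identical
  under a fixed (config, seed); wall-clock timings are written to a
  separate file for that reason.
* Degenerate inputs have defined behaviour throughout: zero HC reference
  s.d. errors naming the domain; all-identical clustering input yields
  AC = 0 with a warning; a perfectly fitting mixed model reports the
  boundary σ² → 0 instead of failing; constant permutation-test pairs
  return p = 1 with a warning; singular null covariance errors with a
  ridge suggestion.
* The pipeline refuses to profile subgroups when the existence test has
  not rejected (p > α) unless forced — profiling clusters that may not
  exist is the one methodological foot-gun the orchestration guards
  against.

## Problem sizes used by the verification suite

Oracle equivalence runs 200 random instances at n ≤ 12 across the four
linkages; null-test calibration uses 200 replicate tests at n = 200,
M = 199; stability behaviour uses 50 runs at n = 200, B = 100; REML
coverage uses 200 replicates at n = 400 participants; end-to-end recovery
and the family-wise-error study use 20 and 200 generated cohorts
respectively. These sizes give binomial confidence intervals tight enough
for the pass criteria while keeping the full suite under two minutes.
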