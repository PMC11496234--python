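# inflamcog

Transdiagnostic **inflammatory-cognitive subtyping** for longitudinal
case-control cohorts of severe mental illness (schizophrenia-spectrum SZ,
bipolar-spectrum BD) and healthy controls (HC), with two visits roughly one
year apart. The package is aimed at biostatisticians and psychiatric
researchers who want to exercise, validate or extend this subtyping
procedure without access to clinical data: a synthetic-cohort generator with
known ground truth stands in for the (non-public) patient sample.

## What it computes

Given a long-format participant-visit table with C-reactive protein (CRP,
mg/L), nine cognitive-domain scores and clinical scales:

1. **Preprocessing** — log10(CRP); exclusion of participants with CRP > 10
   mg/L at either visit (acute infection); Z-standardization of each
   cognitive domain against the HC baseline mean and s.d.; a cognitive
   composite (mean of available domain Z-scores, requiring ≥ 5 non-missing
   baseline domains).
2. **Longitudinal course** — per outcome Y (each domain, CRP) a
   random-intercept linear mixed model fitted by REML,

       Y_ij = β0 + β1·time_j + β2·group_i + β3·(time×group)_ij + covariates + b_i + e_ij,

   b_i ~ N(0, σ²_b), e_ij ~ N(0, σ²_e), time coded 0/1, HC the reference
   group; sex/age covariates (plus BMI for CRP); Wald tests with Bonferroni
   correction across the 10 outcomes.
3. **Subgroup discovery** — agglomerative hierarchical clustering of the
   baseline (log10 CRP, composite) feature matrix: Euclidean distances;
   linkage chosen by agglomerative coefficient among single / complete /
   average / Ward; number of clusters chosen by average silhouette;
4. **Cluster validation** — a parametric-simulation test of cluster
   existence (mean silhouette against data drawn from a single multivariate
   Gaussian fitted to the features, Monte-Carlo p-value) and bootstrap
   Jaccard stability (mean per-cluster Jaccard > 0.7 ⇒ stable);
5. **Subgroup profiling** — Welch t / Cohen's d, chi-squared, Kruskal–Wallis,
   permutation t tests, Wilcoxon signed-rank with effect size r, change
   scores ΔY = Y₁ − Y₀, all Bonferroni-corrected.

The clustering core (Lance–Williams agglomeration for all four linkages,
agglomerative coefficient, silhouette, tree cutting) is written from
scratch and verified in the test suite against brute-force re-agglomeration
and independent library implementations.

## Worked example

Run the analysis scripts in order (each reads/writes under `results/`):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_preprocess.py
python analysis/03_mixed_models.py
python analysis/04_cluster.py
python analysis/05_validate_clusters.py
python analysis/06_subgroup_profiles.py
```

The clustering and validation stages print:

```
agglomerative coefficients: {'single': 0.9145, 'complete': 0.9796, 'average': 0.967, 'ward': 0.9956}
selected linkage: ward
mean silhouette by k: {2: 0.435, 3: 0.335, 4: 0.292, 5: 0.287, 6: 0.291, 7: 0.295, 8: 0.284}
selected k = 2 (mean silhouette 0.435)
cluster sizes: {1: 244, 2: 184}
Gaussian-null test: observed mean silhouette 0.435, p = 0.001 (M=999)
cluster 1: mean Jaccard 0.823 -> stable
cluster 2: mean Jaccard 0.803 -> stable
```

Ward's linkage wins with agglomerative coefficient ≈ 0.996 (strong
hierarchical structure), the silhouette curve peaks at two clusters, the
single-Gaussian null is rejected at the smallest attainable p (0.001 with
999 simulations), and both clusters are stable under bootstrapping. The
profiling stage then shows what the clusters mean — cluster 2 is the
higher-inflammation / lower-cognition subgroup at both visits (Cohen's
|d| ≈ 2 here; the synthetic default is deliberately well-separated), it is
enriched for SZ (composition chi-squared p ≪ 0.001), and the recovered
partition agrees with the generator's latent truth (adjusted Rand
index 0.70).

The same pipeline runs as one command, from a config or a user-supplied
cohort CSV:

```sh
inflamcog run --seed 42 --out results/          # synthetic end-to-end
inflamcog run --cohort mycohort.csv --out out/  # your own data
```

`inflamcog simulate/preprocess/lmm/cluster/validate` expose the individual
stages.

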