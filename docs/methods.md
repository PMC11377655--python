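# Methods notes

This note documents the modelling and numerical choices behind
`structconn`: what each stage computes, which conventions were open and
how they were fixed, what the synthetic cohorts do and do not emulate,
and the problem sizes used by the test suite.

## Thresholding and AUC integration

Proportional (density) thresholding keeps exactly
k = round(d · n(n−1)/2) edges (round half away from zero). Ties at the
cutoff weight are broken by a fixed total order — weight descending,
then row index, then column index ascending. The rule is arbitrary but
deterministic, and it gives *nested supports*: the edge set at a lower
density is always a subset of the set at a higher density, which in turn
makes fragmentation monotone in density. Streamline counts are integers,
so ties are common and an undocumented tie rule would make runs
irreproducible.

The default integration grid is 0.10–0.55 in steps of 0.05 (10
densities). Data-driven selection is available: the lower bound is the
smallest candidate density at which no subject has a strength-0
(fragmented) node, the upper bound the largest at which every subject's
σ exceeds 1 (the "all subjects" fraction is configurable via
`thresholds.sigma_fraction`). Candidate densities default to 1–10% in
1% steps and 10–90% in 5% steps; both sub-grids are exposed in
configuration because either convention is defensible. Metrics are
summarized per subject by the trapezoidal area under the
metric-vs-density curve; the trapezoid rule is exact for the constant
and linear curves used as test oracles.

## Graph metrics

Edge weights are mapped to lengths by ℓ = 1/w — the standard convention
for count-weighted connectomes, where more streamlines mean a shorter
effective distance. Shortest paths are exact: dense Floyd–Warshall for
n ≤ 256 (faster at connectome scale), Dijkstra per source above.
Betweenness is the unnormalized Brandes variant with tied geodesics
splitting credit; group inference on AUC values is invariant to any
common normalization, so none is imposed. Clustering is Onnela's
formula with weights normalized by the in-network maximum, matching the
common toolbox convention. Inside a selected threshold range networks
are guaranteed connected, so the nodal APL policy defaults to "strict"
(an unreachable pair is an error naming the nodes); a "reachable-mean"
policy exists for exploratory use outside the range.

Small-worldness is σ = (C/C_null)/(L/L_null) with C the mean Onnela
clustering and L the characteristic path length over reachable ordered
pairs. Nulls are Maslov–Sneppen degree-preserving rewires of the binary
topology (10 swap attempts per edge by default) with the original
weight multiset randomly permuted onto the rewired edges; exact
strength-preserving weighted rewiring is underdetermined and much more
expensive, and the σ coefficient's provenance is the binary-degree
null. Surrogate connectivity is not enforced (enforcement biases
C_null upward); a fragmented surrogate's L is a reachable-pair mean.
The default ensemble size is 20 surrogates per (subject, density); each
draw is seeded from (stage seed, subject index, density index), so any
single σ value can be reproduced in isolation.

The participation coefficient needs a community partition that is
comparable across subjects and thresholds, so one Louvain
(modularity-maximizing) partition is computed on the control-group mean
matrix thresholded at the grid's midpoint density, then frozen. PC is
reported descriptively but excluded from hypothesis tests, which cover
nodal strength, betweenness, clustering and APL on the MTL and DMN node
sets, module total strength and mean APL, and the three global metrics.

## Group inference and associations

The permutation statistic is the raw difference of group means of AUC
values — the minimal reading of "non-parametric resampling"; a
studentized variant would change little at n = 61/61 but would add a
choice the method does not need. Group labels are permuted preserving
group sizes; p = (1 + #{|Δ*| ≥ |Δ_obs|}) / (1 + n_iter) is two-sided
and never zero. All scopes share one permutation draw per run, which
keeps the comparison table mutually consistent and reproducible from a
single seed. No multiple-testing correction is applied anywhere, and
the written summary carries an explicit banner to that effect;
significance is α = 0.05 throughout.

Clinical associations are implemented as fixed-covariate adjustment:
predictor and outcome are each residualized on age and years of
education (plus intercept) by least squares over listwise-complete
cases, and the partial Pearson r of the residuals is tested against a t
distribution with n − k − 2 degrees of freedom. The data are
cross-sectional with one row per subject, leaving no grouping structure
for random effects, so a mixed model would reduce to exactly this.

Volumes are adjusted as Vol_adj = Vol_obs − β(ICV − ICV_mean), with β
estimated by OLS on the pooled sample (a controls-only estimation mask
is available and logged). Adjustment is idempotent — re-estimating β on
adjusted volumes gives 0 to numerical precision — and group comparisons
use Welch's t test, the safer default when variances may differ.

## The synthetic cohort generator

The generator produces the statistical structure the analysis assumes,
with full ground truth for recovery tests. Expected counts follow
λ_ij = base_scale · h_i h_j · g_ij · u:

- **h** — per-region hubness, a named editable preset (default elevates
  bilateral hippocampus, thalamus, precuneus, superior frontal and a few
  secondary hubs; everything else 1.0);
- **g** — a geometric backbone: within-hemisphere pairs are boosted by
  1 + 20·exp(−(ring distance − 1)/4.5) and homotopic pairs by a flat
  factor 12. This gives thresholded networks lattice-like clustering:
  they stay small-world (σ > 1 for essentially all subjects) through
  density 0.55, lose σ > 1 above it, and fragment only below ~8%
  density — the regime the threshold-range selection logic expects;
- **u** — a per-subject lognormal factor (sd 0.15, unit mean) mimicking
  residual global tractogram-size variation.

Counts are negative binomial with dispersion 8 (variance = λ + λ²/8;
`dispersion=inf` gives a Poisson mode used by the tests), drawn once per
upper-triangle cell, so matrices are symmetric integer-valued with zero
diagonal by construction. Patients get every edge incident to a
lesioned node multiplied by 1 − δ (default: both hippocampi, δ = 0.15 —
chosen for statistical power at n = 61/61, not as an empirical effect
size) and edges of a gain node by 1 + γ (default right precuneus,
γ = 0.05), modelling hub failure with partial load redistribution.

Hippocampal volumes are linear in the subject's own-hemisphere
hippocampal strength AUC plus an ICV term and Gaussian noise; the
memory score is linear in left hippocampal strength AUC with age and
education confounds. Slopes and noise variances are solved so the
model-implied correlations equal the configured targets (0.33 / 0.53
for volumes, 0.30 partial r for memory), using the strength-AUC
variance estimated from a pilot ensemble of patient draws. The pilot
has 150 draws: the strength-AUC distribution is heavy-tailed (lognormal
subject factor × negative binomial counts), so a much smaller pilot
gives sd estimates with >10% error that propagate directly into the
realized correlations. Everything — matrices, phenotypes, manifest —
is byte-reproducible from the single generator seed.

What the generator does **not** emulate: spatial embedding and true
fiber geometry, distance-dependent tractography biases, hemispheric
asymmetries, realistic covariance between demographics and connectivity
(age and education are independent of the matrices by construction),
and any longitudinal structure. Passing recovery tests therefore shows
that the pipeline detects the encoded effect type at the encoded
magnitude under overdispersed count noise — not that it would do so
under every real-world artifact.

## Problem sizes and numerical tolerances

- Asymmetry tolerance on input matrices: 1e-9 absolute (counts are
  integers upstream; the tolerance only absorbs text round-trip noise).
  Matrices are written with 17 significant digits and parsed with
  round-trip float precision, so write→load is bit-exact.
- Oracle comparisons (Floyd–Warshall, exhaustive-path betweenness,
  naive Onnela) run on random graphs with n ≤ 7 at tolerance 1e-9;
  continuous weights avoid coincidental tied geodesics, and a
  power-of-two-weight case checks tie splitting exactly.
- Permutation calibration uses 1,000 null datasets × 2,000 iterations;
  full-pipeline lesion recovery uses 20 replicate cohorts of 61/61 with
  2,000 permutations, a strength-plus-global metric battery and 3
  surrogates per σ (5 swap attempts per edge); coupling calibration
  uses 50 replicate cohorts. These sizes keep the default suite to a
  few minutes while leaving the Monte-Carlo bands comfortably wider
  than the assertion tolerances.
- The modularity partition, all permutation draws, σ ensembles and the
  generator derive from named stage seeds fanned out of one global seed
  via `SeedSequence`; two runs with the same configuration produce
  byte-identical output tables.

## Known limitations

- Participation coefficients depend on the frozen reference partition;
  an alternative partition changes their absolute values (they are not
  hypothesis-tested for this reason).
- σ with small null ensembles is noisy; it enters group comparisons
  symmetrically for both groups, so tests stay calibrated, but single
  σ values should not be over-interpreted.
- The permutation test assumes exchangeability under the null; strong
  group differences in variance would require a studentized statistic
  (available only by extension).
- Bootstrap resampling (as opposed to label permutation) is exposed
  nowhere by default; the permutation reading of "resampling" is the
  implemented one.
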