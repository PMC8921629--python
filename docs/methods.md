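# Methods

This note documents the models and procedures implemented in `cimp`, the
design choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and the numerical
conventions (tolerances, tie-breaks, degenerate inputs) a maintainer
needs to know.

## The statistical model of CIMP

CIMP is treated as the existence, within one cancer cohort, of a sample
subset with coordinately elevated CpG-island methylation relative to
another subset of the same cohort. The operational definition has three
ingredients:

* a **DMP set**: probes whose beta-value distributions differ across the
  methylation clusters (Kruskal–Wallis per probe, Bonferroni with family
  size = probes tested, adjusted p < 0.05);
* **group order**: clusters ranked by mean beta over the DMP set into
  low / (intermediate) / high;
* the **call**: CIMP-positive iff `mean_β(high) − mean_β(low) > 0.20`
  over the DMP set *and* the per-sample mean-beta distributions of the
  two groups differ (Kruskal–Wallis on per-sample means, Bonferroni over
  the number of group pairs, p < 0.05).

The 0.20 cutoff is a convention, not an estimate; it is exposed as
`PipelineConfig.cimp_delta` so sensitivity analyses are one-flag
experiments. The distribution test deliberately uses per-sample mean
betas (n = samples) rather than pooled per-probe values, so its units
are independent sampling units.

The **CIMP score** of a sample is its mean beta over the DMP set — a
continuous hypermethylation index used for the gradient-like cohorts
where a hard grouping is a caricature. The same DMP set defines groups,
call and score; it is estimated once, on the provisional clusters, and
never re-estimated from the named groups, avoiding a circular
definition.

## Preprocessing

Fixed order: context/NA/sex filter → non-variable filter → purity
correction → age/gender filter. Per-probe SD is computed after missing-
value removal and before purity correction.

* **Context/NA/sex.** Retained probes are non-OpenSea (islands, shores,
  shelves), fully observed in every sample, and autosomal. Filters only
  drop probe rows; the sample set is never changed.
* **Non-variable probes.** 1-D k-means (k = 2, 10 restarts, fixed seed)
  on the per-probe SDs; the cluster with the lower centroid is removed.
  A centroid gap below 1e-6 raises a degenerate-variance error (there is
  no meaningful split to make). An exact centroid tie keeps the
  higher-SD cluster.
* **Purity correction.** The bulk methylation of sample s is modeled as
  a two-component mixture `β_obs = p_s·β_tumor + (1−p_s)·β_normal` with
  known purity p_s and a per-probe normal reference (cohort normal-mean
  or simulation truth). The tumor component is recovered by the closed-
  form inverse, clipped to [0,1]. This is a deliberately simple,
  exactly-testable deconvolution: remixing the corrected values with the
  same purity and reference reproduces the observed matrix exactly on
  unclipped entries, a property the test suite asserts. Samples with
  unknown purity are passed through unchanged and logged; purity 0 is an
  error (the mixture is not invertible).
* **Age/gender probes.** Blacklisted probes (externally curated
  age-related positions) are removed unconditionally. Then, per cohort,
  each probe is tested for Pearson correlation with age and
  point-biserial correlation with gender (two-sided t-test), BH-adjusted
  within cohort and variable. Probes significant (q < 0.05) for the same
  variable in at least two cohorts are removed from every cohort —
  cohort-specific associations are kept because they may be subtype
  signal. With a single cohort only the blacklist applies (logged). The
  BH family is the probes tested within one cohort; pooling across
  cohorts would couple the families and was rejected.

## Clustering and confidence

Samples are clustered on their filtered beta vectors. The affinity is
the binary 10-nearest-neighbor graph (Euclidean), OR-symmetrized, zero
diagonal. Spectral clustering (normalized Laplacian embedding + k-means)
is run 10 times with distinct derived seeds; consensus(i,j) is the
fraction of runs co-assigning i and j; final labels cut the
average-linkage dendrogram of (1 − consensus) at k. The consensus
scheme (co-association matrix + linkage cut) is the standard way to make
the result independent of any single k-means initialization, and it is
deterministic given the seed. An empty k-means cluster inside a spectral
run is retried with a new derived seed up to 5 times, then errors; an
empty cluster in the final cut errors immediately.

k ∈ {2,3} is chosen by running the full procedure per candidate and
keeping the k with the largest high–low delta over its own DMP set,
subject to every cluster holding ≥ 5% of samples. Deltas within 0.01 of
the best count as ties and the smallest such k wins: splitting a
homogeneous group nearly always buys a marginally higher delta by
selecting the more extreme sub-cluster as "high", and the tolerance
prevents that spurious preference for k = 3. If no candidate yields any
DMP, groups are ordered by overall mean beta and the call is necessarily
negative (empty DMP set).

Per-sample confidence is the silhouette coefficient on the full filtered
beta vectors with Euclidean distance (not on the spectral embedding —
the confidence should describe the data representation, not the
algorithm's internal coordinates). Samples with silhouette > 0 are
high-confidence (HC); all driver and survival statistics use HC samples
only.

## Driver screens

* **Fisher enrichment.** Two-sided Fisher's exact test per gene on the
  2×2 table (mutated/wild × low/high), HC samples only, BH across genes.
  Two-sided because enrichment in either group is of interest. A gene is
  *reported* when p < 0.05 and |freq_high − freq_low| > 0.10; genes with
  BH q ≥ 0.1 carry a non-significant flag. Genes mutated in fewer than 3
  HC samples cohort-wide are excluded from testing (no power) but stay
  in the random-forest input, which can exploit combinations.
* **Burden-corrected empirical p.** Hypermutated (MSI-high) samples
  inflate every gene's frequency, and MSI itself associates with the
  high-methylation group — so naive Fisher flags passengers. The null
  redraws each sample's indicator for a gene as Bernoulli with
  probability proportional to that sample's total mutation burden,
  calibrated so the expected mutated count equals the observed count;
  the statistic is freq_high − freq_low and
  `empirical_p = (1 + #{null ≥ observed}) / (1 + n_perm)`. This
  preserves exactly the confounder (per-sample rate) while breaking the
  gene–group link, and it is calibrated: on genes generated from the
  null itself the empirical p-values are uniform (asserted by KS test in
  the suite).
* **Random-forest screen.** A class-weight-balanced forest (500 trees
  by default, sqrt-features, unlimited depth — deliberately not tuned)
  predicts group membership of HC samples from the full binary matrix
  under stratified 5-fold CV. The screen passes when mean CV balanced
  accuracy exceeds the 95th percentile of a label-permutation null; on a
  pass, genes with positive validation-fold permutation importance
  (averaged over folds) are selected. Permutation importance on held-out
  folds was chosen over impurity importance because the latter inflates
  high-cardinality/noisy features.
* **Score correlation.** Point-biserial r (Pearson with the 0/1
  mutation vector) against the CIMP score, t-test p, BH; significant at
  q < 0.1. Constant mutation columns are excluded from the family.

## Clinical outcome

Kaplan–Meier per group and pairwise log-rank tests on HC patients, BH
across all tests of the invocation (a pan-cohort caller can pool extra
p-values into the same family). Groups with zero events get a curve but
no test (logged). The Cox model uses indicator covariates for the
high/intermediate groups against the low baseline plus age, 0/1-coded
gender and ordinally-coded stage; single-valued or absent covariates are
dropped with a note; Wald p-values are uncorrected. The proportional-
hazards assumption is deliberately not tested; reported hazard ratios
should be read as weighted averages of possibly time-varying hazards.
Fewer than five events per covariate triggers a logged warning, not an
error.

The probe panel: candidates are the DMP set (capped at the 100 probes
with the largest |mean(high) − mean(low)| when larger, for
tractability); a seeded stratified 90/10 train/test split; sequential
forward selection adds the probe maximizing mean stratified 5-fold CV
adjusted balanced accuracy of a balanced-class-weight logistic
regression, stopping at five probes, at no CV improvement, or at a
perfect CV score. The final model is refit on the training split and
scored once on the held-out 10%. The SHA-256 checksum of the sorted
training indices is recorded so tests can verify the held-out samples
never entered selection. ABAC = (balanced accuracy − 1/C)/(1 − 1/C)
maps chance to 0 and perfection to 1.

## Downstream and immune

A gene is a downstream target when differentially expressed between the
high and low groups (pluggable test; built-in default is the rank-sum
test with BH q < 0.05 — an external DE table can be supplied instead)
and annotated (manifest gene column, semicolon-split, multi-gene probes
counting for each gene) to ≥ 1 probe with mean(high) − mean(low) > 0.10.
The expression direction is deliberately unconstrained; the methylation
direction is hypermethylation in the high group.

Gene-set enrichment uses the EASE score: the one-sided Fisher p of the
2×2 table with the target/set overlap decremented by one (floored at 0)
— a conservative jackknife that sends any single-gene overlap to p = 1.
It is never smaller than the plain one-sided Fisher p (property-tested
on random table sweeps). Sets are flat; no ontology-graph propagation.

Immune structure: per categorical subtype, Fisher's exact test of
(subtype vs rest) × (high vs low), BH across subtypes; per continuous
signature/cell-fraction column, Spearman rho against the CIMP score
(t-test p), BH across columns; q < 0.05. Constant columns are excluded
and logged.

## The synthetic-cohort generator

The generator plants every structure the pipeline is designed to
detect, and records it in a `GroundTruth` object:

* **Probe roles** (disjoint): informative probes (baseline U(0.15,0.35),
  +Δβ in CIMP samples; default Δβ = 0.30 on 10% of probes), non-variable
  probes (noise SD 0.003 — the low-SD regime the variance filter must
  remove), age probes (linear slope, default 0.05 beta/decade, ages
  U(30,80)), sex-chromosome / OpenSea / missing-value probes exercising
  the context filter, and variable background probes. Baseline means for
  generic probes come from a low/mid/high mixture (≈0.1/0.5/0.8),
  mimicking the bimodality of real beta distributions.
* **Variability model.** Measurement noise is truncated Gaussian on the
  beta scale (default SD 0.05), plus per-probe biological sample-to-
  sample heterogeneity (SD drawn U(0.08, 0.12)) on all variable probes.
  The heterogeneity is zero-mean, so planted group means are unaffected,
  but it gives variable probes the realistically larger SD that makes
  the k-means variance filter a two-regime problem rather than a
  noise-floor artifact. Clipping to [0,1] introduces a small bias near
  the boundaries; test tolerances account for it.
* **Purity.** Observed betas are the exact mixture of the tumor signal
  with the probe-baseline normal reference at per-sample purity
  U(0.4, 0.95). Because the mixing is exact (no post-mixing noise), the
  closed-form correction recovers the tumor signal up to clipping, and
  the purity-recovery test measures numerical fidelity, not an
  identifiability claim about real deconvolution.
* **Cohorts and age probes.** Multi-cohort simulation shares one probe
  space and manifest; half the age probes carry their slope in the first
  two cohorts (they must be removed by the ≥ 2-cohort rule), half only
  in cohort 0 (they must survive).
* **Mutations.** Driver genes mutate at planted group-specific
  frequencies (default IDH1 at 80%/5%); background genes at a flat 10%.
  In MSI mode, MSI-high status is drawn with probability 0.5 in the high
  group vs 0.1 elsewhere, and multiplies the background mutation
  probability by 5 — creating exactly the burden confound the empirical
  p-value must remove.
* **Survival.** Event times are exponential with hazard
  `baseline_hazard × HR` (HR = 3 by default) for the high group. A
  `censor_rate` fraction of samples (independent Bernoulli) is censored
  at a uniform fraction of its event time, giving an exact expected
  censoring fraction; `censor_rate = 1` yields an all-censored cohort.
* **Expression and immune.** A chosen number of genes annotated to
  informative probes is log2-shifted (2-fold down by default) in the
  high group. One immune signature is a noisy monotone function of the
  sample's informative-probe methylation (so it tracks the continuous
  CIMP score, not merely the binary group), one is independent noise,
  and a categorical subtype is enriched (≈42% vs ≈17%) in the high
  group.

**What the generator does not emulate:** array chemistry (type I/II
probe bias), batch effects, correlated probe blocks within CGIs, TCGA's
exact marginal distributions, non-exponential survival, and realistic
mutation co-occurrence structure. Passing tests therefore demonstrate
that the implementation recovers what it is designed to recover under a
faithful statistical caricature — not that the pipeline's biological
conclusions transfer to any real cohort.

## Determinism and seeds

Every random draw descends from a single integer seed through named
substreams (`numpy` SeedSequence lists for the generator; arithmetic
derivations below 2^31 for scikit-learn components), so a full pipeline
run with a fixed config is byte-identical across executions — asserted
by hashing every output file of two runs. JSON outputs are written with
sorted keys and fixed separators for the same reason.

## Problem sizes used by the test and acceptance suites

Chosen as the package's own benchmark conditions: the planted-recovery
cohort is 200 samples × 5000 probes (Δβ = 0.30, 40% CIMP, noise 0.05);
specificity uses 50 null cohorts of 150 × 1500 (on null cohorts the
cluster-then-test delta concentrates around 0.18 — a selection bias that
is precisely why the 0.20 positivity margin exists, and why the null
suite uses cohorts of at least this size); calibration uses 200
permutation-null genes and 200 log-rank replicates; Cox recovery uses
n = 500 and coverage 100 replicates of n = 150; the exhaustive Fisher
cross-check enumerates all 2×2 tables with margins ≤ 15 (≤ 12 in the
fast unit variant). Random-forest settings are reduced in tests
(50–200 trees, 5–40 label permutations) relative to the 500/100
defaults; the screen's behavior is insensitive to this beyond runtime.

## Known limitations

* The two-component purity inversion assumes a single normal reference
  per probe and known purity; it is not a reference-free deconvolution.
* DMP detection and group naming share one data pass; the 0.20 delta
  threshold is the guard against the resulting selection bias, as the
  null-cohort suite quantifies.
* The delta-maximizing k selection with a 0.01 tie tolerance is a
  pragmatic separability rule, not a model-selection criterion.
* Bonferroni across ~10³–10⁴ probes is conservative; very weak DMPs are
  missed by design.
* The EASE score treats gene sets as flat and independent; BH across
  overlapping sets is approximate.
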