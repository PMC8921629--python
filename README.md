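# cimp

Discovery of the **CpG island methylator phenotype (CIMP)** from DNA
methylation beta-value matrices: a tested, reusable implementation of the
full analysis path from a raw probe × sample matrix to CIMP calls,
per-sample CIMP scores, candidate driver mutations, survival
stratification, a minimal diagnostic probe panel, and downstream
expression / tumor-microenvironment associations.

It is written for computational epigenomics researchers who want to run
CIMP discovery on their own (450k-style) methylation cohorts, or to study
the statistical behavior of the procedure itself: a synthetic-cohort
generator with complete ground truth makes every stage testable without
any data download.

## The method

A tumor cohort is represented by beta-values β ∈ [0,1] per CpG probe and
sample. The pipeline:

1. **Probe reduction** — keep probes on CpG islands, shores and shelves,
   fully observed, autosomal; drop non-variable probes by a k-means
   (k = 2) split of the per-probe SD distribution; invert the
   two-component purity mixture
   `β_obs = p·β_tumor + (1−p)·β_normal` per sample (tumor purity p,
   normal reference β_normal) and keep the tumor component; remove
   blacklisted and age/gender-associated probes (Pearson / point-biserial
   per cohort, BH q < 0.05 in ≥ 2 cohorts).
2. **Grouping** — consensus spectral clustering of samples (10-nearest-
   neighbor affinity, 10 random initializations, co-assignment consensus
   cut by average linkage), k ∈ {2,3} chosen to maximize high–low
   separability. Probes differentially methylated across clusters
   (Kruskal–Wallis, Bonferroni) form the DMP set; clusters ordered by
   mean beta over the DMPs become the low / intermediate / high
   methylation groups. Per-sample silhouette (Euclidean) > 0 defines
   high-confidence (HC) patients.
3. **CIMP call and score** — the cohort is CIMP-positive when
   `mean_β(high) − mean_β(low) > 0.20` over the DMP set and the group
   distributions differ significantly; the **CIMP score** of a sample is
   its mean beta over the DMP set.
4. **Drivers** — per-gene Fisher's exact test between HC low and high
   groups (BH; reported at p < 0.05 and frequency difference > 10%); a
   burden-corrected empirical p-value for hypermutated (MSI) cohorts
   (per-sample burden-proportional Bernoulli null); a random-forest
   screen against a label-permutation null; point-biserial correlation
   of mutations with the CIMP score (q < 0.1).
5. **Clinical outcome** — Kaplan–Meier and pairwise log-rank (BH) on HC
   patients; Cox proportional hazards with age, gender and stage; a
   ≤ 5-probe logistic-regression panel selected by sequential forward
   selection, scored with adjusted balanced accuracy
   (ABAC = (BA − 1/C)/(1 − 1/C)).
6. **Downstream** — genes both differentially expressed (rank-sum, BH)
   and hypermethylated (> 0.10 beta) in the high group; gene-set
   enrichment with the EASE score (one-sided Fisher with the overlap
   decremented by one); immune-subtype Fisher tests and Spearman
   correlations of signatures with the CIMP score.

## Worked example

`examples/01_simulate_and_call_cimp.py` simulates 200 tumors × 5000
probes in which 40% of samples carry a +0.30 beta shift on 10% of probes,
then runs the full pipeline:

```
probes: 5000 -> 4600 (context/NA/sex) -> 3100 (variance) -> 3100 (age/gender)
chosen k: 2, differentially methylated probes: 500
CIMP status: positive
high-low mean beta difference over DMPs: 0.299 (planted 0.30)
fraction of DMPs hypomethylated in the high group: 0.000
adjusted Rand index vs planted groups: 1.000
```

The filter funnel removed open-sea/sex-chromosome/incomplete probes, then
the non-variable regime; clustering recovered the planted grouping
exactly (ARI 1.0) and the high–low delta matches the planted effect, so
the cohort is called CIMP-positive. The other examples cover driver
screens with the MSI burden confound (`02`), survival and the probe panel
(`03`: Cox HR 3.60 [2.67–4.87] for a planted hazard ratio of 3, test
ABAC 1.0), downstream/immune associations (`04`), and the one-command
end-to-end run (`05`).

A thin CLI mirrors the stages:

```sh
cimp simulate --out cohort/ --seed 11
cimp config-init --out cimp.yaml      # edit paths/thresholds
cimp run --config cimp.yaml --out run/
cimp validate --beta cohort/beta.tsv --manifest cohort/manifest.tsv
```

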