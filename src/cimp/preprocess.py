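"""Probe filtering and purity correction for beta-value matrices.

The fixed reduction order is: CGI-context / missing-value / sex-chromosome
filter, non-variable probe removal (k-means split of the per-probe SD
distribution), two-component tumor-purity correction, and removal of
age/gender-associated probes (blacklist plus a cross-cohort FDR rule).
Filters only ever drop probe rows; purity correction changes values but
never dimensions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "FilterStats",
    "filter_context_na_sex",
    "filter_nonvariable",
    "correct_purity",
    "filter_age_gender",
    "preprocess_pipeline",
]

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass
class FilterStats:
    """Per-stage probe counts, mirroring a filter-funnel summary."""

    n_input: int = 0
    n_after_context: int = 0
    n_after_nonvariable: int = 0
    n_after_age_gender: int = 0
    removed_by_blacklist: int = 0
    removed_by_age_gender: int = 0
    probe_sd: pd.Series | None = None
    age_q_by_cohort: pd.DataFrame | None = None
    gender_q_by_cohort: pd.DataFrame | None = None
    notes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["input", "context_na_sex", "nonvariable", "age_gender"],
                "probes": [
                    self.n_input,
                    self.n_after_context,
                    self.n_after_nonvariable,
                    self.n_after_age_gender,
                ],
            }
        )


def _check_beta(beta: pd.DataFrame) -> None:
    if beta.index.has_duplicates or beta.columns.has_duplicates:
        raise ValueError("probe and sample identifiers must be unique")
    vals = beta.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("beta-values must lie in [0, 1]")


def filter_context_na_sex(beta: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Keep probes on CpG islands/shores/shelves, fully observed, autosomal.

    A probe is retained iff its relation-to-island is not OpenSea, it has
    no missing value in any sample, and it is not on chrX/chrY. Samples
    are untouched.
    """
    _check_beta(beta)
    missing_ann = beta.index.difference(ann.index)
    if len(missing_ann):
        raise KeyError(
            f"{len(missing_ann)} probes missing from the annotation, e.g. {missing_ann[0]!r}"
        )
    ann = ann.loc[beta.index]
    keep = (
        (ann["relation_to_island"] != "OpenSea")
        & (~ann["chr"].isin(SEX_CHROMOSOMES))
        & beta.notna().all(axis=1)
    )
    return beta.loc[keep.to_numpy()]


def filter_nonvariable(
    beta: pd.DataFrame, seed: int = 0, min_centroid_gap: float = 1e-6
) -> tuple[pd.DataFrame, pd.Series]:
    """Drop the low-variance probe regime.

    Per-probe standard deviations are split by 1-D k-means (k=2, 10
    restarts); probes in the cluster with the lower centroid are removed.
    Returns the surviving matrix and the full SD series.
    """
    if beta.shape[0] < 2 or beta.shape[1] < 2:
        raise ValueError("need at least 2 probes and 2 samples")
    sd = beta.std(axis=1, ddof=1)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(sd.to_numpy().reshape(-1, 1))
    centroids = km.cluster_centers_.ravel()
    if abs(centroids[0] - centroids[1]) < min_centroid_gap:
        raise ValueError(
            "degenerate probe-variance distribution: k-means centroids "
            f"separated by {abs(centroids[0] - centroids[1]):.2e} < {min_centroid_gap}"
        )
    # ties broken toward keeping the higher-SD cluster
    high_cluster = int(np.argmax(centroids))
    keep = labels == high_cluster
    return beta.loc[keep], sd.rename("sd")


def correct_purity(
    beta: pd.DataFrame, samples: pd.DataFrame, normal_ref: pd.Series
) -> pd.DataFrame:
    """Invert the two-component tumor/normal mixture per sample.

    Observed bulk methylation is modeled as
    ``observed = purity * tumor + (1 - purity) * normal``; the tumor
    component is recovered as ``(observed - (1 - p) * normal) / p``,
    clipped to [0, 1]. Samples without a purity estimate are returned
    unchanged (logged).
    """
    missing_ref = beta.index.difference(normal_ref.index)
    if len(missing_ref):
        raise KeyError(f"normal reference missing {len(missing_ref)} probes, e.g. {missing_ref[0]!r}")
    purity = samples["purity"] if "purity" in samples.columns else pd.Series(dtype=float)
    out = beta.copy()
    ref = normal_ref.loc[beta.index].to_numpy()
    uncorrected = []
    for s in beta.columns:
        p = purity.get(s, np.nan)
        if pd.isna(p):
            uncorrected.append(s)
            continue
        if p == 0:
            raise ValueError(f"sample {s!r} has purity 0: mixture is not invertible")
        if not 0 < p <= 1:
            raise ValueError(f"sample {s!r} has purity {p} outside (0, 1]")
        out[s] = np.clip((beta[s].to_numpy() - (1.0 - p) * ref) / p, 0.0, 1.0)
    if uncorrected:
        logger.info("purity unknown for %d samples, left uncorrected: %s", len(uncorrected), uncorrected[:5])
    return out


def _corr_with_pvalues(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each row of X against y, with two-sided t-test p-values.

    Point-biserial association is the same computation with y coded 0/1.
    Constant rows (or constant y) get r = 0, p = 1.
    """
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, Xc @ yc / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(np.maximum(n - 2, 1) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[denom == 0] = 1.0
    return r, np.clip(p, 0.0, 1.0)


def filter_age_gender(
    betas_by_cohort: list[pd.DataFrame],
    samples_by_cohort: list[pd.DataFrame],
    blacklist: set[str] | None = None,
    q_threshold: float = 0.05,
    min_cohorts: int = 2,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Remove blacklisted and cross-cohort age/gender-associated probes.

    Blacklist probes are dropped unconditionally. Then, per cohort, every
    probe is tested for Pearson correlation with age and point-biserial
    correlation with gender (t-test p, BH-adjusted within cohort and
    variable); probes significant (q < ``q_threshold``) for the same
    variable in at least ``min_cohorts`` cohorts are removed from every
    cohort. With a single cohort, only the blacklist applies (logged).

    Returns the filtered matrices and a probe x statistic table with the
    per-cohort q-values.
    """
    if len(betas_by_cohort) != len(samples_by_cohort):
        raise ValueError("betas_by_cohort and samples_by_cohort must align")
    blacklist = set(blacklist or ())
    single_cohort = len(betas_by_cohort) < min_cohorts
    if single_cohort:
        logger.info("only %d cohort(s): cross-cohort age/gender rule skipped, blacklist only", len(betas_by_cohort))

    all_probes = betas_by_cohort[0].index
    for b in betas_by_cohort[1:]:
        all_probes = all_probes.union(b.index)

    age_q = pd.DataFrame(index=all_probes, dtype=float)
    gender_q = pd.DataFrame(index=all_probes, dtype=float)
    for i, (beta, samples) in enumerate(zip(betas_by_cohort, samples_by_cohort)):
        has_age = "age" in samples.columns and samples["age"].notna().any()
        has_gender = "gender" in samples.columns and samples["gender"].notna().any()
        if not has_age and not has_gender:
            raise ValueError(f"cohort {i} lacks both age and gender columns")
        X = beta.to_numpy(dtype=float)
        if has_age:
            y = samples.loc[beta.columns, "age"].to_numpy(dtype=float)
            _, p = _corr_with_pvalues(X, y)
            age_q.loc[beta.index, f"cohort{i}"] = multipletests(p, method="fdr_bh")[1]
        if has_gender:
            g = samples.loc[beta.columns, "gender"]
            y = (g == sorted(g.dropna().unique())[0]).to_numpy(dtype=float)
            _, p = _corr_with_pvalues(X, y)
            gender_q.loc[beta.index, f"cohort{i}"] = multipletests(p, method="fdr_bh")[1]

    to_remove = set(blacklist)
    if not single_cohort:
        for qtab in (age_q, gender_q):
            if qtab.empty:
                continue
            hits = (qtab < q_threshold).sum(axis=1)
            to_remove |= set(qtab.index[hits >= min_cohorts])

    filtered = [b.loc[~b.index.isin(to_remove)] for b in betas_by_cohort]
    stats_tab = pd.concat(
        {"age_q": age_q, "gender_q": gender_q}, axis=1
    )
    stats_tab["removed"] = stats_tab.index.isin(to_remove)
    stats_tab["blacklisted"] = stats_tab.index.isin(blacklist)
    return filtered, stats_tab


def preprocess_pipeline(
    betas_by_cohort: list[pd.DataFrame],
    anns_by_cohort: list[pd.DataFrame],
    samples_by_cohort: list[pd.DataFrame],
    normal_refs: list[pd.Series],
    blacklist: set[str] | None = None,
    seed: int = 0,
) -> tuple[list[pd.DataFrame], FilterStats]:
    """Run the full reduction in the fixed order:
    context/NA/sex -> non-variable -> purity -> age/gender.

    Per-probe SD for the non-variable split is computed after NA removal
    and before purity correction.
    """
    fs = FilterStats(n_input=sum(b.shape[0] for b in betas_by_cohort))
    stage1 = [filter_context_na_sex(b, a) for b, a in zip(betas_by_cohort, anns_by_cohort)]
    fs.n_after_context = sum(b.shape[0] for b in stage1)
    stage2, sds = [], []
    for b in stage1:
        kept, sd = filter_nonvariable(b, seed=seed)
        stage2.append(kept)
        sds.append(sd)
    fs.n_after_nonvariable = sum(b.shape[0] for b in stage2)
    fs.probe_sd = sds[0] if len(sds) == 1 else pd.concat(sds, keys=range(len(sds)), names=["cohort"])
    stage3 = [
        correct_purity(b, s, ref)
        for b, s, ref in zip(stage2, samples_by_cohort, normal_refs)
    ]
    stage4, ag_stats = filter_age_gender(stage3, samples_by_cohort, blacklist=blacklist)
    fs.n_after_age_gender = sum(b.shape[0] for b in stage4)
    fs.removed_by_blacklist = int(ag_stats["blacklisted"].sum())
    fs.removed_by_age_gender = int(ag_stats["removed"].sum())
    fs.age_q_by_cohort = ag_stats
    return stage4, fs
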