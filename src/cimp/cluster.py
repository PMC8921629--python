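"""Consensus spectral clustering of methylation profiles and CIMP calling.

Samples are clustered on their filtered beta-value vectors with spectral
clustering on a 10-nearest-neighbor graph, stabilized by 10-fold consensus
over random initializations. Clusters are ordered by mean methylation over
the differentially methylated probes (DMPs; Kruskal-Wallis, Bonferroni)
into low / intermediate / high groups. A cohort is CIMP-positive when the
high-low difference in mean beta over the DMP set exceeds 0.20 and the
group distributions differ significantly; the per-sample mean beta over
the DMP set is the continuous CIMP score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import SpectralClustering
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import kneighbors_graph

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "MethylationGrouping",
    "CimpCall",
    "silhouette_euclidean",
    "build_knn_affinity",
    "consensus_spectral",
    "detect_dmps",
    "assign_groups",
    "select_k",
    "call_cimp",
    "cluster_clinical_association",
]

GROUP_NAMES_2 = ("low", "high")
GROUP_NAMES_3 = ("low", "intermediate", "high")


@dataclass
class ClusterResult:
    """Final consensus labels with per-sample confidence."""

    labels: pd.Series  # cluster index per sample (0-based)
    k: int
    consensus: pd.DataFrame  # sample x sample co-assignment fraction
    ssc: pd.Series  # sample silhouette coefficient, Euclidean
    hc_mask: pd.Series  # high-confidence: ssc > 0

    def __post_init__(self) -> None:
        c = self.consensus.to_numpy()
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("consensus matrix must be symmetric with unit diagonal")


@dataclass
class MethylationGrouping:
    """Clusters named by methylation level over the DMP set."""

    group_of_sample: pd.Series  # low / intermediate / high
    cluster_of_sample: pd.Series
    dmp_set: list[str]
    group_means: pd.Series  # mean beta over dmp_set per group
    kw_p: pd.Series  # per-probe Kruskal-Wallis p (raw)
    bonferroni_m: int


@dataclass
class CimpCall:
    status: str  # "positive" / "negative"
    delta_high_low: float
    kw_group_p: float
    cimp_score: pd.Series  # per-sample mean beta over dmp_set
    hypo_fraction: float
    delta_high_normal: float | None = None


def silhouette_euclidean(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample silhouette coefficient with Euclidean distance.

    This is the confidence measure attached to every clustering result;
    samples with positive silhouette are the high-confidence (HC) set
    used by the downstream statistics.
    """
    return silhouette_samples(np.asarray(X, dtype=float), np.asarray(labels), metric="euclidean")


def build_knn_affinity(beta: pd.DataFrame, n_neighbors: int = 10) -> pd.DataFrame:
    """Binary symmetric k-NN connectivity between sample beta vectors.

    Edges join each sample to its ``n_neighbors`` Euclidean nearest
    neighbors, symmetrized by OR; the diagonal is zero.
    """
    n = beta.shape[1]
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n_samples={n}")
    X = beta.to_numpy(dtype=float).T
    g = kneighbors_graph(X, n_neighbors=n_neighbors, mode="connectivity", include_self=False)
    a = g.toarray()
    a = np.maximum(a, a.T)
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=beta.columns, columns=beta.columns)


def _spectral_once(affinity: np.ndarray, k: int, seed: int, max_retries: int = 5) -> np.ndarray:
    """One spectral clustering run (normalized Laplacian embedding +
    k-means); an empty cluster triggers a retry with a new derived seed."""
    import warnings

    for attempt in range(max_retries):
        sc = SpectralClustering(
            n_clusters=k,
            affinity="precomputed",
            assign_labels="kmeans",
            random_state=(seed + 7919 * attempt) % (2**31),
            n_init=10,
        )
        with warnings.catch_warnings():
            # a disconnected k-NN graph is expected for well-separated groups
            warnings.filterwarnings("ignore", message="Graph is not fully connected")
            labels = sc.fit_predict(affinity)
        if len(np.unique(labels)) == k:
            return labels
    raise RuntimeError(f"spectral clustering produced an empty cluster in {max_retries} attempts (k={k})")


def consensus_spectral(
    beta: pd.DataFrame,
    k: int,
    n_runs: int = 10,
    seed: int = 0,
    n_neighbors: int = 10,
) -> ClusterResult:
    """Consensus spectral clustering of samples.

    Spectral clustering on the k-NN affinity is run ``n_runs`` times with
    distinct derived seeds; the consensus matrix holds the fraction of
    runs co-assigning each sample pair. Final labels cut an
    average-linkage dendrogram of (1 - consensus) at ``k``. Silhouette
    coefficients are computed on the raw beta vectors (Euclidean) against
    the final labels.
    """
    n = beta.shape[1]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n / 5:
        raise ValueError(f"k={k} too large for n={n} samples (need k <= n/5)")
    affinity = build_knn_affinity(beta, n_neighbors=n_neighbors).to_numpy()

    co = np.zeros((n, n))
    for r in range(n_runs):
        labels_r = _spectral_once(affinity, k, seed=(seed * 1000003 + r) % (2**31))
        co += (labels_r[:, None] == labels_r[None, :]).astype(float)
    co /= n_runs
    np.fill_diagonal(co, 1.0)

    dist = 1.0 - co
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    final = fcluster(Z, t=k, criterion="maxclust") - 1
    sizes = np.bincount(final, minlength=k)
    if (sizes == 0).any():
        raise RuntimeError(f"consensus cut produced an empty cluster at k={k}")

    X = beta.to_numpy(dtype=float).T
    ssc = silhouette_euclidean(X, final)
    labels_s = pd.Series(final, index=beta.columns, name="cluster")
    ssc_s = pd.Series(ssc, index=beta.columns, name="ssc")
    return ClusterResult(
        labels=labels_s,
        k=k,
        consensus=pd.DataFrame(co, index=beta.columns, columns=beta.columns),
        ssc=ssc_s,
        hc_mask=(ssc_s > 0).rename("hc"),
    )


def detect_dmps(
    beta: pd.DataFrame, labels: pd.Series, alpha: float = 0.05
) -> tuple[list[str], pd.Series]:
    """Probes differentially methylated across clusters.

    Per-probe Kruskal-Wallis across the clusters, Bonferroni-corrected
    with family size = probes tested; the DMP set holds probes with
    adjusted p < ``alpha``.
    """
    groups = [beta.columns[labels.loc[beta.columns] == c] for c in sorted(labels.unique())]
    if len(groups) < 2:
        raise ValueError("need >= 2 clusters")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every cluster needs >= 2 samples for the Kruskal-Wallis test")
    arrays = [beta[g].to_numpy(dtype=float) for g in groups]
    m = beta.shape[0]
    pvals = np.ones(m)
    for i in range(m):
        samples = [a[i] for a in arrays]
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:  # identical values: zero statistic
            continue
        pvals[i] = stats.kruskal(*samples).pvalue
    kw_p = pd.Series(pvals, index=beta.index, name="kw_p")
    adj = np.minimum(pvals * m, 1.0)
    dmp = list(beta.index[adj < alpha])
    return dmp, kw_p


def assign_groups(
    beta: pd.DataFrame, labels: pd.Series, dmp_set: list[str], kw_p: pd.Series | None = None
) -> MethylationGrouping:
    """Name clusters low / (intermediate) / high by mean beta over DMPs.

    Ties in the cluster means are broken toward the lower cluster index
    becoming the lower methylation group (stable sort).
    """
    if not dmp_set:
        raise ValueError("dmp_set is empty: no differential methylation to order groups by")
    clusters = sorted(labels.unique())
    sub = beta.loc[dmp_set]
    means = {c: float(sub[labels.index[labels == c]].to_numpy().mean()) for c in clusters}
    order = sorted(clusters, key=lambda c: (means[c], c))
    names = GROUP_NAMES_2 if len(clusters) == 2 else GROUP_NAMES_3
    if len(clusters) > 3:
        names = ["low"] + [f"intermediate{i}" for i in range(1, len(clusters) - 1)] + ["high"]
    name_of_cluster = {c: names[i] for i, c in enumerate(order)}
    group = labels.map(name_of_cluster).rename("group")
    group_means = pd.Series({name_of_cluster[c]: means[c] for c in clusters}, name="mean_beta")
    if kw_p is None:
        kw_p = pd.Series(np.nan, index=beta.index, name="kw_p")
    return MethylationGrouping(
        group_of_sample=group,
        cluster_of_sample=labels,
        dmp_set=list(dmp_set),
        group_means=group_means,
        kw_p=kw_p,
        bonferroni_m=beta.shape[0],
    )


def select_k(
    beta: pd.DataFrame,
    candidates=(2, 3),
    seed: int = 0,
    n_runs: int = 10,
    n_neighbors: int = 10,
    min_cluster_frac: float = 0.05,
    delta_tolerance: float = 0.01,
):
    """Choose the number of clusters maximizing high-low separability.

    For each candidate k the full consensus clustering + DMP detection +
    group naming is run; candidates with any cluster smaller than
    ``min_cluster_frac`` of the cohort are rejected; among the rest the k
    with the largest high-low mean-beta difference over its DMP set wins.
    Candidates within ``delta_tolerance`` of the best delta count as ties
    and the smallest such k is returned (an extra cluster must buy a
    meaningful gain in separability, not just relabel within-group noise).
    """
    n = beta.shape[1]
    results = {}
    for k in sorted(candidates):
        if not 2 <= k <= n / 5:
            continue
        try:
            cr = consensus_spectral(beta, k=k, n_runs=n_runs, seed=seed, n_neighbors=n_neighbors)
        except RuntimeError:
            continue
        if cr.labels.value_counts().min() < min_cluster_frac * n:
            continue
        dmp, kw_p = detect_dmps(beta, cr.labels)
        if dmp:
            grouping = assign_groups(beta, cr.labels, dmp, kw_p)
            delta = grouping.group_means["high"] - grouping.group_means["low"]
        else:
            # nothing differential: order groups by overall mean beta so a
            # (necessarily negative) CIMP call can still be produced
            grouping = assign_groups(beta, cr.labels, list(beta.index), kw_p)
            grouping.dmp_set = []
            delta = 0.0
        results[k] = (delta, cr, grouping)
    if not results:
        raise RuntimeError("no candidate k satisfies the cluster-size constraint")
    best_delta = max(d for d, _, _ in results.values())
    best_k = min(k for k, (d, _, _) in results.items() if d >= best_delta - delta_tolerance)
    return best_k, results[best_k][1], results[best_k][2]


def call_cimp(
    grouping: MethylationGrouping,
    beta: pd.DataFrame,
    normal_ref: pd.Series | None = None,
    delta_threshold: float = 0.20,
    alpha: float = 0.05,
) -> CimpCall:
    """Call cohort CIMP status and compute per-sample CIMP scores.

    CIMP-positive requires the high-low difference in mean beta over the
    DMP set to exceed ``delta_threshold`` (0.20) with the per-sample mean
    beta distributions of the two groups significantly different
    (Kruskal-Wallis, Bonferroni over group-pair comparisons).
    """
    if not grouping.dmp_set:
        logger.warning("empty DMP set: CIMP status negative, scores undefined")
        return CimpCall(
            status="negative",
            delta_high_low=0.0,
            kw_group_p=1.0,
            cimp_score=pd.Series(np.nan, index=grouping.group_of_sample.index),
            hypo_fraction=np.nan,
        )
    sub = beta.loc[grouping.dmp_set]
    score = sub.mean(axis=0).rename("cimp_score")
    group = grouping.group_of_sample
    k = group.nunique()
    n_pairs = k * (k - 1) // 2
    hi = score[group == "high"].to_numpy()
    lo = score[group == "low"].to_numpy()
    if np.ptp(np.concatenate([hi, lo])) == 0:
        kw_group_p = 1.0
    else:
        kw_group_p = min(stats.kruskal(hi, lo).pvalue * n_pairs, 1.0)
    delta = float(hi.mean() - lo.mean())

    mean_hi = sub[group.index[group == "high"]].mean(axis=1)
    mean_lo = sub[group.index[group == "low"]].mean(axis=1)
    hypo_fraction = float((mean_hi < mean_lo).mean())

    delta_high_normal = None
    if normal_ref is not None:
        ref = normal_ref.loc[sub.index]
        delta_high_normal = float(mean_hi.mean() - ref.mean())

    status = "positive" if (delta > delta_threshold and kw_group_p < alpha) else "negative"
    return CimpCall(
        status=status,
        delta_high_low=delta,
        kw_group_p=float(kw_group_p),
        cimp_score=score,
        hypo_fraction=hypo_fraction,
        delta_high_normal=delta_high_normal,
    )


def cluster_clinical_association(
    grouping: MethylationGrouping,
    samples: pd.DataFrame,
    continuous: tuple[str, ...] = ("age", "purity"),
    categorical: tuple[str, ...] = ("gender", "stage", "msi_status", "immune_subtype"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each clinical variable against group membership.

    Kruskal-Wallis for continuous variables, chi-square for categorical
    ones; Bonferroni over the variables tested. Constant variables are
    skipped (logged).
    """
    group = grouping.group_of_sample
    records = []
    for var in continuous:
        if var not in samples.columns:
            continue
        vals = samples.loc[group.index, var]
        if vals.dropna().nunique() < 2:
            logger.info("clinical variable %r constant, skipped", var)
            continue
        arrays = [vals[group == g].dropna().to_numpy() for g in group.unique()]
        p = stats.kruskal(*arrays).pvalue
        records.append({"unit": var, "kind": "continuous", "p": float(p)})
    for var in categorical:
        if var not in samples.columns:
            continue
        vals = samples.loc[group.index, var]
        if vals.dropna().nunique() < 2:
            logger.info("clinical variable %r constant, skipped", var)
            continue
        table = pd.crosstab(vals, group)
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        records.append({"unit": var, "kind": "categorical", "p": float(p), "statistic": float(stat)})
    out = pd.DataFrame(records)
    if not out.empty:
        m = len(out)
        out["p_bonferroni"] = np.minimum(out["p"] * m, 1.0)
        out["significant"] = out["p_bonferroni"] < alpha
    return out
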