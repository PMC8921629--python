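"""Candidate genomic drivers of CIMP.

Four complementary screens over a binary gene x sample mutation matrix,
all restricted to high-confidence (positive-silhouette) patients:

* Fisher's exact enrichment of each gene between the low and high
  methylation groups (BH across genes; reported when p < 0.05 and the
  group frequency difference exceeds 10%).
* A burden-corrected empirical p-value for hypermutated (MSI-like)
  cohorts: the null redraws each sample's mutation indicator with
  probability proportional to its total mutation burden, so genes whose
  apparent enrichment merely tracks hypermutation are suppressed.
* A random-forest screen over the full mutation matrix, validated
  against a label-permutation null.
* Point-biserial correlation between mutation status and the continuous
  CIMP score (BH; significant at q < 0.1).
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "load_methylation_gene_list",
    "fisher_enrichment",
    "msi_empirical_p",
    "rf_screen",
    "score_mutation_correlation",
]


def load_methylation_gene_list(path=None) -> set[str]:
    """Genes involved in DNA/histone (de)methylation; the packaged default
    covers the DNMT, TET, IDH, KMT2, SETD, NSD, KDM, PRDM, EHMT, SMYD,
    MBD, CTCF(L), UHRF, BAZ2A and ATRX families."""
    if path is None:
        text = resources.files("cimp").joinpath("data/methylation_genes.txt").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return {
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    }


def _hc_group_samples(grouping, hc_mask: pd.Series, sample_ids: pd.Index):
    """High-confidence samples of the low and high groups present in the
    mutation matrix."""
    group = grouping.group_of_sample
    hc = hc_mask.reindex(group.index, fill_value=False)
    low = group.index[(group == "low") & hc].intersection(sample_ids)
    high = group.index[(group == "high") & hc].intersection(sample_ids)
    return low, high


def fisher_enrichment(
    mut: pd.DataFrame,
    grouping,
    hc_mask: pd.Series,
    min_mutated: int = 3,
    freq_gate: float = 0.10,
    alpha: float = 0.05,
    ns_q: float = 0.10,
) -> pd.DataFrame:
    """Two-sided Fisher enrichment of each gene, low vs high group.

    Only high-confidence samples enter the 2x2 tables. Genes mutated in
    fewer than ``min_mutated`` HC samples cohort-wide are excluded from
    testing (power floor). BH is applied across the tested genes. A gene
    is ``reported`` when p < ``alpha`` and |freq_high - freq_low| >
    ``freq_gate``; ``ns_flag`` marks genes with q >= ``ns_q``.
    """
    low, high = _hc_group_samples(grouping, hc_mask, mut.columns)
    if len(low) < 2 or len(high) < 2:
        raise ValueError("need >= 2 high-confidence samples in both the low and high groups")
    records = []
    for gene in mut.index:
        m_low = int(mut.loc[gene, low].sum())
        m_high = int(mut.loc[gene, high].sum())
        if m_low + m_high < min_mutated:
            continue
        table = [[m_high, len(high) - m_high], [m_low, len(low) - m_low]]
        p = stats.fisher_exact(table, alternative="two-sided")[1]
        f_low, f_high = m_low / len(low), m_high / len(high)
        records.append(
            {
                "unit": gene,
                "freq_low": f_low,
                "freq_high": f_high,
                "effect": f_high - f_low,
                "p": float(p),
            }
        )
    out = pd.DataFrame(records)
    if out.empty:
        return out
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["reported"] = (out["p"] < alpha) & (out["effect"].abs() > freq_gate)
    out["ns_flag"] = out["q"] >= ns_q
    return out.set_index("unit")


def msi_empirical_p(
    mut: pd.DataFrame,
    grouping,
    hc_mask: pd.Series,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Burden-corrected empirical enrichment p-values.

    The observed statistic per gene is ``freq_high - freq_low`` over HC
    samples. Under the null each sample's indicator for the gene is
    redrawn Bernoulli with probability proportional to the sample's total
    mutation burden, calibrated so the expected mutated count matches the
    observed count; ``empirical_p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    low, high = _hc_group_samples(grouping, hc_mask, mut.columns)
    samples = low.union(high)
    sub = mut[samples]
    burden = sub.sum(axis=0).to_numpy(dtype=float)
    if burden.sum() == 0:
        raise ValueError("total mutation burden is zero")
    is_high = samples.isin(high)
    n_high, n_low = int(is_high.sum()), int((~is_high).sum())
    w = burden / burden.sum()
    rng = np.random.default_rng([int(seed), 17])

    records = []
    for gene in sub.index:
        x = sub.loc[gene].to_numpy(dtype=float)
        m = x.sum()
        obs = x[is_high].sum() / n_high - x[~is_high].sum() / n_low
        probs = np.clip(m * w, 0.0, 1.0)
        draws = rng.random((n_perm, len(samples))) < probs[None, :]
        null = draws[:, is_high].sum(axis=1) / n_high - draws[:, ~is_high].sum(axis=1) / n_low
        emp_p = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)
        records.append(
            {
                "unit": gene,
                "freq_low": x[~is_high].mean(),
                "freq_high": x[is_high].mean(),
                "effect": float(obs),
                "empirical_p": float(emp_p),
            }
        )
    return pd.DataFrame(records).set_index("unit")


def rf_screen(
    mut: pd.DataFrame,
    grouping,
    hc_mask: pd.Series,
    n_trees: int = 500,
    n_label_perm: int = 100,
    n_splits: int = 5,
    seed: int = 0,
):
    """Random-forest screen for mutational predictability of the groups.

    A class-weight-balanced forest predicts group membership of HC
    samples from the full binary mutation matrix under stratified
    cross-validation. The screen passes when the mean CV balanced
    accuracy exceeds the 95th percentile of a label-permutation null; on
    a pass, genes with positive validation-fold permutation importance
    (averaged over folds) are selected.

    Hyperparameters are deliberately fixed (no grid search): ``n_trees``
    trees, sqrt-features, unlimited depth.
    """
    group = grouping.group_of_sample
    hc = hc_mask.reindex(group.index, fill_value=False)
    samples = group.index[hc].intersection(mut.columns)
    if len(samples) < 20:
        raise ValueError("need >= 20 high-confidence samples for the random-forest screen")
    y = group.loc[samples].to_numpy()
    counts = pd.Series(y).value_counts()
    if counts.min() < n_splits:
        raise ValueError(f"a group has < {n_splits} HC samples: cannot stratify folds")
    X = mut[samples].to_numpy(dtype=float).T

    def _cv_accuracy(y_vec, rf_seed, with_importance=False):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=rf_seed)
        accs, importances = [], np.zeros(X.shape[1])
        for fold, (tr, te) in enumerate(skf.split(X, y_vec)):
            clf = RandomForestClassifier(
                n_estimators=n_trees,
                class_weight="balanced",
                random_state=(rf_seed + fold) % (2**31),
                n_jobs=1,
            )
            clf.fit(X[tr], y_vec[tr])
            accs.append(balanced_accuracy_score(y_vec[te], clf.predict(X[te])))
            if with_importance:
                imp = permutation_importance(
                    clf, X[te], y_vec[te], n_repeats=5,
                    random_state=(rf_seed + 31 * fold) % (2**31), n_jobs=1,
                )
                importances += imp.importances_mean
        return float(np.mean(accs)), importances / n_splits

    base_seed = int(seed) % (2**31)
    cv_acc, importances = _cv_accuracy(y, base_seed, with_importance=True)

    rng = np.random.default_rng([int(seed), 23])
    null_accs = []
    for _ in range(n_label_perm):
        y_perm = rng.permutation(y)
        acc, _ = _cv_accuracy(y_perm, base_seed)
        null_accs.append(acc)
    null_q95 = float(np.quantile(null_accs, 0.95))
    passed = cv_acc > null_q95
    selected = list(mut.index[importances > 0]) if passed else []
    return {
        "passed": bool(passed),
        "selected_genes": selected,
        "cv_balanced_accuracy": cv_acc,
        "null_q95": null_q95,
        "importances": pd.Series(importances, index=mut.index, name="importance"),
    }


def score_mutation_correlation(
    cimp_score: pd.Series,
    mut: pd.DataFrame,
    genes: list[str] | None = None,
    sig_q: float = 0.10,
) -> pd.DataFrame:
    """Point-biserial correlation of mutation status with the CIMP score.

    Pearson r of the 0/1 mutation indicator against the continuous score,
    t-test p, BH across genes; significant at q < ``sig_q``. Constant
    mutation columns are flagged undefined and excluded from the BH
    family.
    """
    samples = cimp_score.index.intersection(mut.columns)
    score = cimp_score.loc[samples].to_numpy(dtype=float)
    genes = list(genes) if genes is not None else list(mut.index)
    records, skipped = [], []
    for gene in genes:
        x = mut.loc[gene, samples].to_numpy(dtype=float)
        if x.min() == x.max():
            skipped.append(gene)
            continue
        r, p = stats.pointbiserialr(x, score)
        records.append(
            {
                "unit": gene,
                "effect": float(r),
                "p": float(p),
                "freq_low": np.nan,
                "freq_high": np.nan,
            }
        )
    if skipped:
        logger.info("constant mutation columns excluded from correlation: %s", skipped[:5])
    out = pd.DataFrame(records)
    if out.empty:
        return out
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < sig_q
    return out.set_index("unit")
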