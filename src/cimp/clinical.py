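"""Survival stratification of methylation groups and the minimal
diagnostic probe panel.

Kaplan-Meier curves and pairwise log-rank tests (BH-corrected) compare
the methylation groups on high-confidence patients; a Cox proportional-
hazards model adds age, gender and stage as covariates (Wald p,
uncorrected; the PH assumption is deliberately not tested). For clinical
translation, sequential forward selection builds a panel of up to five
differentially methylated probes whose balanced-class-weight logistic
regression predicts CIMP status, scored by adjusted balanced accuracy
(chance = 0, perfect = 1) under stratified 5-fold cross-validation on a
90/10 train/test split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalResult",
    "ProbePanel",
    "km_logrank",
    "cox_fit",
    "abac",
    "select_probe_panel",
]


@dataclass
class SurvivalResult:
    km_curves: dict  # group -> DataFrame(time, survival)
    logrank_p: dict = field(default_factory=dict)  # (g1, g2) -> raw p
    logrank_q: dict = field(default_factory=dict)  # (g1, g2) -> BH q
    cox_summary: pd.DataFrame | None = None  # HR, CI, Wald p per covariate
    notes: list = field(default_factory=list)


@dataclass
class ProbePanel:
    probes: list[str]
    cv_abac: float
    test_abac: float
    coefficients: pd.Series  # per-probe weight; "intercept" row included
    train_index_checksum: str = ""


_GROUP_ORDER = {"low": 0, "intermediate": 1, "high": 2}


def _hc_survival_frame(samples: pd.DataFrame, grouping, hc_mask: pd.Series) -> pd.DataFrame:
    group = grouping.group_of_sample
    hc = hc_mask.reindex(group.index, fill_value=False)
    idx = group.index[hc].intersection(samples.index)
    df = samples.loc[idx, ["survival_time", "event"]].copy()
    df["group"] = group.loc[idx]
    if (df["survival_time"] < 0).any():
        raise ValueError("negative survival times")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event flags must be 0/1")
    return df


def km_logrank(
    samples: pd.DataFrame,
    grouping,
    hc_mask: pd.Series,
    min_group: int = 5,
    extra_tests: list | None = None,
) -> SurvivalResult:
    """Kaplan-Meier per methylation group plus pairwise log-rank tests.

    Only high-confidence patients are modeled. All adjacent and low-high
    group pairs with >= ``min_group`` samples and >= 1 event each are
    tested; BH is applied across every test in the invocation
    (``extra_tests`` lets a pan-cohort caller pool p-values from other
    cohorts into the same family).
    """
    df = _hc_survival_frame(samples, grouping, hc_mask)
    groups = sorted(df["group"].unique(), key=lambda g: _GROUP_ORDER.get(g, 99))
    curves, notes = {}, []
    for g in groups:
        sub = df[df["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["survival_time"], sub["event"], label=g)
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf[g].to_numpy()})

    pvals = {}
    for g1, g2 in combinations(groups, 2):
        a, b = df[df["group"] == g1], df[df["group"] == g2]
        if len(a) < min_group or len(b) < min_group:
            notes.append(f"log-rank {g1}-{g2} skipped: group below {min_group} HC samples")
            continue
        if a["event"].sum() == 0 or b["event"].sum() == 0:
            notes.append(f"log-rank {g1}-{g2} skipped: a group has zero events")
            continue
        res = logrank_test(
            a["survival_time"], b["survival_time"], a["event"], b["event"]
        )
        pvals[(g1, g2)] = float(res.p_value)

    all_p = list(pvals.values()) + list(extra_tests or [])
    qmap = {}
    if all_p:
        q = multipletests(all_p, method="fdr_bh")[1]
        qmap = {pair: float(q[i]) for i, pair in enumerate(pvals)}
    return SurvivalResult(km_curves=curves, logrank_p=pvals, logrank_q=qmap, notes=notes)


def cox_fit(
    samples: pd.DataFrame,
    grouping,
    hc_mask: pd.Series,
    covariates: tuple[str, ...] = ("age", "gender", "stage"),
    min_samples: int = 20,
) -> SurvivalResult:
    """Cox proportional-hazards model of group effect with clinical
    covariates.

    The low group is the baseline; indicator covariates mark the high
    (and intermediate) groups. Stage is encoded ordinally, gender 0/1;
    covariates missing from the table, or single-valued (e.g. gender in a
    single-sex cohort), are dropped with a note. Wald p-values are
    reported uncorrected.
    """
    df = _hc_survival_frame(samples, grouping, hc_mask)
    if len(df) < min_samples:
        raise ValueError(f"need >= {min_samples} high-confidence samples for the Cox model")
    notes = []
    X = pd.DataFrame(index=df.index)
    for g in sorted(df["group"].unique(), key=lambda g: _GROUP_ORDER.get(g, 99)):
        if g == "low":
            continue
        X[f"group_{g}"] = (df["group"] == g).astype(float)
    for cov in covariates:
        if cov not in samples.columns:
            notes.append(f"covariate {cov!r} not in the clinical table, omitted")
            continue
        col = samples.loc[df.index, cov]
        if cov == "gender":
            levels = sorted(col.dropna().unique())
            if len(levels) < 2:
                notes.append("gender single-valued, omitted")
                continue
            X[cov] = (col == levels[-1]).astype(float)
        elif cov == "stage":
            levels = sorted(col.dropna().unique())
            if len(levels) < 2:
                notes.append("stage single-valued, omitted")
                continue
            X[cov] = col.map({s: i for i, s in enumerate(levels)}).astype(float)
        else:
            if col.dropna().nunique() < 2:
                notes.append(f"covariate {cov!r} single-valued, omitted")
                continue
            X[cov] = col.astype(float)
    n_events = int(df["event"].sum())
    if n_events < 5 * X.shape[1]:
        msg = f"only {n_events} events for {X.shape[1]} covariates (< 5 per covariate)"
        notes.append(msg)
        logger.warning(msg)

    fit_df = pd.concat([df[["survival_time", "event"]], X], axis=1).dropna()
    cph = CoxPHFitter()
    try:
        cph.fit(fit_df, duration_col="survival_time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    summ = cph.summary[["exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]].copy()
    summ.columns = ["hr", "ci_lower", "ci_upper", "wald_p"]
    return SurvivalResult(km_curves={}, cox_summary=summ, notes=notes)


def abac(y_true, y_pred) -> float:
    """Adjusted balanced accuracy: mean per-class recall rescaled so that
    chance level maps to 0 and a perfect prediction to 1,
    ``(BA - 1/C) / (1 - 1/C)`` for C classes present in ``y_true``."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("adjusted balanced accuracy needs >= 2 classes in y_true")
    return float(balanced_accuracy_score(y_true, np.asarray(y_pred), adjusted=True))


def _cv_abac(X: np.ndarray, y: np.ndarray, n_splits: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        clf = LogisticRegression(class_weight="balanced", max_iter=1000)
        clf.fit(X[tr], y[tr])
        scores.append(abac(y[te], clf.predict(X[te])))
    return float(np.mean(scores))


def select_probe_panel(
    beta: pd.DataFrame,
    grouping,
    cimp_positive_labels: pd.Series | None = None,
    max_probes: int = 5,
    seed: int = 0,
    test_size: float = 0.10,
    n_splits: int = 5,
    max_candidates: int = 100,
) -> ProbePanel:
    """Minimal diagnostic probe panel by sequential forward selection.

    Candidate features are the DMP set (capped at ``max_candidates``
    probes ranked by |mean(high) - mean(low)| for tractability). After a
    stratified seeded 90/10 train/test split, SFS greedily adds the probe
    maximizing mean stratified 5-fold CV adjusted balanced accuracy of a
    balanced-class-weight logistic regression, stopping at ``max_probes``
    or when no addition improves the CV score. The final model is refit
    on the whole training split and scored once on the held-out 10%.

    ``cimp_positive_labels`` may supply the binary target (e.g. per-sample
    CIMP status); by default the high group vs the rest is predicted.
    """
    import hashlib

    if not grouping.dmp_set:
        raise ValueError("empty DMP set: no candidate probes")
    if cimp_positive_labels is None:
        y_all = (grouping.group_of_sample == "high").astype(int)
    else:
        y_all = cimp_positive_labels.astype(int)
    y_all = y_all.loc[beta.columns]
    counts = y_all.value_counts()
    if counts.min() < 10 or len(counts) < 2:
        raise ValueError("both classes need >= 10 samples for panel selection")

    dmps = [p for p in grouping.dmp_set if p in beta.index]
    sub = beta.loc[dmps]
    if len(dmps) > max_candidates:
        hi = sub[y_all.index[y_all == 1]].mean(axis=1)
        lo = sub[y_all.index[y_all == 0]].mean(axis=1)
        dmps = list((hi - lo).abs().sort_values(ascending=False).index[:max_candidates])
        sub = beta.loc[dmps]

    X_all = sub.to_numpy(dtype=float).T
    y_vec = y_all.to_numpy()
    idx = np.arange(len(y_vec))
    tr_idx, te_idx = train_test_split(
        idx, test_size=test_size, stratify=y_vec, random_state=int(seed) % (2**31)
    )
    if len(np.unique(y_vec[tr_idx])) < 2:
        raise ValueError("a class is absent from the training split")
    checksum = hashlib.sha256(np.sort(tr_idx).astype(np.int64).tobytes()).hexdigest()

    Xtr, ytr = X_all[tr_idx], y_vec[tr_idx]
    panel: list[int] = []
    best_score = -np.inf
    cv_seed = (int(seed) + 1) % (2**31)
    for _ in range(max_probes):
        best_gain, best_j, best_cand_score = 0.0, None, best_score
        for j in range(len(dmps)):
            if j in panel:
                continue
            score = _cv_abac(Xtr[:, panel + [j]], ytr, n_splits, cv_seed)
            if score > best_cand_score + 1e-12:
                best_cand_score, best_j = score, j
        if best_j is None:
            break
        panel.append(best_j)
        best_score = best_cand_score
        if best_score >= 1.0:
            break

    clf = LogisticRegression(class_weight="balanced", max_iter=1000)
    clf.fit(Xtr[:, panel], ytr)
    test_score = abac(y_vec[te_idx], clf.predict(X_all[te_idx][:, panel]))
    coef = pd.Series(clf.coef_.ravel(), index=[dmps[j] for j in panel])
    coef["intercept"] = float(clf.intercept_[0])
    return ProbePanel(
        probes=[dmps[j] for j in panel],
        cv_abac=float(best_score),
        test_abac=float(test_score),
        coefficients=coef,
        train_index_checksum=checksum,
    )
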