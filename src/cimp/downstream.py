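"""Downstream transcriptional targets of CIMP, gene-set enrichment via
the EASE score, and tumor-microenvironment associations.

A gene is a putative CIMP downstream target when it is differentially
expressed between the high- and low-methylation groups (pluggable test;
rank-sum + BH by default) *and* carries at least one annotated probe
hypermethylated by more than 0.10 beta in the high group. Target sets are
tested against GMT gene-set collections with the EASE score — a one-sided
Fisher's exact test with the overlap decremented by one, a deliberately
conservative variant. Immune structure is assessed by Fisher enrichment
of categorical subtypes in the high vs low group and Spearman correlation
of continuous signatures with the CIMP score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "default_de_test",
    "select_downstream_targets",
    "ease_enrichment",
    "immune_association",
]


@dataclass
class GeneSetCollection:
    sets: dict  # name -> set of gene symbols
    background: set = field(default_factory=set)

    def harmonize(self) -> "GeneSetCollection":
        """Intersect every set with the background; drop emptied sets."""
        out = {}
        for name, genes in self.sets.items():
            g = set(genes) & self.background
            if g:
                out[name] = g
            else:
                logger.info("gene set %r empty after harmonization, dropped", name)
        return GeneSetCollection(sets=out, background=set(self.background))


def read_gmt(path, background: set | None = None) -> GeneSetCollection:
    """Read a GMT file (set name, description, tab-separated symbols)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    bg = background if background is not None else set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, background=set(bg))


def default_de_test(expression: pd.DataFrame, group: pd.Series) -> pd.DataFrame:
    """Rank-sum (Mann-Whitney U) differential expression, high vs low
    group, BH-corrected. Returns gene-indexed columns ``p`` and ``q``."""
    hi = group.index[group == "high"].intersection(expression.columns)
    lo = group.index[group == "low"].intersection(expression.columns)
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("need >= 2 samples per group for the rank-sum test")
    A = expression[hi].to_numpy(dtype=float)
    B = expression[lo].to_numpy(dtype=float)
    pvals = np.ones(expression.shape[0])
    for i in range(expression.shape[0]):
        if np.ptp(np.concatenate([A[i], B[i]])) == 0:
            continue
        pvals[i] = stats.mannwhitneyu(A[i], B[i], alternative="two-sided").pvalue
    out = pd.DataFrame({"p": pvals}, index=expression.index)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def _probe_gene_map(ann: pd.DataFrame) -> pd.DataFrame:
    """Long-form probe -> gene pairs; semicolon-annotated probes
    contribute to each listed gene (450k-manifest convention)."""
    rows = []
    for probe, cell in ann["gene"].items():
        if not isinstance(cell, str) or not cell:
            continue
        for g in cell.split(";"):
            g = g.strip()
            if g:
                rows.append((probe, g))
    if not rows:
        raise ValueError("no probe-gene mapping available in the annotation")
    return pd.DataFrame(rows, columns=["probe_id", "gene"])


def select_downstream_targets(
    expression: pd.DataFrame,
    beta: pd.DataFrame,
    grouping,
    ann: pd.DataFrame,
    de_test=None,
    de_q: float = 0.05,
    probe_delta: float = 0.10,
) -> pd.DataFrame:
    """Genes both differentially expressed and hypermethylated in the
    high group.

    DE evidence: BH q < ``de_q`` from ``de_test`` (any direction).
    Methylation evidence: >= 1 annotated probe with mean(high) -
    mean(low) beta exceeding ``probe_delta``. Returns the target genes
    with their evidence (``de_q``, ``max_probe_delta``).
    """
    group = grouping.group_of_sample
    shared = expression.columns.intersection(beta.columns)
    if shared.empty:
        raise ValueError("expression and beta matrices share no samples")
    de = (de_test or default_de_test)(expression[shared], group.loc[shared])

    pg = _probe_gene_map(ann.loc[ann.index.intersection(beta.index)])
    hi = group.index[group == "high"].intersection(beta.columns)
    lo = group.index[group == "low"].intersection(beta.columns)
    delta = (beta[hi].mean(axis=1) - beta[lo].mean(axis=1)).rename("delta")
    pg = pg[pg["probe_id"].isin(delta.index)]
    pg["delta"] = delta.loc[pg["probe_id"]].to_numpy()
    max_delta = pg.groupby("gene")["delta"].max()

    genes = sorted(
        set(de.index[de["q"] < de_q])
        & set(max_delta.index[max_delta > probe_delta])
    )
    return pd.DataFrame(
        {
            "gene": genes,
            "de_q": de.loc[genes, "q"].to_numpy(),
            "max_probe_delta": max_delta.loc[genes].to_numpy(),
        }
    ).set_index("gene")


def ease_enrichment(targets: set, collection: GeneSetCollection) -> pd.DataFrame:
    """EASE-score gene-set enrichment.

    For each set the one-sided Fisher (enrichment direction) p-value is
    computed on the 2x2 table with the target/set overlap decremented by
    one (floored at 0) — the jackknifed Fisher variant used by annotation
    tools; BH across sets. An overlap of 0 or 1 therefore yields p = 1.
    """
    if not collection.background:
        raise ValueError("empty gene-set background")
    coll = collection.harmonize()
    targets_bg = set(targets) & coll.background
    dropped = len(set(targets)) - len(targets_bg)
    if dropped:
        logger.info("%d target genes outside the background dropped", dropped)
    M = len(coll.background)
    n_list = len(targets_bg)
    records = []
    for name, geneset in coll.sets.items():
        K = len(geneset)
        overlap = len(targets_bg & geneset)
        a = max(overlap - 1, 0)
        # P(X >= a) for X ~ Hypergeom(M, K, n_list)
        p = float(stats.hypergeom.sf(a - 1, M, K, n_list)) if a > 0 else 1.0
        records.append(
            {
                "unit": name,
                "overlap": overlap,
                "set_size": K,
                "list_size": n_list,
                "background": M,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(records)
    if out.empty:
        return out
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.set_index("unit")


def immune_association(
    cimp_score: pd.Series,
    grouping,
    immune: pd.DataFrame,
    subtype_col: str = "immune_subtype",
    alpha_q: float = 0.05,
) -> pd.DataFrame:
    """Immune subtype enrichment and signature correlations.

    Categorical subtypes: per subtype, Fisher's exact test of (subtype vs
    other) x (high vs low group), BH across subtypes. Continuous columns:
    Spearman rho of the CIMP score against each signature / cell-fraction
    column (t-test p), BH across columns. Significance at q < ``alpha_q``.
    Constant columns are excluded (logged).
    """
    group = grouping.group_of_sample
    shared = group.index.intersection(immune.index)
    records = []

    if subtype_col in immune.columns:
        sub = immune.loc[shared, subtype_col]
        hi = group.loc[shared] == "high"
        lo = group.loc[shared] == "low"
        sub_pvals = []
        for st in sorted(sub.dropna().unique()):
            is_st = sub == st
            table = [
                [int((is_st & hi).sum()), int((~is_st & hi).sum())],
                [int((is_st & lo).sum()), int((~is_st & lo).sum())],
            ]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            sub_pvals.append({"unit": st, "kind": "subtype", "effect": float(odds), "p": float(p)})
        if sub_pvals:
            q = multipletests([r["p"] for r in sub_pvals], method="fdr_bh")[1]
            for r, qi in zip(sub_pvals, q):
                r["q"] = float(qi)
            records.extend(sub_pvals)

    score = cimp_score.loc[shared]
    cont_records = []
    for col in immune.columns:
        if col == subtype_col or not pd.api.types.is_numeric_dtype(immune[col]):
            continue
        vals = immune.loc[shared, col]
        if vals.dropna().nunique() < 2:
            logger.info("immune column %r constant, excluded", col)
            continue
        ok = vals.notna() & score.notna()
        rho, p = stats.spearmanr(score[ok], vals[ok])
        cont_records.append({"unit": col, "kind": "signature", "effect": float(rho), "p": float(p)})
    if cont_records:
        q = multipletests([r["p"] for r in cont_records], method="fdr_bh")[1]
        for r, qi in zip(cont_records, q):
            r["q"] = float(qi)
        records.extend(cont_records)

    out = pd.DataFrame(records)
    if not out.empty:
        out["significant"] = out["q"] < alpha_q
        out = out.set_index("unit")
    return out
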