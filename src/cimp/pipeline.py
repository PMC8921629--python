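"""End-to-end orchestration: preprocess -> cluster -> drivers ->
clinical -> downstream for one cohort, with input validation and a
deterministic run summary.

Every random draw descends from the single configured seed; two runs
with equal configuration produce byte-identical TSV/JSON outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import preprocess as pp
from . import cluster as cl
from . import drivers as dr
from . import clinical as cn
from . import downstream as ds

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and toggles of one pipeline run.

    Threshold defaults: CIMP high-low delta 0.20, mutation frequency gate
    0.10, downstream probe delta 0.10, alpha 0.05 (q < 0.1 for the
    CIMP-score/mutation correlation). The 0.20 CIMP cutoff is exposed so
    sensitivity analyses are one-flag experiments.
    """

    beta: str = ""
    manifest: str = ""
    clinical: str = ""
    normal_ref: str = ""
    mutations: str = ""
    expression: str = ""
    immune: str = ""
    gmt: str = ""
    blacklist: str = ""

    cimp_delta: float = 0.20
    freq_gate: float = 0.10
    probe_delta: float = 0.10
    alpha: float = 0.05
    score_corr_q: float = 0.10
    k: str = "auto"  # "2", "3" or "auto"
    n_consensus_runs: int = 10
    n_neighbors: int = 10
    msi_mode: bool = False
    n_perm: int = 2000
    rf_label_perm: int = 30
    rf_trees: int = 200
    seed: int = 0

    stages: tuple[str, ...] = ("preprocess", "cluster", "drivers", "clinical", "downstream")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["stages"] = list(d["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def validate_inputs(paths: dict) -> list[dict]:
    """Check formats and cross-table concordance; returns an issue list
    (``level`` fatal/warning, ``message``)."""
    issues = []

    def fatal(msg):
        issues.append({"level": "fatal", "message": msg})

    def warn(msg):
        issues.append({"level": "warning", "message": msg})

    beta = ann = clin = None
    for key in ("beta", "manifest", "clinical"):
        p = paths.get(key)
        if p and not Path(p).exists():
            fatal(f"{key} file not found: {p}")
    try:
        if paths.get("beta"):
            beta = cio.read_beta(paths["beta"])
    except Exception as exc:
        fatal(f"beta: {exc}")
    try:
        if paths.get("manifest"):
            ann = cio.read_manifest(paths["manifest"])
    except Exception as exc:
        fatal(f"manifest: {exc}")
    try:
        if paths.get("clinical"):
            clin = cio.read_clinical(paths["clinical"])
    except Exception as exc:
        fatal(f"clinical: {exc}")

    if beta is not None and ann is not None:
        missing = beta.index.difference(ann.index)
        if len(missing):
            fatal(f"{len(missing)} beta probes missing from the manifest, e.g. {missing[0]!r}")
    if beta is not None and clin is not None:
        missing = beta.columns.difference(clin.index)
        if len(missing):
            warn(f"{len(missing)} beta samples missing from the clinical table: {list(missing[:5])}")
    return issues


def _run_cohort(config: PipelineConfig, out: Path, tracker: list | None = None) -> dict:
    tracker = tracker if tracker is not None else ["setup"]
    beta = cio.read_beta(config.beta)
    ann = cio.read_manifest(config.manifest)
    clin = cio.read_clinical(config.clinical)
    normal_ref = cio.read_normal_ref(config.normal_ref) if config.normal_ref else None
    blacklist = cio.read_blacklist(config.blacklist) if config.blacklist else set()

    summary: dict = {"seed": config.seed}

    tracker[0] = "preprocess"
    filtered, fstats = pp.preprocess_pipeline(
        [beta], [ann], [clin],
        [normal_ref if normal_ref is not None else beta.mean(axis=1)],
        blacklist=blacklist, seed=config.seed,
    )
    beta_f = filtered[0]
    fstats.to_frame().to_csv(out / "filter_stats.tsv", sep="\t", index=False)
    summary["filters"] = {
        "input_probes": fstats.n_input,
        "after_context_na_sex": fstats.n_after_context,
        "after_nonvariable": fstats.n_after_nonvariable,
        "after_age_gender": fstats.n_after_age_gender,
    }
    if "preprocess" == config.stages[-1]:
        return summary

    tracker[0] = "cluster"
    if config.k == "auto":
        k, cres, grouping = cl.select_k(
            beta_f, seed=config.seed, n_runs=config.n_consensus_runs,
            n_neighbors=config.n_neighbors,
        )
    else:
        k = int(config.k)
        cres = cl.consensus_spectral(
            beta_f, k=k, n_runs=config.n_consensus_runs, seed=config.seed,
            n_neighbors=config.n_neighbors,
        )
        dmp, kw_p = cl.detect_dmps(beta_f, cres.labels, alpha=config.alpha)
        grouping = cl.assign_groups(beta_f, cres.labels, dmp, kw_p)

    call = cl.call_cimp(
        grouping, beta_f, normal_ref=normal_ref,
        delta_threshold=config.cimp_delta, alpha=config.alpha,
    )
    groups_tab = pd.DataFrame(
        {
            "sample_id": grouping.group_of_sample.index,
            "cluster": grouping.cluster_of_sample.to_numpy(),
            "group": grouping.group_of_sample.to_numpy(),
            "ssc": cres.ssc.to_numpy(),
            "hc": cres.hc_mask.astype(int).to_numpy(),
            "cimp_score": call.cimp_score.reindex(grouping.group_of_sample.index).to_numpy(),
        }
    )
    groups_tab.to_csv(out / "groups.tsv", sep="\t", index=False)
    with open(out / "dmps.txt", "w") as fh:
        fh.write("\n".join(grouping.dmp_set) + "\n")
    cio.write_json(
        {
            "status": call.status,
            "delta_high_low": round(call.delta_high_low, 10),
            "kw_group_p": call.kw_group_p,
            "hypo_fraction": call.hypo_fraction,
            "delta_high_normal": call.delta_high_normal,
            "k": k,
            "n_dmps": len(grouping.dmp_set),
        },
        out / "cimp_call.json",
    )
    summary["cimp"] = {
        "status": call.status,
        "delta_high_low": round(call.delta_high_low, 10),
        "kw_group_p": call.kw_group_p,
        "hypo_fraction": call.hypo_fraction,
        "k": k,
        "n_dmps": len(grouping.dmp_set),
        "score_quantiles": {
            q: round(float(call.cimp_score.quantile(q)), 10) for q in (0.25, 0.5, 0.75)
        },
    }

    tracker[0] = "drivers"
    if "drivers" in config.stages and config.mutations:
        mut = cio.read_mutations(config.mutations)
        fisher = dr.fisher_enrichment(
            mut, grouping, cres.hc_mask, freq_gate=config.freq_gate, alpha=config.alpha,
        )
        corr = dr.score_mutation_correlation(call.cimp_score, mut, sig_q=config.score_corr_q)
        enrichment = fisher.copy()
        if config.msi_mode:
            emp = dr.msi_empirical_p(
                mut, grouping, cres.hc_mask, n_perm=config.n_perm, seed=config.seed,
            )
            enrichment = enrichment.join(emp[["empirical_p"]], how="left")
        enrichment.to_csv(out / "enrichment.tsv", sep="\t")
        corr.to_csv(out / "score_correlation.tsv", sep="\t")
        rf = dr.rf_screen(
            mut, grouping, cres.hc_mask, n_trees=config.rf_trees,
            n_label_perm=config.rf_label_perm, seed=config.seed,
        )
        cio.write_json(
            {
                "passed": rf["passed"],
                "selected_genes": rf["selected_genes"],
                "cv_balanced_accuracy": rf["cv_balanced_accuracy"],
                "null_q95": rf["null_q95"],
            },
            out / "rf_screen.json",
        )
        summary["drivers"] = {
            "reported": sorted(fisher.index[fisher["reported"]]),
            "rf_passed": rf["passed"],
            "rf_selected": rf["selected_genes"],
            "score_corr_significant": sorted(corr.index[corr["significant"]]) if not corr.empty else [],
        }
    elif "drivers" in config.stages:
        raise FileNotFoundError("drivers stage enabled but no mutations file configured")

    tracker[0] = "clinical"
    if "clinical" in config.stages and {"survival_time", "event"} <= set(clin.columns):
        surv = cn.km_logrank(clin, grouping, cres.hc_mask)
        cox = None
        try:
            cox = cn.cox_fit(clin, grouping, cres.hc_mask)
        except (ValueError, RuntimeError) as exc:
            logger.warning("Cox model skipped: %s", exc)
        panel = cn.select_probe_panel(beta_f, grouping, seed=config.seed)
        cio.write_json(
            {
                "km_curves": {
                    g: {"time": c["time"].tolist(), "survival": c["survival"].tolist()}
                    for g, c in surv.km_curves.items()
                },
                "logrank_p": {f"{a}-{b}": p for (a, b), p in surv.logrank_p.items()},
                "logrank_q": {f"{a}-{b}": q for (a, b), q in surv.logrank_q.items()},
                "cox": cox.cox_summary.to_dict() if cox is not None else None,
            },
            out / "survival.json",
        )
        cio.write_json(
            {
                "probes": panel.probes,
                "cv_abac": panel.cv_abac,
                "test_abac": panel.test_abac,
                "coefficients": panel.coefficients.to_dict(),
            },
            out / "panel.json",
        )
        summary["clinical"] = {
            "logrank_q": {f"{a}-{b}": q for (a, b), q in surv.logrank_q.items()},
            "cox_hr_high": (
                round(float(cox.cox_summary.loc["group_high", "hr"]), 10)
                if cox is not None and "group_high" in cox.cox_summary.index
                else None
            ),
            "panel": panel.probes,
            "panel_cv_abac": panel.cv_abac,
            "panel_test_abac": panel.test_abac,
        }

    tracker[0] = "downstream"
    if "downstream" in config.stages and config.expression:
        expr = cio.read_matrix(config.expression)
        targets = ds.select_downstream_targets(
            expr, beta_f, grouping, ann, de_q=config.alpha, probe_delta=config.probe_delta,
        )
        with open(out / "targets.txt", "w") as fh:
            fh.write("\n".join(targets.index) + "\n")
        summary["downstream"] = {"n_targets": int(len(targets))}
        if config.gmt:
            coll = ds.read_gmt(config.gmt)
            ease = ds.ease_enrichment(set(targets.index), coll)
            ease.to_csv(out / "ease.tsv", sep="\t")
            summary["downstream"]["ease_significant"] = (
                sorted(ease.index[ease["q"] < config.alpha]) if not ease.empty else []
            )
        if config.immune:
            imm = cio.read_matrix(config.immune)
            assoc = ds.immune_association(call.cimp_score, grouping, imm, alpha_q=config.alpha)
            assoc.to_csv(out / "immune.tsv", sep="\t")
            summary["downstream"]["immune_significant"] = (
                sorted(assoc.index[assoc["significant"]]) if not assoc.empty else []
            )
    return summary


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the configured stages; write per-stage outputs plus
    ``summary.json``. Stage failures abort with the stage named; outputs
    written before the failure are retained."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key in ("beta", "manifest", "clinical"):
        p = getattr(config, key)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"required input {key!r} missing: {p!r}")
    if "drivers" in config.stages and config.mutations and not Path(config.mutations).exists():
        raise FileNotFoundError(f"mutations file not found: {config.mutations}")
    tracker = ["setup"]
    try:
        summary = _run_cohort(config, out, tracker)
    except Exception as exc:
        raise RuntimeError(f"stage {tracker[0]!r} failed: {exc}") from exc
    cio.write_json(summary, out / "summary.json")
    return out
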