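"""Synthetic methylation cohorts with known ground truth.

Generates pan-cancer-like inputs — a beta-value matrix with CpG-island
context structure, a planted hypermethylated (CIMP) sample subset, tumor
purity mixing against a normal reference, age/gender-associated probes,
driver mutations, group-dependent survival, methylation-repressed gene
expression and immune covariates — so that every downstream stage of the
pipeline has a parameter-recovery test that needs no external download.

The central contract: ``simulate_cohort`` returns both the observed data
and a :class:`GroundTruth` recording exactly what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_multi_cohort",
    "simulate_survival",
    "simulate_expression",
    "simulate_immune",
    "write_cohort",
]

#: CGI-relation vocabulary used by Illumina-style manifests.
CGI_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: Tumor-microenvironment subtype labels used for the categorical immune covariate.
IMMUNE_SUBTYPES = (
    "wound_healing",
    "ifn_gamma_dominant",
    "inflammatory",
    "lymphocyte_depleted",
    "immunologically_quiet",
    "tgf_beta_dominant",
)

# Per-stream offsets so each generator draws from an independent stream
# derived from the one user-facing seed.
_STREAM_COHORT = 0
_STREAM_SURVIVAL = 1
_STREAM_EXPRESSION = 2
_STREAM_IMMUNE = 3
_STREAM_PROBES = 4  # probe roles + manifest, shared across cohorts


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Defaults describe a mid-sized cancer cohort with a clearly planted
    CIMP subset: 200 tumors, 5000 probes, 40% CIMP samples carrying a
    +0.30 beta shift on 10% of probes, beta-scale noise SD 0.05 and tumor
    purity uniform on [0.4, 0.95].
    """

    n_samples: int = 200
    n_probes: int = 5000
    frac_cimp_samples: float = 0.4
    frac_informative_probes: float = 0.10
    delta_beta: float = 0.30
    frac_nonvariable_probes: float = 0.30
    noise_sd: float = 0.05
    purity_range: tuple[float, float] = (0.4, 0.95)
    n_age_probes: int = 100
    age_effect: float = 0.05  # beta units per decade of age
    n_cohorts: int = 1
    driver_genes: Sequence[tuple[str, float, float]] = (("IDH1", 0.05, 0.80),)
    background_genes: int = 50
    background_mut_rate: float = 0.10
    msi_mode: bool = False
    msi_burden_multiplier: float = 5.0
    hazard_ratio_high: float = 3.0
    baseline_hazard: float = 0.1  # events per time unit in the low group
    censor_rate: float = 0.2
    n_repressed_genes: int = 20
    expression_fold: float = 0.5  # fold-change of repressed genes in the high group
    seed: int = 0

    # structural fractions for probes exercising the context/NA filters
    frac_sex_probes: float = 0.02
    frac_opensea_probes: float = 0.05
    frac_na_probes: float = 0.01
    nonvariable_noise_sd: float = 0.003
    # biological sample-to-sample variability of variable probes (SD range
    # on the beta scale, drawn per probe); keeps the SD distribution
    # bimodal so the k-means variance filter separates the regimes
    bio_sd_range: tuple[float, float] = (0.08, 0.12)

    def validate(self) -> None:
        fracs = {
            "frac_cimp_samples": self.frac_cimp_samples,
            "frac_informative_probes": self.frac_informative_probes,
            "frac_nonvariable_probes": self.frac_nonvariable_probes,
            "censor_rate": self.censor_rate,
            "background_mut_rate": self.background_mut_rate,
            "delta_beta": self.delta_beta,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"purity_range must satisfy 0 < lo <= hi <= 1, got {self.purity_range}")
        if self.hazard_ratio_high <= 0:
            raise ValueError("hazard_ratio_high must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.n_samples < 20:
            raise ValueError("n_samples must be >= 20")
        if round(self.n_samples * self.frac_cimp_samples) < 2:
            raise ValueError("planted CIMP group would have < 2 samples")


@dataclass
class GroundTruth:
    """What was planted in a synthetic cohort, for recovery tests."""

    group_of_sample: pd.Series  # "low" / "high" per sample
    informative_probes: set[str]
    nonvariable_probes: set[str]
    age_probes: set[str]
    shared_age_probes: set[str]  # age effect present in >= 2 cohorts
    single_age_probes: set[str]  # age effect present in exactly 1 cohort
    driver_genes: set[str]
    true_purity: pd.Series
    true_tumor_beta: pd.DataFrame
    normal_ref: pd.Series
    true_hr: float
    repressed_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        sets = [self.informative_probes, self.nonvariable_probes, self.age_probes]
        for i, a in enumerate(sets):
            for b in sets[i + 1 :]:
                if a & b:
                    raise ValueError("informative, nonvariable and age probe sets must be disjoint")

    @property
    def high_samples(self) -> pd.Index:
        return self.group_of_sample.index[self.group_of_sample == "high"]

    def to_json_dict(self) -> dict:
        return {
            "group_of_sample": self.group_of_sample.to_dict(),
            "informative_probes": sorted(self.informative_probes),
            "nonvariable_probes": sorted(self.nonvariable_probes),
            "age_probes": sorted(self.age_probes),
            "shared_age_probes": sorted(self.shared_age_probes),
            "single_age_probes": sorted(self.single_age_probes),
            "driver_genes": sorted(self.driver_genes),
            "true_purity": self.true_purity.to_dict(),
            "true_hr": self.true_hr,
            "repressed_genes": sorted(self.repressed_genes),
        }


def _rng(config: SimulationConfig, stream: int, extra: int = 0) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng([int(config.seed), stream, extra])


def _truncnorm(rng: np.random.Generator, loc, scale, size) -> np.ndarray:
    """Gaussian noise clipped to keep betas in [0,1]; clipping happens at the end."""
    return rng.normal(loc, scale, size)


def _partition_probes(config: SimulationConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Assign probe indices to structural roles, pairwise disjoint."""
    n = config.n_probes
    n_info = int(round(n * config.frac_informative_probes))
    n_nonvar = int(round(n * config.frac_nonvariable_probes))
    n_age = config.n_age_probes
    n_sex = int(round(n * config.frac_sex_probes))
    n_sea = int(round(n * config.frac_opensea_probes))
    n_na = int(round(n * config.frac_na_probes))
    if n_info + n_nonvar + n_age + n_sex + n_sea + n_na > n:
        raise ValueError("probe role fractions exceed the number of probes")
    perm = rng.permutation(n)
    out, start = {}, 0
    for name, count in [
        ("informative", n_info),
        ("nonvariable", n_nonvar),
        ("age", n_age),
        ("sex", n_sex),
        ("opensea", n_sea),
        ("na", n_na),
    ]:
        out[name] = np.sort(perm[start : start + count])
        start += count
    out["background"] = np.sort(perm[start:])
    return out


def _make_annotation(
    probe_ids: pd.Index, roles: dict[str, np.ndarray], rng: np.random.Generator
) -> pd.DataFrame:
    n = len(probe_ids)
    chroms = np.array([f"chr{1 + (i % 22)}" for i in range(n)], dtype=object)
    chroms[roles["sex"]] = rng.choice(["chrX", "chrY"], size=len(roles["sex"]))
    relation = rng.choice(CGI_RELATIONS[:5], size=n, p=[0.6, 0.1, 0.1, 0.1, 0.1]).astype(object)
    relation[roles["opensea"]] = "OpenSea"
    # informative probes anchored on CpG islands; each maps to a target gene
    relation[roles["informative"]] = "Island"
    genes = np.array([""] * n, dtype=object)
    genes[roles["informative"]] = [f"TG{j:04d}" for j in range(len(roles["informative"]))]
    genes[roles["background"]] = [f"BGG{j:04d}" for j in range(len(roles["background"]))]
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chr": chroms,
            "pos": np.arange(1, n + 1) * 1000,
            "relation_to_island": relation,
            "gene": genes,
        }
    ).set_index("probe_id", drop=False)


def simulate_cohort(
    config: SimulationConfig,
    *,
    cohort_label: str = "C0",
    cohort_index: int = 0,
    age_effect_mask: np.ndarray | None = None,
):
    """Generate one cohort: beta matrix, probe annotation, sample table,
    mutation matrix and ground truth.

    Observed betas follow the two-component mixture
    ``observed = purity * tumor + (1 - purity) * normal_ref`` clipped to
    [0,1], where the tumor signal carries the planted CIMP shift
    (+``delta_beta`` on informative probes for CIMP samples), the age
    effect and truncated-Gaussian noise.

    ``age_effect_mask`` (boolean over age probes) switches the age slope
    on or off per probe; it is used by :func:`simulate_multi_cohort` to
    plant probes that are age-associated in some cohorts but not others.
    """
    config.validate()
    rng = _rng(config, _STREAM_COHORT, cohort_index)

    n, p = config.n_samples, config.n_probes
    probe_ids = pd.Index([f"cg{i:07d}" for i in range(p)], name="probe_id")
    sample_ids = pd.Index([f"{cohort_label}S{i:04d}" for i in range(n)], name="sample_id")

    # probe roles and manifest come from a cohort-independent stream so that
    # multi-cohort simulations share one probe space and one annotation
    probe_rng = _rng(config, _STREAM_PROBES)
    roles = _partition_probes(config, probe_rng)
    ann = _make_annotation(probe_ids, roles, probe_rng)

    # planted CIMP membership
    n_high = int(round(n * config.frac_cimp_samples))
    high_idx = rng.choice(n, size=n_high, replace=False)
    group = np.array(["low"] * n, dtype=object)
    group[high_idx] = "high"
    group_s = pd.Series(group, index=sample_ids, name="group")

    # per-probe baseline means: bimodal for generic probes, low plateau for
    # informative probes so the +delta shift stays inside [0,1]
    base = np.empty(p)
    mix = rng.choice([0, 1, 2], size=p, p=[0.4, 0.2, 0.4])
    base[mix == 0] = rng.normal(0.10, 0.03, (mix == 0).sum())
    base[mix == 1] = rng.normal(0.50, 0.05, (mix == 1).sum())
    base[mix == 2] = rng.normal(0.80, 0.03, (mix == 2).sum())
    base[roles["informative"]] = rng.uniform(0.15, 0.35, len(roles["informative"]))
    base[roles["age"]] = rng.uniform(0.35, 0.55, len(roles["age"]))
    base = np.clip(base, 0.02, 0.98)

    # clinical covariates
    age = rng.uniform(30, 80, n)
    gender = rng.choice(["male", "female"], size=n)
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=[0.3, 0.3, 0.25, 0.15])
    purity = rng.uniform(config.purity_range[0], config.purity_range[1], n)

    # tumor signal: baseline + CIMP shift + age slope + noise
    tumor = np.tile(base[:, None], (1, n))
    is_high = group == "high"
    info = roles["informative"]
    tumor[np.ix_(info, np.where(is_high)[0])] += config.delta_beta

    if age_effect_mask is None:
        age_effect_mask = np.ones(len(roles["age"]), dtype=bool)
    active_age = roles["age"][age_effect_mask]
    tumor[active_age, :] += config.age_effect * (age[None, :] - 55.0) / 10.0

    noise = _truncnorm(rng, 0.0, config.noise_sd, (p, n))
    noise[roles["nonvariable"], :] = _truncnorm(
        rng, 0.0, config.nonvariable_noise_sd, (len(roles["nonvariable"]), n)
    )
    # biological heterogeneity: variable probes fluctuate between samples
    # beyond measurement noise (zero-mean, so group means are unaffected)
    bio_sd = rng.uniform(config.bio_sd_range[0], config.bio_sd_range[1], p)
    bio_sd[roles["nonvariable"]] = 0.0
    tumor = np.clip(tumor + noise + bio_sd[:, None] * rng.standard_normal((p, n)), 0.0, 1.0)

    # normal reference: probe baselines without CIMP or age effects
    normal_ref = pd.Series(base, index=probe_ids, name="normal_ref")

    observed = np.clip(purity[None, :] * tumor + (1.0 - purity[None, :]) * base[:, None], 0.0, 1.0)
    beta = pd.DataFrame(observed, index=probe_ids, columns=sample_ids)
    # plant missing values on the designated probes (one random sample each)
    for pi in roles["na"]:
        beta.iloc[pi, int(rng.integers(n))] = np.nan

    # MSI status: enriched in the planted high group when msi_mode is on
    if config.msi_mode:
        p_msi = np.where(is_high, 0.5, 0.1)
        msi = np.where(rng.random(n) < p_msi, "MSI-H", "MSS")
    else:
        msi = np.array(["MSS"] * n, dtype=object)

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": age,
            "gender": gender,
            "stage": stage,
            "purity": purity,
            "msi_status": msi,
            "cohort": cohort_label,
        }
    ).set_index("sample_id", drop=False)

    mutations = _simulate_mutations(config, rng, sample_ids, is_high, msi)

    truth = GroundTruth(
        group_of_sample=group_s,
        informative_probes=set(probe_ids[roles["informative"]]),
        nonvariable_probes=set(probe_ids[roles["nonvariable"]]),
        age_probes=set(probe_ids[roles["age"]]),
        shared_age_probes=set(probe_ids[active_age]),
        single_age_probes=set(),
        driver_genes={g for g, _, _ in config.driver_genes},
        true_purity=pd.Series(purity, index=sample_ids, name="purity"),
        true_tumor_beta=pd.DataFrame(tumor, index=probe_ids, columns=sample_ids),
        normal_ref=normal_ref,
        true_hr=config.hazard_ratio_high,
    )
    return beta, ann, samples, mutations, truth


def _simulate_mutations(
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_ids: pd.Index,
    is_high: np.ndarray,
    msi: np.ndarray,
) -> pd.DataFrame:
    """Binary gene x sample mutation indicators.

    Driver genes mutate at planted group-specific frequencies; background
    genes mutate at a flat rate, inflated by the burden multiplier for
    MSI-high samples — the hypermutator confound the burden-corrected
    empirical p-value is designed to remove.
    """
    n = len(sample_ids)
    rows, names = [], []
    for gene, f_low, f_high in config.driver_genes:
        prob = np.where(is_high, f_high, f_low)
        rows.append((rng.random(n) < prob).astype(np.int8))
        names.append(gene)
    burden_scale = np.where(msi == "MSI-H", config.msi_burden_multiplier, 1.0)
    bg_prob = np.clip(config.background_mut_rate * burden_scale, 0.0, 1.0)
    for j in range(config.background_genes):
        rows.append((rng.random(n) < bg_prob).astype(np.int8))
        names.append(f"BG{j:03d}")
    return pd.DataFrame(np.vstack(rows), index=pd.Index(names, name="gene"), columns=sample_ids)


def simulate_multi_cohort(config: SimulationConfig):
    """Generate ``config.n_cohorts`` cohorts sharing a probe space.

    Age probes are split in two: a *shared* half whose age slope is active
    in the first ``min(2, n_cohorts)`` cohorts (so the >=2-cohort filter
    rule must remove them) and a *single-cohort* half active only in
    cohort 0 (which the filter must retain).

    Returns lists (betas, annotations, sample tables, mutation matrices,
    truths), one entry per cohort; all truths agree on the probe-role sets.
    """
    if config.n_cohorts < 1:
        raise ValueError("n_cohorts must be >= 1")
    n_age = config.n_age_probes
    shared_mask = np.zeros(n_age, dtype=bool)
    shared_mask[: n_age // 2] = True

    betas, anns, samples, muts, truths = [], [], [], [], []
    n_shared_cohorts = min(2, config.n_cohorts)
    for j in range(config.n_cohorts):
        if j < n_shared_cohorts:
            mask = shared_mask.copy()
        else:
            mask = np.zeros(n_age, dtype=bool)
        if j == 0:  # single-cohort age probes live only here
            mask = mask | ~shared_mask
        b, a, s, m, t = simulate_cohort(
            config, cohort_label=f"C{j}", cohort_index=j, age_effect_mask=mask
        )
        betas.append(b)
        anns.append(a)
        samples.append(s)
        muts.append(m)
        truths.append(t)

    # recover the (cohort-independent) age-probe ordering to label the
    # shared vs single-cohort subsets on every truth object
    probe_ids = betas[0].index
    roles = _partition_probes(config, _rng(config, _STREAM_PROBES))
    shared_ids = set(probe_ids[roles["age"][shared_mask]])
    single_ids = set(probe_ids[roles["age"][~shared_mask]])
    for t in truths:
        t.shared_age_probes = shared_ids
        t.single_age_probes = single_ids
    return betas, anns, samples, muts, truths


def simulate_survival(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Exponential survival with a group-dependent hazard.

    Event times are exponential with rate ``baseline_hazard`` for the low
    group and ``baseline_hazard * true_hr`` for the planted high group.
    A ``censor_rate`` fraction of samples (independent Bernoulli draws) is
    right-censored at a uniform fraction of its event time.
    """
    config.validate()
    if config.baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    rng = _rng(config, _STREAM_SURVIVAL)
    group = truth.group_of_sample
    rate = np.where(group.to_numpy() == "high", config.baseline_hazard * truth.true_hr, config.baseline_hazard)
    t_event = rng.exponential(1.0 / rate)
    censored = rng.random(len(group)) < config.censor_rate
    t_obs = np.where(censored, t_event * rng.uniform(0, 1, len(group)), t_event)
    return pd.DataFrame(
        {"survival_time": t_obs, "event": (~censored).astype(int)}, index=group.index
    )


def simulate_expression(truth: GroundTruth, config: SimulationConfig, ann: pd.DataFrame) -> pd.DataFrame:
    """Gene x sample expression (log2 scale) with methylation-repressed genes.

    ``n_repressed_genes`` genes annotated to informative probes lose
    log2(1/fold) units of expression in the planted high group (2-fold
    down by default). The repressed gene set is recorded on the truth.
    """
    config.validate()
    rng = _rng(config, _STREAM_EXPRESSION)
    mapped = ann.loc[ann.index.isin(truth.informative_probes), "gene"]
    mapped_genes = sorted({g for cell in mapped if cell for g in str(cell).split(";")})
    if not mapped_genes:
        raise ValueError("no probe-gene mapping available for informative probes")
    if config.n_repressed_genes > len(mapped_genes):
        raise ValueError(
            f"n_repressed_genes={config.n_repressed_genes} exceeds the "
            f"{len(mapped_genes)} genes mapped to informative probes"
        )
    repressed = set(
        rng.choice(mapped_genes, size=config.n_repressed_genes, replace=False).tolist()
    )
    other = [f"EXG{j:04d}" for j in range(100)]
    genes = mapped_genes + other
    samples = truth.group_of_sample.index
    is_high = (truth.group_of_sample == "high").to_numpy()

    base = rng.uniform(4.0, 8.0, len(genes))
    expr = base[:, None] + rng.normal(0.0, 0.5, (len(genes), len(samples)))
    shift = np.log2(config.expression_fold)  # negative for repression
    for i, g in enumerate(genes):
        if g in repressed:
            expr[i, is_high] += shift
    truth.repressed_genes = repressed
    return pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)


def simulate_immune(
    truth: GroundTruth, config: SimulationConfig, signature_noise_sd: float = 0.1
) -> pd.DataFrame:
    """Immune covariates: one signature monotone in the planted
    hypermethylation level, one independent signature, and a categorical
    subtype enriched in the high group (the interferon-gamma-dominant
    label)."""
    config.validate()
    rng = _rng(config, _STREAM_IMMUNE)
    samples = truth.group_of_sample.index
    n = len(samples)
    is_high = (truth.group_of_sample == "high").to_numpy()

    # monotone in the tumor's informative-probe methylation, so it tracks
    # the continuous CIMP score rather than only the binary group label
    meth_level = (
        truth.true_tumor_beta.loc[sorted(truth.informative_probes)].mean(axis=0).to_numpy()
    )
    monotone = meth_level + rng.normal(0.0, signature_noise_sd, n)
    independent = rng.normal(0.0, 1.0, n)
    base_p = np.full(len(IMMUNE_SUBTYPES), 1.0 / len(IMMUNE_SUBTYPES))
    high_p = base_p.copy()
    high_p[IMMUNE_SUBTYPES.index("ifn_gamma_dominant")] = 0.6
    high_p /= high_p.sum()
    subtype = np.array(
        [
            rng.choice(IMMUNE_SUBTYPES, p=(high_p if h else base_p))
            for h in is_high
        ],
        dtype=object,
    )
    return pd.DataFrame(
        {
            "immune_subtype": subtype,
            "sig_monotone": monotone,
            "sig_independent": independent,
        },
        index=samples,
    )


def write_cohort(out_dir, beta, ann, samples, mutations, truth, expression=None, immune=None) -> None:
    """Write a cohort in the TSV formats the pipeline reads, plus
    ``ground_truth.json`` and ``normal_ref.tsv``."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    beta.to_csv(out / "beta.tsv", sep="\t")
    ann.to_csv(out / "manifest.tsv", sep="\t", index=False)
    samples.to_csv(out / "clinical.tsv", sep="\t", index=False)
    mutations.to_csv(out / "mutations.tsv", sep="\t")
    truth.normal_ref.to_frame().to_csv(out / "normal_ref.tsv", sep="\t")
    if expression is not None:
        expression.to_csv(out / "expression.tsv", sep="\t")
    if immune is not None:
        immune.to_csv(out / "immune.tsv", sep="\t")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
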