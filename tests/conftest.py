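import numpy as np
import pandas as pd
import pytest

from cimp import SimulationConfig, simulate_cohort
from cimp.cluster import MethylationGrouping


def grouping_from_truth(truth) -> MethylationGrouping:
    """Build a grouping directly from planted labels, bypassing the
    clustering stage, so module tests isolate the stage under test."""
    group = truth.group_of_sample
    return MethylationGrouping(
        group_of_sample=group,
        cluster_of_sample=(group == "high").astype(int),
        dmp_set=sorted(truth.informative_probes),
        group_means=pd.Series(dtype=float),
        kw_p=pd.Series(dtype=float),
        bonferroni_m=0,
    )


def all_hc(truth) -> pd.Series:
    return pd.Series(True, index=truth.group_of_sample.index)


@pytest.fixture(scope="session")
def small_cohort():
    """120 samples x 600 probes, planted driver and MSI burden confound."""
    cfg = SimulationConfig(n_samples=120, n_probes=600, msi_mode=True, seed=4)
    beta, ann, samples, mut, truth = simulate_cohort(cfg)
    return cfg, beta, ann, samples, mut, truth


@pytest.fixture(scope="session")
def mid_cohort():
    """200 samples x 600 probes, no MSI, for survival/panel/downstream tests."""
    cfg = SimulationConfig(n_samples=200, n_probes=600, seed=9)
    beta, ann, samples, mut, truth = simulate_cohort(cfg)
    return cfg, beta, ann, samples, mut, truth
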