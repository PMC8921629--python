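"""Probe filters and purity correction."""

import numpy as np
import pandas as pd
import pytest

from cimp import SimulationConfig, simulate_cohort, simulate_multi_cohort
from cimp.preprocess import (
    correct_purity,
    filter_age_gender,
    filter_context_na_sex,
    filter_nonvariable,
    preprocess_pipeline,
)


def _ann(rows):
    return pd.DataFrame(
        rows, columns=["probe_id", "chr", "pos", "relation_to_island", "gene"]
    ).set_index("probe_id", drop=False)


class TestContextNaSexFilter:
    def test_removal_rules(self):
        beta = pd.DataFrame(
            {
                "s1": [0.1, 0.2, 0.3, np.nan, 0.5],
                "s2": [0.2, 0.3, 0.4, 0.5, 0.6],
            },
            index=pd.Index(["pX", "pSea", "pOK", "pNA", "pShore"], name="probe_id"),
        )
        ann = _ann(
            [
                ("pX", "chrX", 1, "Island", ""),     # sex chromosome
                ("pSea", "chr1", 2, "OpenSea", ""),  # open sea
                ("pOK", "chr1", 3, "Island", ""),
                ("pNA", "chr2", 4, "Island", ""),    # one missing value
                ("pShore", "chr3", 5, "N_Shore", ""),
            ]
        )
        out = filter_context_na_sex(beta, ann)
        assert list(out.index) == ["pOK", "pShore"]
        assert list(out.columns) == ["s1", "s2"]

    def test_complete_version_of_na_probe_is_retained(self):
        ann = _ann([("p1", "chr1", 1, "Island", "")])
        with_na = pd.DataFrame({"s1": [np.nan], "s2": [0.4]}, index=pd.Index(["p1"], name="probe_id"))
        complete = pd.DataFrame({"s1": [0.3], "s2": [0.4]}, index=pd.Index(["p1"], name="probe_id"))
        assert filter_context_na_sex(with_na, ann).empty
        assert len(filter_context_na_sex(complete, ann)) == 1

    def test_unannotated_probe_raises_with_name(self):
        beta = pd.DataFrame({"s1": [0.1]}, index=pd.Index(["mystery"], name="probe_id"))
        with pytest.raises(KeyError, match="mystery"):
            filter_context_na_sex(beta, _ann([("other", "chr1", 1, "Island", "")]))


class TestNonvariableFilter:
    def test_forced_split_keeps_high_sd_probe(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.4, 0.6, 20)
        beta = pd.DataFrame(
            [np.full(20, 0.3), np.full(20, 0.5), np.clip(base + rng.normal(0, 0.5, 20), 0, 1)],
            index=["flat1", "flat2", "variable"],
        )
        kept, sd = filter_nonvariable(beta)
        assert list(kept.index) == ["variable"]
        assert (sd >= 0).all() and len(sd) == 3

    def test_two_regime_recovery(self):
        rng = np.random.default_rng(0)
        n = 30
        low = rng.normal(0.5, 0.01, (500, n))
        high = rng.normal(0.5, 0.15, (500, n))
        beta = pd.DataFrame(
            np.clip(np.vstack([low, high]), 0, 1),
            index=[f"lo{i}" for i in range(500)] + [f"hi{i}" for i in range(500)],
        )
        kept, _ = filter_nonvariable(beta, seed=0)
        hi_kept = sum(1 for p in kept.index if p.startswith("hi")) / 500
        lo_kept = sum(1 for p in kept.index if p.startswith("lo")) / 500
        assert hi_kept >= 0.95
        assert lo_kept <= 0.05

    def test_degenerate_variance_errors(self):
        beta = pd.DataFrame(np.full((10, 5), 0.5), index=[f"p{i}" for i in range(10)])
        with pytest.raises(ValueError, match="degenerate"):
            filter_nonvariable(beta)


class TestPurityCorrection:
    def _inputs(self, purities):
        beta = pd.DataFrame(
            {"s1": [0.5, 0.3], "s2": [0.5, 0.3]},
            index=pd.Index(["p1", "p2"], name="probe_id"),
        )
        samples = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "purity": purities}
        ).set_index("sample_id", drop=False)
        ref = pd.Series([0.2, 0.2], index=["p1", "p2"])
        return beta, samples, ref

    def test_purity_one_is_identity(self):
        beta, samples, ref = self._inputs([1.0, 1.0])
        out = correct_purity(beta, samples, ref)
        pd.testing.assert_frame_equal(out, beta)

    def test_mixture_inverse_arithmetic(self):
        beta, samples, ref = self._inputs([0.5, 1.0])
        out = correct_purity(beta, samples, ref)
        # (0.5 - 0.5*0.2)/0.5 = 0.8
        assert out.loc["p1", "s1"] == pytest.approx(0.8)
        assert out.loc["p1", "s2"] == pytest.approx(0.5)

    def test_zero_purity_errors(self):
        beta, samples, ref = self._inputs([0.0, 1.0])
        with pytest.raises(ValueError, match="purity 0"):
            correct_purity(beta, samples, ref)

    def test_missing_purity_left_unchanged(self):
        beta, samples, ref = self._inputs([np.nan, 0.5])
        out = correct_purity(beta, samples, ref)
        pd.testing.assert_series_equal(out["s1"], beta["s1"])
        assert out.loc["p1", "s2"] != beta.loc["p1", "s2"]

    def test_remixing_reconstructs_observed(self):
        # inverse followed by the forward mixture is the identity on
        # entries that were not clipped
        rng = np.random.default_rng(1)
        beta = pd.DataFrame(
            rng.uniform(0.2, 0.8, (50, 10)),
            index=[f"p{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(10)],
        )
        purity = rng.uniform(0.4, 0.95, 10)
        samples = pd.DataFrame({"purity": purity}, index=beta.columns)
        ref = pd.Series(rng.uniform(0.2, 0.8, 50), index=beta.index)
        corrected = correct_purity(beta, samples, ref)
        unclipped = (corrected.to_numpy() > 0) & (corrected.to_numpy() < 1)
        remixed = corrected.to_numpy() * purity[None, :] + (1 - purity[None, :]) * ref.to_numpy()[:, None]
        np.testing.assert_allclose(
            remixed[unclipped], beta.to_numpy()[unclipped], atol=1e-12
        )

    def test_recovers_true_tumor_signal(self):
        cfg = SimulationConfig(n_samples=80, n_probes=400, noise_sd=0.02,
                               purity_range=(0.4, 0.95), frac_na_probes=0.0, seed=21)
        beta, ann, samples, mut, truth = simulate_cohort(cfg)
        corrected = correct_purity(beta, samples, truth.normal_ref)
        est = corrected.to_numpy()
        true = truth.true_tumor_beta.to_numpy()
        unclipped = (est > 0) & (est < 1)
        rmse = np.sqrt(np.mean((est[unclipped] - true[unclipped]) ** 2))
        assert rmse < 0.03


class TestAgeGenderFilter:
    def _cohorts(self):
        cfg = SimulationConfig(n_samples=120, n_probes=800, n_cohorts=3, seed=8)
        betas, anns, samples, muts, truths = simulate_multi_cohort(cfg)
        return betas, samples, truths[0]

    def test_cross_cohort_rule(self):
        betas, samples, truth = self._cohorts()
        filtered, stats = filter_age_gender(betas, samples)
        kept = set(filtered[0].index)
        shared_kept = len(kept & truth.shared_age_probes) / len(truth.shared_age_probes)
        single_kept = len(kept & truth.single_age_probes) / len(truth.single_age_probes)
        assert shared_kept <= 0.05  # age-associated in >= 2 cohorts: removed
        assert single_kept >= 0.95  # single-cohort association: retained
        # removal applies to every cohort
        for f in filtered[1:]:
            assert len(set(f.index) & truth.shared_age_probes) / len(truth.shared_age_probes) <= 0.05

    def test_blacklist_is_unconditional(self):
        betas, samples, truth = self._cohorts()
        victim = next(iter(truth.nonvariable_probes))  # zero age correlation
        filtered, stats = filter_age_gender(betas, samples, blacklist={victim})
        assert all(victim not in f.index for f in filtered)
        assert bool(stats.loc[victim, "blacklisted"].item()) is True

    def test_single_cohort_applies_blacklist_only(self):
        betas, samples, truth = self._cohorts()
        victim = sorted(truth.shared_age_probes)[0]
        filtered, _ = filter_age_gender([betas[0]], [samples[0]], blacklist={victim})
        kept = set(filtered[0].index)
        assert victim not in kept
        # without >= 2 cohorts no age probe is removed by the FDR rule
        assert len(kept & truth.shared_age_probes) == len(truth.shared_age_probes) - 1

    def test_missing_age_and_gender_errors(self):
        betas, samples, _ = self._cohorts()
        bare = [s.drop(columns=["age", "gender"]) for s in samples]
        with pytest.raises(ValueError, match="age and gender"):
            filter_age_gender(betas, bare)


def test_pipeline_preserves_samples_and_recovers_planted_probes():
    cfg = SimulationConfig(n_samples=150, n_probes=1500, seed=11)
    beta, ann, samples, mut, truth = simulate_cohort(cfg)
    filtered, fs = preprocess_pipeline([beta], [ann], [samples], [truth.normal_ref], seed=0)
    out = filtered[0]
    assert list(out.columns) == list(beta.columns)  # filters never drop samples
    info_kept = len(set(out.index) & truth.informative_probes) / len(truth.informative_probes)
    nonvar_kept = len(set(out.index) & truth.nonvariable_probes) / len(truth.nonvariable_probes)
    assert info_kept >= 0.90
    assert nonvar_kept <= 0.05
    assert fs.n_input >= fs.n_after_context >= fs.n_after_nonvariable >= fs.n_after_age_gender


class TestMixtureProperties:
    """Algebraic properties of the two-component purity model."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @staticmethod
    def _frame(obs, ref):
        beta = pd.DataFrame({"s": [obs]}, index=pd.Index(["p"], name="probe_id"))
        return beta, pd.Series([ref], index=["p"])

    @settings(max_examples=50, derandomize=True)
    @given(
        obs=st.floats(0.0, 1.0),
        purity=st.floats(0.05, 1.0),
        ref=st.floats(0.0, 1.0),
    )
    def test_corrected_value_in_range_and_invertible(self, obs, purity, ref):
        beta, refs = self._frame(obs, ref)
        samples = pd.DataFrame({"purity": [purity]}, index=["s"])
        out = correct_purity(beta, samples, refs)
        val = out.loc["p", "s"]
        assert 0.0 <= val <= 1.0
        if 0.0 < val < 1.0:  # unclipped entries remix exactly
            assert purity * val + (1 - purity) * ref == pytest.approx(obs, abs=1e-9)
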