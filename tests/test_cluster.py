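"""Consensus spectral clustering, DMP detection, group naming, CIMP call."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cimp.cluster import (
    assign_groups,
    build_knn_affinity,
    call_cimp,
    cluster_clinical_association,
    consensus_spectral,
    detect_dmps,
    select_k,
    silhouette_euclidean,
)


def _beta_from_points(points: np.ndarray) -> pd.DataFrame:
    """samples-as-points -> probe x sample frame."""
    return pd.DataFrame(points.T, columns=[f"s{i}" for i in range(points.shape[0])])


def brute_force_silhouette(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """O(n^2) silhouette from the definition, the independent oracle."""
    n = len(labels)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    out = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if same.sum() == 0:
            out[i] = 0.0
            continue
        a = D[i, same].mean()
        b = min(D[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
        out[i] = (b - a) / max(a, b)
    return out


class TestAffinity:
    def test_small_brute_force_neighbors(self):
        beta = _beta_from_points(np.array([[0.0], [0.1], [1.0]]))
        a = build_knn_affinity(beta, n_neighbors=1)
        m = a.to_numpy()
        assert m[0, 1] == 1  # mutual nearest pair
        assert m[1, 2] == 1  # sample 2's nearest neighbor is 1 (OR-symmetrized)
        assert np.allclose(m, m.T) and np.all(np.diag(m) == 0)

    def test_duplicate_samples_are_mutual_neighbors(self):
        beta = _beta_from_points(np.array([[0.5], [0.5], [0.9], [0.1]]))
        a = build_knn_affinity(beta, n_neighbors=1).to_numpy()
        assert a[0, 1] == 1 and a[1, 0] == 1

    def test_too_many_neighbors_rejected(self):
        beta = _beta_from_points(np.random.default_rng(0).random((5, 2)))
        with pytest.raises(ValueError):
            build_knn_affinity(beta, n_neighbors=5)


class TestSilhouette:
    def test_hand_computed_value(self):
        # points {0, 0.1} vs {1, 1.1}: s(0) = (1.05 - 0.1)/1.05
        X = np.array([[0.0], [0.1], [1.0], [1.1]])
        labels = np.array([0, 0, 1, 1])
        s = silhouette_euclidean(X, labels)
        assert s[0] == pytest.approx((1.05 - 0.1) / 1.05, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.random((50, 4))
        labels = rng.integers(0, 3, 50)
        np.testing.assert_allclose(
            silhouette_euclidean(X, labels), brute_force_silhouette(X, labels), atol=1e-12
        )


class TestConsensus:
    def test_two_blobs_recovered_exactly(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.2, 0.02, (100, 5))
        b = rng.normal(0.8, 0.02, (100, 5))
        X = np.clip(np.vstack([a, b]), 0, 1)
        truth = np.array([0] * 100 + [1] * 100)
        beta = _beta_from_points(X)
        res = consensus_spectral(beta, k=2, seed=1)
        assert adjusted_rand_score(truth, res.labels.to_numpy()) == 1.0
        cvals = res.consensus.to_numpy()
        assert np.isin(cvals, (0.0, 1.0)).all()
        assert (res.hc_mask == (res.ssc > 0)).all()

    def test_single_run_consensus_is_binary(self):
        rng = np.random.default_rng(2)
        beta = _beta_from_points(rng.random((30, 3)))
        res = consensus_spectral(beta, k=2, n_runs=1, seed=0)
        assert np.isin(res.consensus.to_numpy(), (0.0, 1.0)).all()

    def test_k_bounds(self):
        beta = _beta_from_points(np.random.default_rng(0).random((20, 2)))
        with pytest.raises(ValueError):
            consensus_spectral(beta, k=1)
        with pytest.raises(ValueError):
            consensus_spectral(beta, k=5)  # > n/5


class TestDmps:
    def _labels(self, n0, n1):
        return pd.Series(
            [0] * n0 + [1] * n1, index=[f"s{i}" for i in range(n0 + n1)]
        )

    def test_constant_probe_excluded_and_shift_detected(self):
        rng = np.random.default_rng(3)
        labels = self._labels(50, 50)
        shifted = np.concatenate([rng.normal(0.3, 0.05, 50), rng.normal(0.6, 0.05, 50)])
        beta = pd.DataFrame(
            [np.full(100, 0.5), np.clip(shifted, 0, 1)],
            index=["flat", "shifted"],
            columns=labels.index,
        )
        dmp, kw_p = detect_dmps(beta, labels)
        assert dmp == ["shifted"]
        assert kw_p.loc["flat"] == 1.0

    def test_bonferroni_family_size_caps_at_one(self):
        # raw p=0.01 with m=1000 is adjusted to 1.0 and excluded: embed one
        # weak probe among 999 flats
        rng = np.random.default_rng(4)
        labels = self._labels(6, 6)
        weak = np.concatenate([rng.normal(0.45, 0.05, 6), rng.normal(0.55, 0.05, 6)])
        rows = [np.full(12, 0.5)] * 999 + [np.clip(weak, 0, 1)]
        beta = pd.DataFrame(rows, index=[f"p{i}" for i in range(1000)], columns=labels.index)
        dmp, kw_p = detect_dmps(beta, labels)
        assert kw_p.iloc[-1] > 0.05 / 1000  # cannot survive m=1000
        assert dmp == []

    def test_small_cluster_rejected(self):
        labels = pd.Series([0, 0, 1], index=["s0", "s1", "s2"])
        beta = pd.DataFrame([[0.1, 0.2, 0.9]], index=["p"], columns=labels.index)
        with pytest.raises(ValueError):
            detect_dmps(beta, labels)


class TestGroups:
    def _beta(self, means, n_per=4):
        cols, vals = [], []
        for ci, m in enumerate(means):
            for j in range(n_per):
                cols.append(f"c{ci}s{j}")
                vals.append(m)
        return (
            pd.DataFrame([vals], index=["p1"], columns=cols),
            pd.Series(sum([[ci] * n_per for ci in range(len(means))], []),
                      index=cols),
        )

    def test_two_and_three_cluster_orderings(self):
        beta, labels = self._beta([0.30, 0.60])
        g = assign_groups(beta, labels, ["p1"])
        assert set(g.group_of_sample[labels == 0]) == {"low"}
        assert set(g.group_of_sample[labels == 1]) == {"high"}

        beta3, labels3 = self._beta([0.5, 0.2, 0.8])
        g3 = assign_groups(beta3, labels3, ["p1"])
        assert set(g3.group_of_sample[labels3 == 1]) == {"low"}
        assert set(g3.group_of_sample[labels3 == 0]) == {"intermediate"}
        assert set(g3.group_of_sample[labels3 == 2]) == {"high"}
        gm = g3.group_means
        assert gm["low"] <= gm["intermediate"] <= gm["high"]

    def test_exact_tie_goes_to_lower_cluster_index(self):
        beta, labels = self._beta([0.4, 0.4])
        g = assign_groups(beta, labels, ["p1"])
        assert set(g.group_of_sample[labels == 0]) == {"low"}

    def test_empty_dmp_set_rejected(self):
        beta, labels = self._beta([0.3, 0.6])
        with pytest.raises(ValueError):
            assign_groups(beta, labels, [])


class TestSelectK:
    @staticmethod
    def _plateau_beta(levels, n_per, sep, rng):
        pts = np.vstack([rng.normal(lv, 0.02, (n_per, 8)) for lv in levels])
        return _beta_from_points(np.clip(pts, 0, 1))

    def test_two_blobs_give_k2(self):
        rng = np.random.default_rng(5)
        beta = self._plateau_beta([0.2, 0.8], 50, None, rng)
        k, cres, grouping = select_k(beta, seed=0)
        assert k == 2

    def test_three_plateaus_give_k3(self):
        rng = np.random.default_rng(6)
        beta = self._plateau_beta([0.1, 0.5, 0.9], 40, None, rng)
        k, cres, grouping = select_k(beta, seed=0)
        assert k == 3
        assert set(grouping.group_of_sample.unique()) == {"low", "intermediate", "high"}


class TestCimpCall:
    def _grouping(self, lo_vals, hi_vals):
        cols = [f"l{i}" for i in range(len(lo_vals[0]))] + [f"h{i}" for i in range(len(hi_vals[0]))]
        beta = pd.DataFrame(
            np.hstack([lo_vals, hi_vals]),
            index=[f"p{i}" for i in range(len(lo_vals))],
            columns=cols,
        )
        labels = pd.Series([0] * len(lo_vals[0]) + [1] * len(hi_vals[0]), index=cols)
        g = assign_groups(beta, labels, list(beta.index))
        return g, beta

    def test_threshold_rule_positive_and_negative(self):
        rng = np.random.default_rng(7)
        lo = rng.normal(0.30, 0.01, (20, 30))
        g, beta = self._grouping(lo, lo + 0.25)
        call = call_cimp(g, beta)
        assert call.status == "positive"
        assert call.delta_high_low == pytest.approx(0.25, abs=0.01)

        g2, beta2 = self._grouping(lo, lo + 0.15)
        call2 = call_cimp(g2, beta2)
        assert call2.kw_group_p < 0.05  # significant but below the delta cutoff
        assert call2.status == "negative"

    def test_cimp_score_is_mean_over_dmps(self):
        g, beta = self._grouping(
            np.array([[0.2, 0.2], [0.4, 0.4]]), np.array([[0.6, 0.6], [0.8, 0.8]])
        )
        call = call_cimp(g, beta)
        assert call.cimp_score["l0"] == pytest.approx(0.3)
        assert (call.cimp_score >= 0).all() and (call.cimp_score <= 1).all()

    def test_hypermethylation_only_has_low_hypo_fraction(self):
        rng = np.random.default_rng(8)
        lo = rng.normal(0.3, 0.01, (50, 30))
        g, beta = self._grouping(lo, lo + 0.3)
        call = call_cimp(g, beta)
        assert call.hypo_fraction <= 0.05

    def test_normal_reference_delta(self):
        g, beta = self._grouping(np.full((2, 10), 0.3), np.full((2, 10), 0.6))
        ref = pd.Series(0.2, index=beta.index)
        call = call_cimp(g, beta, normal_ref=ref)
        assert call.delta_high_normal == pytest.approx(0.4)


class TestClinicalAssociation:
    def test_hand_chi_square_and_planted_subtype(self):
        cols = [f"s{i}" for i in range(60)]
        group = pd.Series(["low"] * 30 + ["high"] * 30, index=cols)
        beta = pd.DataFrame([np.linspace(0, 1, 60)], index=["p"], columns=cols)
        labels = pd.Series([0] * 30 + [1] * 30, index=cols)
        g = assign_groups(beta, labels, ["p"])
        samples = pd.DataFrame(
            {
                "subtype": ["A"] * 30 + ["B"] * 30,  # perfectly aligned
                "age": np.full(60, 50.0),            # constant: skipped
            },
            index=cols,
        )
        out = cluster_clinical_association(
            g, samples, continuous=("age",), categorical=("subtype",)
        ).set_index("unit")
        # 2x2 table [[30,0],[0,30]] has chi-square statistic n = 60
        assert out.loc["subtype", "statistic"] == pytest.approx(60.0)
        assert bool(out.loc["subtype", "significant"].item())
        assert "age" not in out.index
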