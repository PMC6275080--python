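"""SAM statistic, fudge factor, permutation q-values and DM calling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from methclass import diff_methylation as dm


class TestSamStatistic:
    def test_equal_means_give_zero(self):
        assert dm.sam_statistic([0.3, 0.4, 0.5], [0.5, 0.4, 0.3], 0.1) == 0.0

    def test_hand_arithmetic_with_zero_spread(self):
        # s = 0, so d = (0.4 - 0.2) / s0 = 2.0
        d = dm.sam_statistic([0.2, 0.2, 0.2], [0.4, 0.4, 0.4], 0.1)
        assert d == pytest.approx(2.0)

    def test_abs_d_non_increasing_in_s0(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(5), rng.random(5) + 0.2
        ds = [abs(dm.sam_statistic(a, b, s0)) for s0 in (0.0, 0.1, 0.5, 2.0)]
        assert ds == sorted(ds, reverse=True)

    def test_group_with_single_value_rejected(self):
        with pytest.raises(ValueError):
            dm.sam_statistic([0.2], [0.4, 0.5], 0.1)


class TestEstimateS0:
    def test_median_policy(self):
        s = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        r = np.ones(5)
        assert dm.estimate_s0(r, s, "median-s") == pytest.approx(0.3)

    def test_tusher_minimizes_cv_on_grid(self):
        rng = np.random.default_rng(2)
        s = rng.gamma(2.0, 0.05, size=500)
        r = rng.normal(0, s + 0.05)
        s0 = dm.estimate_s0(r, s, "tusher")
        # oracle: re-scan the same candidate grid independently
        candidates = np.unique(np.percentile(s, np.arange(0, 101, 5)))
        n_bins = min(100, 500 // 10)
        edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
        bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)

        def cv(s0c):
            d = r / (s + s0c)
            spreads = [
                np.median(np.abs(d[bins == b] - np.median(d[bins == b]))) / 0.64
                for b in range(n_bins)
                if (bins == b).sum() >= 2
            ]
            spreads = np.asarray(spreads)
            return spreads.std() / spreads.mean()

        best = min(candidates, key=cv)
        assert s0 == pytest.approx(best)

    def test_constant_s_returns_that_scale(self):
        s = np.full(100, 0.25)
        r = np.linspace(-1, 1, 100)
        for policy in ("median-s", "tusher"):
            assert dm.estimate_s0(r, s, policy) == pytest.approx(0.25)

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError):
            dm.estimate_s0(np.array([1.0]), np.array([0.1]))


def _brute_force_sam_q(x, labels):
    """Independent exhaustive-permutation SAM q-values on a tiny matrix."""
    n = len(labels)
    n_a = int((labels == 0).sum())

    def d_stats(mask_a):
        a, b = x[:, mask_a], x[:, ~mask_a]
        ma, mb = a.mean(1), b.mean(1)
        ss = ((a - ma[:, None]) ** 2).sum(1) + ((b - mb[:, None]) ** 2).sum(1)
        s = np.sqrt((1 / a.shape[1] + 1 / b.shape[1]) * ss / (n - 2))
        return ma, mb, s

    obs_mask = labels == 0
    ma, mb, s = d_stats(obs_mask)
    s0 = dm.estimate_s0(mb - ma, s, "tusher")
    d_obs = (mb - ma) / (s + s0)
    null_counts = []
    for combo in itertools.combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        ma, mb, s = d_stats(mask)
        d_null = np.abs((mb - ma) / (s + s0))
        null_counts.append([(d_null >= abs(d)).sum() for d in d_obs])
    med = np.median(np.array(null_counts), axis=0)
    order = np.argsort(-np.abs(d_obs), kind="stable")
    q_sorted = np.minimum(med[order] / np.arange(1, len(d_obs) + 1), 1.0)
    q_sorted = np.maximum.accumulate(q_sorted)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


class TestPermutationQvalues:
    def test_exhaustive_matches_brute_force_on_3v3_toy(self):
        rng = np.random.default_rng(3)
        x = rng.random((30, 6))
        x[:5, 3:] += 0.5  # a handful of shifted probes
        x = np.clip(x, 0, 1)
        beta = pd.DataFrame(
            x, index=[f"p{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(6)],
        )
        labels = pd.Series([0, 0, 0, 1, 1, 1], index=beta.columns)
        q, d, _ = dm.permutation_qvalues(beta, labels, exhaustive=True)
        expected = _brute_force_sam_q(x, labels.to_numpy())
        np.testing.assert_allclose(q.to_numpy(), expected)

    def test_q_monotone_in_abs_d(self, small_cohort):
        beta = small_cohort.beta.iloc[:500]
        labels = small_cohort.truth["labels"]
        two = labels[labels.isin([2, 3])]
        cfg = dm.DiffMethylConfig(n_permutations=30, seed=1)
        q, d, _ = dm.permutation_qvalues(beta[two.index], two, cfg)
        order = np.argsort(-np.abs(d.to_numpy()), kind="stable")
        qs = q.to_numpy()[order]
        assert (np.diff(qs) >= -1e-12).all()
        assert ((qs >= 0) & (qs <= 1)).all()
        # the largest |d| attains the smallest q
        assert qs[0] == q.min()

    def test_requires_two_classes(self, small_cohort):
        beta = small_cohort.beta.iloc[:50]
        labels = small_cohort.truth["labels"]
        with pytest.raises(ValueError):
            dm.permutation_qvalues(beta, labels)


class TestCallDmProbes:
    def test_calling_rule_consistency(self, small_cohort):
        cfg = dm.DiffMethylConfig(n_permutations=30, seed=2)
        res = dm.call_dm_probes(
            small_cohort.beta.iloc[:800], small_cohort.truth["labels"], (2, 3), cfg
        )
        t = res.table
        high = (t["fold_change"] > cfg.fc_high) & (t["q"] < cfg.q_threshold)
        low = (t["fold_change"] < cfg.fc_low) & (t["q"] < cfg.q_threshold)
        assert (t["call"] == "high").equals(high)
        assert (t["call"] == "low").equals(low)
        # dead zone: fc in [0.95, 1.05] is never called regardless of q
        dead = t["fold_change"].between(cfg.fc_low, cfg.fc_high)
        assert (t.loc[dead, "call"] == "none").all()

    def test_swapping_pair_inverts_fold_change_and_calls(self, small_cohort):
        cfg = dm.DiffMethylConfig(n_permutations=25, seed=3)
        beta = small_cohort.beta.iloc[:400]
        labels = small_cohort.truth["labels"]
        fwd = dm.call_dm_probes(beta, labels, (2, 3), cfg).table
        rev = dm.call_dm_probes(beta, labels, (3, 2), cfg).table
        np.testing.assert_allclose(
            fwd["fold_change"], 1.0 / rev["fold_change"], rtol=1e-12
        )
        np.testing.assert_allclose(fwd["d"], -rev["d"], rtol=1e-9)
        swapped = rev["call"].map({"high": "low", "low": "high", "none": "none"})
        assert (fwd["call"] == swapped).all()

    def test_hypo_calls_recover_flagged_promoter_probes(self, small_cohort):
        cfg = dm.DiffMethylConfig(n_permutations=50, seed=1)
        res = dm.call_dm_probes(
            small_cohort.beta, small_cohort.truth["labels"], (2, 3), cfg
        )
        hypo = res.table.index[res.table["call"] == "low"]
        truth = small_cohort.truth["class3_hypo_probes"]
        recall = truth[hypo].sum() / truth.sum()
        assert recall >= 0.7

    def test_absent_class_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            dm.call_dm_probes(
                small_cohort.beta.iloc[:50], small_cohort.truth["labels"], (2, 9)
            )


class TestMapDmProbesToGenes:
    @pytest.fixture
    def annotation_and_models(self):
        models = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "strand": ["+", "+"],
                "tss": [10_000, 50_000],
                "tx_start": [10_000, 50_000],
                "tx_end": [14_000, 54_000],
                "exons": [[(10_000, 10_500)], [(50_000, 50_500)]],
                "utr5": [[], []],
                "utr3": [[], []],
            },
            index=pd.Index(["GA", "GB"], name="symbol"),
        )
        annotation = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [10_100, 9_000, 52_000, 50_200],
            },
            index=pd.Index(["prom_a1", "prom_a2", "intron_b", "prom_b"],
                           name="probe"),
        )
        return annotation, models

    def _dm_result(self, calls: dict) -> dm.DiffMethylResult:
        table = pd.DataFrame(
            {"call": pd.Series(calls)},
        )
        table["q"] = 0.001
        return dm.DiffMethylResult(table=table, s0=0.1)

    def test_single_high_promoter_probe(self, annotation_and_models):
        annotation, models = annotation_and_models
        res = self._dm_result({"prom_a1": "high"})
        high, low, both = dm.map_dm_probes_to_genes(res, annotation, models)
        assert high == {"GA"} and low == set() and both == set()

    def test_conflicting_promoter_probes_excluded(self, annotation_and_models):
        annotation, models = annotation_and_models
        res = self._dm_result({"prom_a1": "high", "prom_a2": "low"})
        high, low, both = dm.map_dm_probes_to_genes(res, annotation, models)
        assert high == set() and low == set() and both == {"GA"}

    def test_intronic_probe_maps_to_no_gene(self, annotation_and_models):
        annotation, models = annotation_and_models
        res = self._dm_result({"intron_b": "high"})
        high, low, both = dm.map_dm_probes_to_genes(res, annotation, models)
        assert high == set() and low == set()
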