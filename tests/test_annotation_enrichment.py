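"""Region assignment, Fisher enrichment and the fold-enrichment statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from methclass import annotation_enrichment as ae


@pytest.fixture(scope="module")
def toy_models():
    # one + strand gene and one - strand gene on chr1
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "strand": ["+", "-"],
            "tss": [100_000, 250_000],  # for GB, TSS = tx_end
            "tx_start": [100_000, 246_000],
            "tx_end": [104_000, 250_000],
            "exons": [
                [(100_000, 100_499), (101_500, 101_999), (103_500, 103_999)],
                [(246_000, 246_499), (249_500, 249_999)],
            ],
            "utr5": [[(100_000, 100_199)], [(249_800, 249_999)]],
            "utr3": [[(103_800, 103_999)], [(246_000, 246_199)]],
        },
        index=pd.Index(["GA", "GB"], name="symbol"),
    )


def _annotate(positions, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": list(positions)},
        index=pd.Index([f"cg{i}" for i in range(len(positions))], name="probe"),
    )


class TestAssignRegions:
    def test_probe_at_tss_is_promoter(self, toy_models):
        regions = ae.assign_regions(_annotate([100_000]), toy_models)
        assert bool(regions.loc["cg0", "promoter"])

    def test_promoter_boundary_inclusive(self, toy_models):
        regions = ae.assign_regions(
            _annotate([101_500, 101_501, 98_500, 98_499]), toy_models
        )
        assert regions["promoter"].tolist() == [True, False, True, False]

    def test_strand_aware_promoter_on_minus_gene(self, toy_models):
        # GB's TSS is its tx_end (250_000)
        regions = ae.assign_regions(_annotate([251_400, 251_600]), toy_models)
        assert regions["promoter"].tolist() == [True, False]

    def test_intron_inside_transcript_outside_exons(self, toy_models):
        regions = ae.assign_regions(_annotate([101_000]), toy_models)
        row = regions.loc["cg0"]
        assert bool(row["intron"]) and not row["exon"] and not row["intergenic"]

    def test_utr_labels(self, toy_models):
        regions = ae.assign_regions(_annotate([100_100, 103_900]), toy_models)
        assert bool(regions.loc["cg0", "5UTR"])
        assert bool(regions.loc["cg1", "3UTR"])

    def test_between_genes_is_intergenic(self, toy_models):
        regions = ae.assign_regions(_annotate([150_000]), toy_models)
        assert bool(regions.loc["cg0", "intergenic"])
        assert not regions.loc["cg0", list(ae.REGION_LABELS[:-1])].any()

    def test_unknown_chromosome_flagged_intergenic(self, toy_models):
        regions = ae.assign_regions(_annotate([5_000], chrom="chrUn"), toy_models)
        assert bool(regions.loc["cg0", "intergenic"])

    def test_intergenic_iff_no_other_label(self, small_cohort):
        regions = ae.assign_regions(
            small_cohort.annotation, small_cohort.gene_models
        )
        other = regions[list(ae.REGION_LABELS[:-1])].any(axis=1)
        assert (regions["intergenic"] == ~other).all()


class TestFisherEnrichment:
    def test_balanced_table_no_association(self):
        orr, p = ae.fisher_enrichment(1, 2, 2, 4)
        assert orr == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_odds_ratio(self):
        orr, p = ae.fisher_enrichment(8, 20, 10, 100)
        assert orr == pytest.approx(8 * 78 / (2 * 12))
        # oracle: two-sided exhaustive hypergeometric enumeration
        pmf = hypergeom.pmf(np.arange(0, 11), 100, 20, 10)
        expected = pmf[pmf <= pmf[8] * (1 + 1e-12)].sum()
        assert p == pytest.approx(expected)

    def test_query_saturates_background(self):
        _, p = ae.fisher_enrichment(10, 100, 10, 100)
        assert p == pytest.approx(1.0)

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            ae.fisher_enrichment(5, 3, 10, 100)


class TestFoldEnrichment:
    def test_saturated_is_zero(self):
        assert ae.fold_enrichment(20, 20, 100, 100) == 0.0

    def test_direct_evaluation(self):
        assert ae.fold_enrichment(9, 19, 9, 99) == pytest.approx(np.log2(5))

    def test_empty_set_reduction(self):
        n, N = 9, 99
        assert ae.fold_enrichment(0, 0, n, N) == pytest.approx(
            -np.log2((n + 1) / (N + 1))
        )

    @given(
        K=st.integers(1, 200), n=st.integers(1, 200), N=st.integers(1, 400)
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_k(self, K, n, N):
        N = max(N, K, n)
        kmax = min(K, n)
        vals = [ae.fold_enrichment(k, K, n, N) for k in range(kmax + 1)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestBH:
    def test_single_p_unchanged(self):
        assert ae.bh_qvalues([0.03])[0] == pytest.approx(0.03)

    def test_permutation_invariance_and_stepup_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.random(rng.integers(2, 40))
            q = ae.bh_qvalues(p)
            # brute-force min-over-suffix oracle
            m = len(p)
            order = np.argsort(p)
            expected = np.empty(m)
            for rank, idx in enumerate(order, start=1):
                expected[idx] = min(
                    p[j] * m / (list(order).index(j) + 1) for j in order[rank - 1:]
                )
            np.testing.assert_allclose(q, np.minimum(expected, 1.0))
            perm = rng.permutation(m)
            np.testing.assert_allclose(ae.bh_qvalues(p[perm]), q[perm])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ae.bh_qvalues([0.5, 1.4])


class TestRegionEnrichment:
    def test_uniform_query_shows_no_enrichment(self, small_cohort):
        regions = ae.assign_regions(
            small_cohort.annotation, small_cohort.gene_models
        )
        rng = np.random.default_rng(0)
        query = rng.choice(small_cohort.beta.index, size=500, replace=False)
        recs = ae.region_enrichment(query, small_cohort.beta.index, regions)
        qs = [r.q for r in recs]
        # fold enrichment is noisy for tiny categories; judge the stable ones
        lf = [abs(r.log2_fold_enrichment) for r in recs if r.K >= 100]
        assert min(qs) > 0.05
        assert max(lf) < 0.5

    def test_all_promoter_query_maximal(self, small_cohort):
        regions = ae.assign_regions(
            small_cohort.annotation, small_cohort.gene_models
        )
        prom = regions.index[regions["promoter"]]
        recs = ae.region_enrichment(prom, small_cohort.beta.index, regions)
        by_name = {r.name: r for r in recs}
        assert by_name["promoter"].k == by_name["promoter"].n
        assert min(recs, key=lambda r: r.q).name == "promoter"

    def test_empty_query_rejected(self, small_cohort):
        regions = ae.assign_regions(
            small_cohort.annotation, small_cohort.gene_models
        )
        with pytest.raises(ValueError):
            ae.region_enrichment([], small_cohort.beta.index, regions)


class TestGenesetEnrichment:
    def test_full_disjoint_set_recovered(self):
        collection = {
            "A": [f"a{i}" for i in range(10)],
            "B": [f"b{i}" for i in range(10)],
            "C": [f"c{i}" for i in range(10)],
        }
        recs = ae.geneset_enrichment(collection["A"], collection)
        by_name = {r.name: r for r in recs}
        assert by_name["A"].k == by_name["A"].K == 10
        assert min(recs, key=lambda r: r.p).name == "A"

    @pytest.mark.parametrize("seed", range(20))
    def test_random_query_yields_no_significant_set(self, seed):
        rng = np.random.default_rng(seed)
        universe = np.array([f"g{i}" for i in range(5000)])
        collection = {
            f"S{j}": list(rng.choice(universe, size=150, replace=False))
            for j in range(30)
        }
        collection["ALL"] = list(universe)  # anchor the universe
        query = list(rng.choice(universe, size=50, replace=False))
        recs = ae.geneset_enrichment(query, collection)
        assert min(r.q for r in recs if r.name != "ALL") > 0.05

    def test_designated_tf_set_recovered_from_truth(self, small_cohort):
        from methclass import diff_methylation as dmod

        cfg = dmod.DiffMethylConfig(n_permutations=50, seed=1)
        res = dmod.call_dm_probes(
            small_cohort.beta, small_cohort.truth["labels"], (2, 3), cfg
        )
        _, low_genes, _ = dmod.map_dm_probes_to_genes(
            res, small_cohort.annotation, small_cohort.gene_models
        )
        recs = ae.geneset_enrichment(sorted(low_genes), small_cohort.tf_sets)
        designated = small_cohort.truth["designated_tf_set"]
        rec = next(r for r in recs if r.name == designated)
        assert rec.q < 0.05
        assert rec.log2_fold_enrichment > 0

    def test_disjoint_query_warns(self):
        collection = {"A": ["x", "y", "z"]}
        with pytest.warns(UserWarning):
            recs = ae.geneset_enrichment(["q1", "q2"], collection)
        assert all(r.k == 0 for r in recs)
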