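"""Empirical ranks, outlier calling, region construction, overlap, annotation."""

import numpy as np
import pandas as pd
import pytest

import popsel


def snp_track(positions, values, chrom="1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions,
                         "id": [f"v{i}" for i in range(len(positions))],
                         "std": values})


def fst_track(positions, p_values, chrom="1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions,
                         "empirical_p": p_values})


def window_track(starts, window, ps, chrom="1"):
    return pd.DataFrame({"chrom": chrom, "start": starts,
                         "end": [s + window - 1 for s in starts],
                         "D": -np.asarray(ps), "skipped": False,
                         "empirical_p": ps})


class TestEmpiricalP:
    def test_most_extreme_of_1000(self):
        v = np.arange(1000, dtype=float)
        p = popsel.empirical_p(v, direction="high")
        assert p[np.argmax(v)] == pytest.approx(0.001)
        assert p[np.argmin(v)] == pytest.approx(1.0)

    def test_ties_share_smallest_rank(self):
        v = np.r_[np.arange(998, dtype=float), [999.0, 999.0]]
        p = popsel.empirical_p(v, direction="high")
        assert p[-1] == p[-2] == pytest.approx(0.001)

    def test_uniform_by_rank_identity(self):
        rng = np.random.default_rng(0)
        v = rng.random(500)
        p = np.sort(popsel.empirical_p(v, direction="low"))
        np.testing.assert_allclose(p, np.arange(1, 501) / 500)

    def test_all_identical_values_p_one(self):
        p = popsel.empirical_p(np.ones(200), direction="high")
        assert np.all(p == 1.0)

    def test_low_resolution_warns(self):
        with pytest.warns(UserWarning, match="resolution"):
            popsel.empirical_p(np.arange(10.0), direction="high")


class TestXpehhOutliers:
    def test_top_fraction_count(self):
        rng = np.random.default_rng(1)
        track = snp_track(np.arange(1, 10_001) * 100, rng.normal(size=10_000))
        out = popsel.xpehh_outliers(track)
        assert len(out) == 10

    def test_direction_flips_tail(self):
        rng = np.random.default_rng(2)
        track = snp_track(np.arange(1, 1001) * 100, rng.normal(size=1000))
        hi = popsel.xpehh_outliers(track, direction="high")
        lo = popsel.xpehh_outliers(track, direction="low")
        assert hi["std"].min() > lo["std"].max()

    def test_neutral_outliers_rarely_cluster(self, neutral_cohort):
        """Null scan: scattered outliers, no composite region emitted."""
        hm = neutral_cohort.haplotypes
        track = popsel.xpehh_scan(hm.subset_population("sweep"),
                                  hm.subset_population("neutral")).table
        out = popsel.xpehh_outliers(track)
        gm = hm.to_genotypes()
        fst = popsel.wc_fst_per_snp(gm, "sweep", "neutral")
        regions = popsel.call_composite_regions(out, fst.table)
        # 5 outliers over 5 Mb: a >=2-SNP cluster within 200 kb is unusual
        assert len(regions) <= 1


class TestCompositeRegions:
    def test_paper_rule_positive_case(self):
        """3 clustered outliers + 1 spanned F_ST hit: one region, 3 SNPs."""
        out = snp_track([100_000, 120_000, 150_000], [5.0, 4.8, 4.5])
        out["empirical_p"] = [0.0002, 0.0004, 0.0006]
        fst = fst_track([110_000, 500_000], [0.005, 0.5])
        regions = popsel.call_composite_regions(out, fst)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.n_members) == (100_000, 150_000, 3)

    def test_isolated_outlier_no_region(self):
        out = snp_track([100_000], [5.0])
        out["empirical_p"] = [0.001]
        fst = fst_track([100_000], [0.001])
        assert popsel.call_composite_regions(out, fst) == []

    def test_fst_condition_gates_the_cluster(self):
        out = snp_track([100_000, 120_000], [5.0, 4.8])
        out["empirical_p"] = [0.0002, 0.0004]
        fst = fst_track([110_000], [0.02])       # p >= 0.01: fails the gate
        assert popsel.call_composite_regions(out, fst) == []

    def test_clusters_split_at_max_gap(self):
        pos = [100_000, 150_000, 500_000, 520_000]
        out = snp_track(pos, [5.0] * 4)
        out["empirical_p"] = [0.0005] * 4
        fst = fst_track(pos, [0.001] * 4)
        regions = popsel.call_composite_regions(out, fst, max_gap_bp=200_000)
        assert len(regions) == 2
        regions1 = popsel.call_composite_regions(out, fst, max_gap_bp=400_000)
        assert len(regions1) == 1

    def test_input_order_invariance_and_idempotence(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(10_000_000, 40, replace=False))
        out = snp_track(pos, rng.normal(size=40))
        out["empirical_p"] = rng.random(40) / 500
        fst = fst_track(pos, rng.random(40) * 0.02)
        a = popsel.call_composite_regions(out, fst)
        shuffled = out.sample(frac=1, random_state=0)
        b = popsel.call_composite_regions(shuffled, fst)
        assert [(r.chrom, r.start, r.end, r.n_members) for r in a] == \
               [(r.chrom, r.start, r.end, r.n_members) for r in b]

    def test_sweep_region_called_and_revalidates(self, sweep_cohort):
        """End-to-end: the caller's output satisfies the verbatim predicate."""
        hm = sweep_cohort.haplotypes
        gm = hm.to_genotypes()
        track = popsel.xpehh_scan(hm.subset_population("sweep"),
                                  hm.subset_population("neutral")).table
        out = popsel.xpehh_outliers(track)
        fst = popsel.wc_fst_per_snp(gm, "sweep", "neutral").table
        fst = fst.assign(empirical_p=popsel.empirical_p(
            fst["theta_clamped"].to_numpy(), direction="high"))
        regions = popsel.call_composite_regions(out, fst)
        assert len(regions) >= 1
        for r in regions:
            members = out[(out.chrom == r.chrom) & (out.pos >= r.start)
                          & (out.pos <= r.end)]
            assert len(members) >= 2
            span = fst[(fst.chrom == r.chrom) & (fst.pos >= r.start)
                       & (fst.pos <= r.end)]
            assert (span["empirical_p"] < 0.01).any()


class TestTajimaRegions:
    def test_consecutive_window_coordinate_arithmetic(self):
        """k consecutive 100-kb windows at 10-kb step: end = start + 100k
        + (k-1)*10k - 1, reproducing the published region coordinates."""
        starts = [35_818_960 + 10_000 * i for i in range(4)]
        win = window_track(starts, 100_000, [0.001] * 4)
        regions = popsel.call_tajima_regions(win)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (35_818_960, 35_948_959)
        assert regions[0].n_members == 4
        assert regions[0].end - regions[0].start + 1 == 130_000

        starts = [48_357_093 + 10_000 * i for i in range(3)]
        regions = popsel.call_tajima_regions(
            window_track(starts, 100_000, [0.0005] * 3))
        assert (regions[0].start, regions[0].end) == (48_357_093, 48_477_092)
        assert regions[0].n_members == 3

    def test_single_window_region_length(self):
        regions = popsel.call_tajima_regions(
            window_track([1_000_001], 100_000, [0.002]))
        assert regions[0].end - regions[0].start + 1 == 100_000

    def test_distant_windows_stay_separate(self):
        win = window_track([1_000_001, 2_000_001], 100_000, [0.001, 0.001])
        assert len(popsel.call_tajima_regions(win)) == 2

    def test_non_significant_windows_ignored(self):
        win = window_track([1_000_001, 1_010_001], 100_000, [0.5, 0.02])
        assert popsel.call_tajima_regions(win) == []


class TestRegionOverlap:
    def _regions(self, spans, label):
        return [popsel.CandidateRegion("1", s, e, 2, 0.001, label)
                for s, e in spans]

    def test_identical_lists_fully_shared(self):
        a = self._regions([(1, 100), (500, 600)], "A")
        b = self._regions([(1, 100), (500, 600)], "B")
        ov = popsel.region_overlap({"A": a, "B": b})
        assert ov.unique_counts == {"A": 0, "B": 0}
        assert ov.venn_cells == {frozenset({"A", "B"}): 2}

    def test_disjoint_lists_all_unique(self):
        a = self._regions([(1, 100)], "A")
        b = self._regions([(200, 300)], "B")
        ov = popsel.region_overlap({"A": a, "B": b})
        assert ov.unique_counts == {"A": 1, "B": 1}
        assert ov.n_shared == 0

    def test_toy_interval_arithmetic(self):
        """A: [1-100], [500-600]; B: [90-120] -> 1 shared, A-unique 1."""
        a = self._regions([(1, 100), (500, 600)], "A")
        b = self._regions([(90, 120)], "B")
        ov = popsel.region_overlap({"A": a, "B": b})
        assert ov.unique_counts == {"A": 1, "B": 0}
        assert ov.venn_cells[frozenset({"A", "B"})] == 1

    def test_different_chromosomes_never_overlap(self):
        a = [popsel.CandidateRegion("1", 1, 100, 2, 0.01, "A")]
        b = [popsel.CandidateRegion("2", 1, 100, 2, 0.01, "B")]
        ov = popsel.region_overlap({"A": a, "B": b})
        assert ov.n_shared == 0


class TestAnnotateRegions:
    GENES = pd.DataFrame({
        "chrom": ["1", "1", "1", "1"],
        "start": [1000, 5000, 5200, 9000],
        "end": [2000, 6000, 5400, 9500],
        "name": ["GENE1", "GENE2", "GENE2B", "GENE3"],
    })

    def test_containing_region_lists_gene(self):
        r = popsel.CandidateRegion("1", 900, 2100, 2, 0.001)
        (_, genes), = popsel.annotate_regions([r], self.GENES)
        assert genes == ["GENE1"]

    def test_intergenic_region_empty(self):
        r = popsel.CandidateRegion("1", 2500, 4000, 2, 0.001)
        (_, genes), = popsel.annotate_regions([r], self.GENES)
        assert genes == []

    def test_nested_genes_both_listed(self):
        r = popsel.CandidateRegion("1", 4900, 6100, 2, 0.001)
        (_, genes), = popsel.annotate_regions([r], self.GENES)
        assert genes == ["GENE2", "GENE2B"]
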