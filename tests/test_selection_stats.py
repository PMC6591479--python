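"""W&C F_ST vs an independent oracle, EHH combinatorics, XP-EHH, Tajima's D."""

import numpy as np
import pandas as pd
import pytest

import popsel
from popsel.selection_stats import wc_fst_components

from conftest import make_genotype_matrix, make_haplotype_matrix


# ---------------------------------------------------------------------------
# Independent single-SNP oracle for the Weir & Cockerham (1984) estimator,
# transcribed directly from the published two-allele formulas with r = 2
# substituted and written scalar-by-scalar (no shared code with the package).
# ---------------------------------------------------------------------------

def wc_oracle_single_snp(n1, n_het1, n_alt1, n2, n_het2, n_alt2):
    """theta-hat components for one SNP from raw counts of two samples.

    n_i: diploids sampled; n_het_i: heterozygotes; n_alt_i: alt alleles.
    """
    p1 = n_alt1 / (2 * n1)
    p2 = n_alt2 / (2 * n2)
    h1 = n_het1 / n1
    h2 = n_het2 / n2
    nbar = (n1 + n2) / 2
    nc = 2 * nbar - (n1 * n1 + n2 * n2) / (2 * nbar)
    pbar = (n1 * p1 + n2 * p2) / (2 * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    hbar = (n1 * h1 + n2 * h2) / (2 * nbar)
    a = (nbar / nc) * (s2 - (1 / (nbar - 1))
                       * (pbar * (1 - pbar) - s2 / 2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2
                               - ((2 * nbar - 1) / (4 * nbar)) * hbar)
    c = hbar / 2
    return a, b, c


def random_count_config(rng):
    n1 = int(rng.integers(5, 60))
    n2 = int(rng.integers(5, 60))
    while True:
        het1 = int(rng.integers(0, n1 + 1))
        hom_alt1 = int(rng.integers(0, n1 - het1 + 1))
        het2 = int(rng.integers(0, n2 + 1))
        hom_alt2 = int(rng.integers(0, n2 - het2 + 1))
        alt1 = het1 + 2 * hom_alt1
        alt2 = het2 + 2 * hom_alt2
        if 0 < alt1 + alt2 < 2 * (n1 + n2):    # polymorphic overall
            return n1, het1, alt1, n2, het2, alt2


class TestWcFst:
    def test_matches_independent_oracle_on_random_configs(self):
        """a, b, c agree with the hand-coded single-SNP oracle to 1e-12."""
        rng = np.random.default_rng(100)
        for _ in range(1000):
            n1, het1, alt1, n2, het2, alt2 = random_count_config(rng)
            a_o, b_o, c_o = wc_oracle_single_snp(n1, het1, alt1,
                                                 n2, het2, alt2)
            a, b, c = wc_fst_components(
                np.array([float(n1)]), np.array([alt1 / (2 * n1)]),
                np.array([het1 / n1]), np.array([float(n2)]),
                np.array([alt2 / (2 * n2)]), np.array([het2 / n2]))
            assert a[0] == pytest.approx(a_o, abs=1e-12)
            assert b[0] == pytest.approx(b_o, abs=1e-12)
            assert c[0] == pytest.approx(c_o, abs=1e-12)

    def test_fixed_difference_theta_near_one(self):
        d = np.vstack([np.zeros((20, 5)), np.full((20, 5), 2)]).astype(np.int8)
        gm = make_genotype_matrix(d, pops=["A"] * 20 + ["B"] * 20)
        res = popsel.wc_fst_per_snp(gm, "A", "B")
        a_o, b_o, c_o = wc_oracle_single_snp(20, 0, 0, 20, 0, 40)
        expect = a_o / (a_o + b_o + c_o)
        assert np.allclose(res.table["theta"], expect)
        assert expect > 0.97

    def test_identical_configurations_clamped_to_zero(self):
        rng = np.random.default_rng(101)
        half = rng.binomial(2, 0.5, size=(30, 50)).astype(np.int8)
        d = np.vstack([half, half])
        gm = make_genotype_matrix(d, pops=["A"] * 30 + ["B"] * 30)
        res = popsel.wc_fst_per_snp(gm, "A", "B")
        assert (res.table["theta_clamped"].dropna() == 0).all()
        assert (res.table["theta"].dropna() <= 0).all()

    def test_negative_estimates_reported_as_zero(self, structured_gm):
        res = popsel.wc_fst_per_snp(structured_gm, "pop1", "pop2")
        t = res.table.dropna(subset=["theta"])
        neg = t[t["theta"] < 0]
        assert len(neg) > 0
        assert (neg["theta_clamped"] == 0).all()

    def test_monomorphic_snp_excluded_from_mean(self):
        d = np.array([[0, 1], [0, 1], [0, 0], [0, 2]], dtype=np.int8)
        gm = make_genotype_matrix(d, pops=["A", "A", "B", "B"])
        res = popsel.wc_fst_per_snp(gm, "A", "B")
        assert np.isnan(res.table["theta"].iloc[0])
        assert np.isfinite(res.mean_fst)


class TestPairwiseMeanFst:
    def test_six_small_pops_low_fst_magnitude(self):
        """F = 0.002 across six pops of 60: estimates ~ the target scale."""
        spec = popsel.SimSpec(n_pops=6, samples_per_pop=60, n_variants=5000,
                              fst_target=0.002, seed=102)
        gm, _ = popsel.simulate_structured_genotypes(spec)
        m = popsel.pairwise_mean_fst(gm)
        off = m.to_numpy()[np.triu_indices(6, 1)]
        assert np.all(off > 0.0005) and np.all(off < 0.005)

    def test_symmetric_zero_diagonal_order_invariant(self, structured_gm):
        m = popsel.pairwise_mean_fst(structured_gm)
        assert np.allclose(m, m.T) and np.allclose(np.diag(m), 0)
        perm = np.random.default_rng(1).permutation(structured_gm.n_samples)
        m2 = popsel.pairwise_mean_fst(structured_gm.take_samples(perm))
        pd.testing.assert_frame_equal(m.sort_index(axis=0).sort_index(axis=1),
                                      m2.sort_index(axis=0).sort_index(axis=1))

    def test_tiny_population_rejected(self):
        d = np.zeros((3, 10), dtype=np.int8)
        gm = make_genotype_matrix(d, pops=["A", "A", "B"])
        with pytest.raises(ValueError, match=">= 2"):
            popsel.pairwise_mean_fst(gm)


class TestEhh:
    def test_ehh_at_core_is_one(self, sweep_cohort):
        prof = popsel.ehh_profile(sweep_cohort.haplotypes, 100,
                                  direction="right")
        assert prof.ehh[0] == 1.0

    def test_four_haplotype_split_combinatorics(self):
        """Groups (2,1,1) at distance d: EHH = C(2,2)/C(4,2) = 1/6."""
        alleles = np.array([
            [0, 0, 0],
            [0, 0, 0],
            [0, 1, 0],
            [0, 0, 1],
        ])
        hm = make_haplotype_matrix(alleles)
        prof = popsel.ehh_profile(hm, 0, direction="right")
        # after the second SNP: groups {0,1,3} vs {2} -> (3,1): EHH = 3/6
        assert prof.ehh[1] == pytest.approx(3 / 6)
        # after the third SNP: groups {0,1},{2},{3} -> (2,1,1): EHH = 1/6
        assert prof.ehh[2] == pytest.approx(1 / 6)

    def test_non_increasing_and_order_invariant(self, sweep_cohort):
        hm = sweep_cohort.haplotypes
        rng = np.random.default_rng(103)
        for core in rng.integers(10, hm.n_variants - 10, size=5):
            prof = popsel.ehh_profile(hm, int(core), direction="left")
            assert np.all(np.diff(prof.ehh) <= 1e-12)
            perm = rng.permutation(hm.n_haplotypes)
            prof_p = popsel.ehh_profile(hm, int(core), haplotype_subset=perm,
                                        direction="left")
            np.testing.assert_allclose(prof.ehh, prof_p.ehh)

    def test_ihh_is_trapezoid_integral(self):
        alleles = np.array([[0, 0], [0, 0], [0, 1], [0, 1]])
        hm = make_haplotype_matrix(alleles, positions=[1000, 2000])
        prof = popsel.ehh_profile(hm, 0, direction="right", cutoff=0.0)
        # EHH: 1 at core, (C(2,2)+C(2,2))/C(4,2)=1/3 after 1000 bp
        assert prof.ihh == pytest.approx(0.5 * (1 + 1 / 3) * 1000)


class TestXpehh:
    def test_identical_populations_score_zero(self, sweep_cohort):
        hm = sweep_cohort.haplotypes.subset_population("sweep")
        track = popsel.xpehh_scan(hm, hm)
        raw = track.table["raw"].dropna()
        assert np.allclose(raw, 0.0)

    def test_sign_flips_when_populations_swap(self, sweep_cohort):
        a = sweep_cohort.haplotypes.subset_population("sweep")
        b = sweep_cohort.haplotypes.subset_population("neutral")
        ab = popsel.xpehh_scan(a, b).table
        ba = popsel.xpehh_scan(b, a).table
        np.testing.assert_allclose(ab["raw"].to_numpy(),
                                   -ba["raw"].to_numpy(), atol=1e-12)

    def test_standardization_exact(self, sweep_cohort):
        a = sweep_cohort.haplotypes.subset_population("sweep")
        b = sweep_cohort.haplotypes.subset_population("neutral")
        std = popsel.xpehh_scan(a, b).table["std"].dropna()
        assert abs(std.mean()) < 1e-12
        assert abs(std.std(ddof=0) - 1) < 1e-12

    def test_sweep_scores_extreme_inside_true_interval(self, sweep_cohort):
        """Standardized XP-EHH > 2 at the injected sweep (the flagged scale)."""
        a = sweep_cohort.haplotypes.subset_population("sweep")
        b = sweep_cohort.haplotypes.subset_population("neutral")
        tab = popsel.xpehh_scan(a, b).table
        lo, hi = sweep_cohort.sweep_interval
        inside = tab[(tab.pos >= lo) & (tab.pos <= hi)]
        assert inside["std"].max() > 2.0


class TestTajimaD:
    def test_hand_computed_example(self):
        """n=4 haplotypes, derived counts (1,2,2): pi=22/12, theta_W=18/11."""
        alleles = np.array([
            [1, 1, 0],
            [0, 1, 0],
            [0, 0, 1],
            [0, 0, 1],
        ])
        hm = make_haplotype_matrix(alleles, positions=[10, 20, 30])
        win = popsel.tajima_d_windows(hm, window=100, step=100)
        row = win[~win["skipped"]].iloc[0]
        assert row["pi"] == pytest.approx(22 / 12)
        assert row["theta_w"] == pytest.approx(18 / 11)
        assert row["D"] == pytest.approx(1.0897626677, abs=1e-6)

    def test_empty_and_sparse_windows_skipped(self):
        alleles = np.array([[1, 0], [0, 0], [0, 0], [0, 0]])
        hm = make_haplotype_matrix(alleles, positions=[100, 150_000])
        win = popsel.tajima_d_windows(hm, window=100_000, step=100_000)
        assert win["skipped"].all()
        assert "fewer_than_2_segregating_sites" in set(win["reason"])

    def test_window_with_missing_genotypes_ignored(self):
        d = np.array([[0, 1], [1, -1], [2, 1], [1, 0]], dtype=np.int8)
        gm = make_genotype_matrix(d, positions=[100, 60_000])
        win = popsel.tajima_d_windows(gm, window=100_000, step=100_000)
        assert win.iloc[0]["reason"] == "missing_genotypes"

    def test_neutral_simulation_mean_near_zero(self, neutral_cohort):
        hm = neutral_cohort.haplotypes.subset_population("neutral")
        win = popsel.tajima_d_windows(hm)
        d = win.loc[~win["skipped"], "D"]
        assert len(d) > 100
        assert -0.3 < d.mean() < 0.3

    def test_sweep_windows_more_negative_than_neutral(self, sweep_cohort):
        """Post-sweep windows show the expected rare-variant excess."""
        hm = sweep_cohort.haplotypes
        lo, hi = sweep_cohort.sweep_interval
        win = popsel.tajima_d_windows(hm.subset_population("sweep"))
        ok = win[~win["skipped"]]
        inside = ok[(ok.end >= lo - 50_000) & (ok.start <= hi + 50_000)]["D"]
        outside = ok[(ok.end < lo - 200_000) | (ok.start > hi + 200_000)]["D"]
        assert inside.mean() < outside.mean() - outside.std()

    def test_matches_tskit_on_msprime_data(self):
        """Cross-check the whole-window statistic against tskit."""
        msprime = pytest.importorskip("msprime")
        ts = msprime.sim_ancestry(samples=25, sequence_length=100_000,
                                  recombination_rate=1e-8,
                                  population_size=10_000, random_seed=7)
        ts = msprime.sim_mutations(ts, rate=1e-8, random_seed=7,
                                   model=msprime.BinaryMutationModel())
        g = ts.genotype_matrix().T
        positions = np.array([int(s.position) + 1 for s in ts.sites()])
        keep = np.r_[True, np.diff(positions) > 0] & (g.max(axis=0) <= 1)
        assert keep.all(), "fixture should be biallelic at unique positions"
        hm = make_haplotype_matrix(g.astype(np.uint8), positions=positions)
        win = popsel.tajima_d_windows(hm, window=100_000, step=100_000)
        mine = win[~win["skipped"]].iloc[0]["D"]
        theirs = ts.Tajimas_D()
        assert mine == pytest.approx(float(theirs), abs=1e-6)
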