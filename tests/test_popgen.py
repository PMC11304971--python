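import numpy as np
import pytest

from helpers import brute_force_site_pi
from sexscaff import popgen as pg
from sexscaff import synthetic_data as sd
from sexscaff.core import Interval, RegionClass, Sex, VariantTable


def make_table(chrom, pos, gts, sexes, qual=None, gq=None, dp=None):
    """gts: list per site of list per sample of (a, b) allele tuples."""
    n, k = len(pos), len(sexes)
    gt = np.array(gts, dtype=np.int8).reshape(n, k, 2)
    return VariantTable(
        chrom=np.array([chrom] * n, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["T"] * n, dtype=object),
        qual=np.array(qual if qual is not None else [100.0] * n, dtype=float),
        samples=[f"s{i}" for i in range(k)],
        sample_sex=list(sexes),
        gt=gt,
        gq=np.array(gq if gq is not None else np.full((n, k), 99), dtype=np.int16),
        dp=np.array(dp if dp is not None else np.full((n, k), 20), dtype=np.int16),
    )


MM = [Sex.MALE, Sex.MALE]


class TestFilterVariants:
    def test_low_qual_site_dropped(self):
        t = make_table("c", [10, 20], [[(0, 1)], [(0, 1)]], [Sex.FEMALE], qual=[25.0, 100.0])
        out, rep = pg.filter_variants(t, pg.FilterConfig(min_maf=0.0, max_missing=0.0))
        assert out.n_sites == 1 and rep.removed_qual == 1

    def test_low_gq_genotype_set_missing(self):
        t = make_table("c", [10], [[(0, 1), (0, 1)]], [Sex.FEMALE, Sex.FEMALE],
                       gq=[[19, 99]])
        out, rep = pg.filter_variants(t, pg.FilterConfig(min_maf=0.0, max_missing=0.0))
        assert rep.n_genotypes_masked == 1
        assert np.all(out.gt[0, 0] == -1)
        assert np.all(out.gt[0, 1] == [0, 1])

    def test_permissive_config_keeps_everything(self):
        t = make_table("c", [10, 20], [[(0, 1)], [(1, 1)]], [Sex.FEMALE])
        out, rep = pg.filter_variants(
            t, pg.FilterConfig(min_gq=0, min_site_qual=0, min_mean_dp=0.1,
                               max_mean_dp=1e9, min_maf=0.0, max_missing=0.0)
        )
        assert out.n_sites == 2 and rep.n_kept == 2
        np.testing.assert_array_equal(out.gt, t.gt)

    def test_maf_missingness_depth_and_exclusion_rules(self):
        sexes = [Sex.FEMALE] * 5
        t = make_table(
            "c",
            [10, 20, 30, 40],
            [
                [(0, 1)] + [(0, 0)] * 4,        # maf 0.1 < 0.2 -> dropped
                [(0, 1), (0, 1)] + [(-1, -1)] * 3,  # call rate 0.4 < 0.5 -> dropped
                [(0, 1), (0, 1), (0, 0), (1, 1), (0, 1)],  # kept
                [(0, 1), (0, 1), (0, 0), (1, 1), (0, 1)],  # in exclude bed
            ],
            sexes,
        )
        cfg = pg.FilterConfig(min_maf=0.2, max_missing=0.5,
                              exclude_bed=(Interval("c", 35, 45),))
        out, rep = pg.filter_variants(t, cfg)
        assert list(out.pos) == [30]
        assert (rep.removed_maf, rep.removed_missing, rep.removed_excluded) == (1, 1, 1)

    def test_rule_order_independence(self):
        rng = np.random.default_rng(0)
        n, k = 200, 6
        gt = rng.choice([0, 1], size=(n, k, 2)).astype(np.int8)
        gt[rng.random((n, k)) < 0.3] = -1
        t = make_table("c", list(range(10, 10 + n)), gt, [Sex.FEMALE] * k,
                       qual=rng.uniform(0, 200, n),
                       dp=rng.integers(0, 50, (n, k)))
        full = pg.FilterConfig(min_maf=0.1, max_missing=0.5)
        joint, _ = pg.filter_variants(t, full)
        # sequential single-rule application in two different orders
        perm_base = dict(min_gq=0, min_site_qual=0, min_mean_dp=1e-9,
                         max_mean_dp=1e9, min_maf=0.0, max_missing=0.0)
        rules = [
            dict(min_gq=full.min_gq),
            dict(min_site_qual=full.min_site_qual),
            dict(min_mean_dp=full.min_mean_dp, max_mean_dp=full.max_mean_dp),
            dict(min_maf=full.min_maf),
            dict(max_missing=full.max_missing),
        ]

        def apply_seq(order):
            cur = t
            for r in order:
                cfg = pg.FilterConfig(**{**perm_base, **r})
                cur, _ = pg.filter_variants(cur, cfg)
            return cur

        fwd = apply_seq(rules)
        rev = apply_seq(rules[::-1])
        assert list(fwd.pos) == list(rev.pos) == list(joint.pos)


class TestWindowedPi:
    def test_one_difference_between_two_haploids(self):
        t = make_table("c", [500], [[(0, -2), (1, -2)]], MM)
        (w,) = pg.windowed_pi(t, contig_lengths={"c": 100_000})
        assert w.pi == pytest.approx(1e-5)
        assert w.n_sites_used == 1

    def test_monomorphic_window_is_zero(self):
        t = make_table("c", [500], [[(0, -2), (0, -2)]], MM)
        (w,) = pg.windowed_pi(t, contig_lengths={"c": 100_000})
        assert w.pi == 0.0

    def test_total_pi_conserved_across_window_sizes(self):
        rng = np.random.default_rng(1)
        pos = sorted(rng.choice(range(1, 200_001), size=80, replace=False))
        gts = rng.choice([0, 1], size=(80, 4, 2)).astype(np.int8)
        t = make_table("c", pos, gts, [Sex.FEMALE] * 4)
        w100 = pg.windowed_pi(t, contig_lengths={"c": 200_000}, window=100_000)
        w50 = pg.windowed_pi(t, contig_lengths={"c": 200_000}, window=50_000)
        tot100 = sum(w.pi * (w.end - w.start + 1) for w in w100)
        tot50 = sum(w.pi * (w.end - w.start + 1) for w in w50)
        assert tot50 == pytest.approx(tot100)

    def test_matches_brute_force_pairwise_oracle(self):
        # every diploid genotype configuration for 3 samples (<= 6 copies)
        rng = np.random.default_rng(2)
        for trial in range(30):
            k = int(rng.integers(2, 4))
            n_sites = int(rng.integers(1, 6))
            gts = rng.choice([0, 1], size=(n_sites, k, 2)).astype(np.int8)
            pos = sorted(rng.choice(range(1, 99_999), size=n_sites, replace=False))
            t = make_table("c", pos, gts, [Sex.FEMALE] * k)
            (w,) = pg.windowed_pi(t, contig_lengths={"c": 100_000})
            expected = sum(
                brute_force_site_pi(gts[i].ravel()) for i in range(n_sites)
            ) / 100_000
            assert w.pi == pytest.approx(expected)

    def test_ploidy_violation_rejected(self):
        t = make_table("slr", [500], [[(0, 1), (0, -2)]], MM)
        with pytest.raises(ValueError, match="ploidy|haploid"):
            pg.windowed_pi(
                t,
                haploid_male_intervals=(Interval("slr", 1, 1000),),
                contig_lengths={"slr": 100_000},
            )

    def test_terminal_short_window_flagged_and_rescaled(self):
        t = make_table("c", [120_001], [[(0, 1)]], [Sex.FEMALE])
        wins = pg.windowed_pi(t, contig_lengths={"c": 150_000})
        assert len(wins) == 2
        assert wins[1].short_window
        assert wins[1].pi == pytest.approx(1.0 / 50_000)

    def test_haploid_slr_pi_below_forced_diploid_on_xy_mixed_genotypes(self):
        # v7-style mosaic reference: male 'diploid' SLR genotypes pair the X
        # and the diverged Y allele, inflating heterozygosity; haploid calling
        # keeps only the X copy.
        rng = np.random.default_rng(3)
        n_sites, n_males = 400, 6
        x_alleles = (rng.random((n_sites, n_males)) < 0.1).astype(np.int8)
        y_allele = (rng.random((n_sites, 1)) < 0.5).astype(np.int8)  # X-Y divergence
        y_alleles = np.repeat(y_allele, n_males, axis=1)
        pos = sorted(rng.choice(range(1, 100_000), size=n_sites, replace=False))
        hap = np.stack([x_alleles, np.full_like(x_alleles, -2)], axis=2)
        dip = np.stack([x_alleles, y_alleles], axis=2)
        sexes = [Sex.MALE] * n_males
        t_hap = make_table("slr", pos, hap, sexes)
        t_dip = make_table("slr", pos, dip, sexes)
        pi_hap = pg.windowed_pi(t_hap, contig_lengths={"slr": 100_000})[0].pi
        pi_dip = pg.windowed_pi(t_dip, contig_lengths={"slr": 100_000})[0].pi
        assert pi_hap <= pi_dip

    def test_compartment_intervals_partition_windows(self):
        t = make_table("lg12", [50, 150_000], [[(0, 1)], [(0, 1)]], [Sex.FEMALE])
        wins = pg.windowed_pi(
            t,
            contig_lengths={"lg12": 200_000},
            compartment_intervals=[
                (Interval("lg12", 1, 100_000), pg.Compartment.SLR),
                (Interval("lg12", 100_001, 200_000), pg.Compartment.PAR),
            ],
        )
        assert [w.compartment for w in wins] == [pg.Compartment.SLR, pg.Compartment.PAR]


class TestCompartmentTests:
    def test_identical_vectors_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = pg.paired_compartment_test(a, a.copy(), "same_vs_same")
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_small_shift_detected_across_populations(self):
        rng = np.random.default_rng(4)
        base = 0.001 + rng.normal(0, 1e-5, size=6)
        shifted = base + 5e-4 + rng.normal(0, 1e-5, size=6)
        res = pg.paired_compartment_test(shifted, base, "shifted_vs_base")
        assert res.p_value < 0.05
        assert res.significant

    def test_constant_nonzero_differences_fall_back_to_signed_rank(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.warns(UserWarning):
            res = pg.paired_compartment_test(a + 0.5, a, "const_shift")
        assert res.test_used is pg.TestKind.WILCOXON_SIGNED_RANK

    def test_non_normal_differences_use_wilcoxon(self):
        rng = np.random.default_rng(5)
        a = np.exp(rng.normal(0, 2, size=40))  # heavily skewed differences
        b = np.zeros(40)
        res = pg.paired_compartment_test(a, b, "skewed")
        assert res.test_used is pg.TestKind.WILCOXON_SIGNED_RANK

    def test_unequal_pairing_rejected(self):
        with pytest.raises(ValueError):
            pg.paired_compartment_test(np.ones(4), np.ones(5), "bad")

    def test_compartment_means_compared_pairwise(self, small_layout):
        table = sd.simulate_variants(small_layout, 2e-3, 4, 4, seed=31)
        comp_of = {
            c.contig_id: (pg.Compartment.Y if c.true_class is RegionClass.Y else pg.Compartment.AUTOSOME)
            for c in small_layout.contigs
        }
        by_pop = {}
        for i, pop in enumerate(["p1", "p2", "p3", "p4"]):
            tab = sd.simulate_variants(small_layout, 2e-3, 4, 4, seed=40 + i)
            wins = pg.windowed_pi(
                tab, contig_lengths=small_layout.contig_lengths, compartment_of=comp_of
            )
            by_pop[pop] = {}
            for w in wins:
                by_pop[pop].setdefault(w.compartment, []).append(w)
        results = pg.compartment_tests(by_pop)
        assert len(results) == 1
        assert results[0].n_pairs == 4
        assert 0 <= results[0].p_value <= 1


class TestNeutralExpectation:
    def test_three_quarters_for_x(self):
        assert pg.neutral_expectation(0.00042, "X") == pytest.approx(0.000315)

    def test_one_quarter_for_y(self):
        assert pg.neutral_expectation(0.00084, "Y") == pytest.approx(0.00021)

    def test_zero_input_gives_zero(self):
        assert pg.neutral_expectation(0.0, "X") == 0.0
        assert pg.neutral_expectation(0.0, "Y") == 0.0

    def test_unknown_compartment_rejected(self):
        with pytest.raises(ValueError):
            pg.neutral_expectation(0.001, "AUTOSOME")
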