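import itertools
import math

import numpy as np
import pytest

from scatpop.diversity import (allelic_richness, exp_het_unbiased, fis_wc,
                               hwe_exact_test, ld_permutation_test,
                               locus_stats_table, null_allele_freq, obs_het)
from scatpop.genodata import GenodataError, GenotypeTable, Locus, allele_frequencies
from .conftest import toy_table


def rarefaction_bruteforce(allele_counts: dict[int, int], g: int) -> float:
    """Mean distinct-allele count over all C(2N, 2g) gene subsets."""
    genes = [a for a, c in allele_counts.items() for _ in range(c)]
    labelled = [len({genes[i] for i in combo})
                for combo in itertools.combinations(range(len(genes)), 2 * g)]
    return float(np.mean(labelled))


class TestHeterozygosity:
    def test_obs_het_counting(self):
        gt = toy_table({"i1": {"L": (1, 2)}, "i2": {"L": (1, 1)}})
        assert obs_het(gt, "L") == 0.5

    def test_all_homozygous(self):
        gt = toy_table({"i1": {"L": (1, 1)}, "i2": {"L": (2, 2)}})
        assert obs_het(gt, "L") == 0.0

    def test_unbiased_he_arithmetic(self):
        assert exp_het_unbiased({1: 0.5, 2: 0.5}, 10) == pytest.approx(20 / 19 * 0.5)

    def test_monomorphic_he_zero(self):
        assert exp_het_unbiased({1: 1.0}, 5) == 0.0

    def test_he_exceeds_biased_form(self):
        f = {1: 0.6, 2: 0.4}
        for n in (2, 5, 50):
            assert exp_het_unbiased(f, n) > 1 - (0.36 + 0.16)

    def test_single_individual_is_error(self):
        with pytest.raises(GenodataError):
            exp_het_unbiased({1: 0.5, 2: 0.5}, 1)


class TestFis:
    def test_all_homozygotes_gives_one(self):
        gt = toy_table({f"i{k}": {"L": (1, 1)} for k in range(5)}
                       | {f"j{k}": {"L": (2, 2)} for k in range(5)})
        per_locus, multi = fis_wc(gt)
        assert per_locus["L"] == pytest.approx(1.0)
        assert multi == pytest.approx(1.0)

    def test_hwe_proportions_give_near_zero(self):
        # 4 AA, 8 AB, 4 BB half het: exact HW proportions at p = 0.5
        rows = {}
        for k in range(4):
            rows[f"aa{k}"] = {"L": (1, 1)}
            rows[f"bb{k}"] = {"L": (2, 2)}
        for k in range(8):
            rows[f"ab{k}"] = {"L": (1, 2)}
        _, multi = fis_wc(toy_table(rows))
        assert abs(multi) < 0.05

    def test_monomorphic_excluded(self):
        gt = toy_table({"i1": {"A": (1, 1), "B": (1, 2)},
                        "i2": {"A": (1, 1), "B": (1, 1)}})
        per_locus, multi = fis_wc(gt)
        assert math.isnan(per_locus["A"])
        assert not math.isnan(multi)

    def test_random_mating_population_near_zero(self):
        rng = np.random.default_rng(77)
        rows = {}
        loci = [f"L{i}" for i in range(10)]
        freqs = {l: rng.dirichlet(np.ones(5)) for l in loci}
        for k in range(200):
            rows[f"i{k}"] = {
                l: tuple(sorted(rng.choice(5, size=2, p=freqs[l]) + 1))
                for l in loci}
        _, multi = fis_wc(toy_table(rows))
        assert abs(multi) < 0.03


class TestAllelicRichness:
    def test_monomorphic_is_one(self):
        assert allelic_richness({1: 20}, 5) == pytest.approx(1.0)

    def test_two_even_alleles_g1(self):
        # C(10,2)/C(20,2) miss probability per allele
        assert allelic_richness({1: 10, 2: 10}, 1) == pytest.approx(2 - 2 * 45 / 190)

    def test_full_sample_returns_observed_count(self):
        counts = {1: 7, 2: 9, 3: 4}
        assert allelic_richness(counts, 10) == pytest.approx(3.0)

    @pytest.mark.parametrize("counts,g", [
        ({1: 10, 2: 10}, 1),
        ({1: 10, 2: 10}, 3),
        ({1: 5, 2: 3, 3: 2}, 2),
        ({1: 14, 2: 2, 3: 2, 4: 2}, 4),
    ])
    def test_matches_exhaustive_enumeration(self, counts, g):
        assert allelic_richness(counts, g) == pytest.approx(
            rarefaction_bruteforce(counts, g), abs=1e-12)

    def test_monotone_in_g(self):
        counts = {1: 8, 2: 6, 3: 4, 4: 2}
        vals = [allelic_richness(counts, g) for g in range(1, 11)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(4.0)

    def test_g_beyond_sample_is_error(self):
        with pytest.raises(GenodataError):
            allelic_richness({1: 4, 2: 4}, 5)


class TestNullAlleles:
    def test_equal_heterozygosities_give_zero(self):
        assert null_allele_freq(0.5, 0.5) == 0.0

    def test_chakraborty_arithmetic(self):
        assert null_allele_freq(0.6, 0.3, "chakraborty") == pytest.approx(1 / 3)

    def test_brookfield_arithmetic(self):
        assert null_allele_freq(0.6, 0.3, "brookfield1") == pytest.approx(0.1875)

    def test_heterozygote_excess_is_negative(self):
        assert null_allele_freq(0.5, 0.7) < 0

    def test_undefined_when_both_zero(self):
        with pytest.raises(GenodataError):
            null_allele_freq(0.0, 0.0, "chakraborty")


class TestHweExact:
    def test_two_by_two_enumeration(self):
        # alleles A=2, B=2 over two individuals: tables {AA,BB} (P=1/3)
        # and {AB,AB} (P=2/3)
        gt = toy_table({"i1": {"L": (1, 1)}, "i2": {"L": (2, 2)}})
        assert hwe_exact_test(gt, "L", mode="enumerate") == pytest.approx(1 / 3)
        gt2 = toy_table({"i1": {"L": (1, 2)}, "i2": {"L": (1, 2)}})
        assert hwe_exact_test(gt2, "L", mode="enumerate") == pytest.approx(1.0)

    def test_enumerate_and_mc_agree(self):
        rng = np.random.default_rng(5)
        rows = {}
        freqs = np.array([0.5, 0.3, 0.2])
        for k in range(30):
            rows[f"i{k}"] = {"L": tuple(sorted(rng.choice(3, size=2, p=freqs) + 1))}
        gt = toy_table(rows)
        p_enum = hwe_exact_test(gt, "L", mode="enumerate")
        p_mc = hwe_exact_test(gt, "L", mode="mc", n_mc=20000, seed=1)
        assert p_mc == pytest.approx(p_enum, abs=0.02)

    def test_monomorphic_is_error(self):
        gt = toy_table({"i1": {"L": (1, 1)}, "i2": {"L": (1, 1)}})
        with pytest.raises(GenodataError):
            hwe_exact_test(gt, "L")

    def test_table_space_bound_advises_mc(self):
        rng = np.random.default_rng(2)
        rows = {f"i{k}": {"L": tuple(sorted(rng.integers(1, 15, size=2)))}
                for k in range(200)}
        gt = toy_table(rows)
        with pytest.raises(GenodataError, match="mc"):
            hwe_exact_test(gt, "L", mode="enumerate", max_tables=1000)

    def test_strong_heterozygote_deficit_detected(self):
        rows = {f"a{k}": {"L": (1, 1)} for k in range(15)}
        rows |= {f"b{k}": {"L": (2, 2)} for k in range(15)}
        assert hwe_exact_test(toy_table(rows), "L", mode="enumerate") < 1e-4


class TestLd:
    def test_locus_duplicated_against_itself(self):
        rng = np.random.default_rng(3)
        rows = {}
        for k in range(30):
            c = tuple(sorted(rng.integers(1, 5, size=2)))
            rows[f"i{k}"] = {"A": c, "B": c}
        p = ld_permutation_test(toy_table(rows), "A", "B", n_perm=999, seed=0)
        assert p <= 0.01

    def test_independent_loci_not_flagged(self):
        rng = np.random.default_rng(4)
        ps = []
        for rep in range(10):
            rows = {f"i{k}": {"A": tuple(sorted(rng.integers(1, 4, size=2))),
                              "B": tuple(sorted(rng.integers(1, 4, size=2)))}
                    for k in range(40)}
            ps.append(ld_permutation_test(toy_table(rows), "A", "B",
                                          n_perm=199, seed=rep))
        assert np.mean(np.array(ps) < 0.05) <= 0.2
        assert np.mean(ps) > 0.3

    def test_zero_permutations_is_error(self):
        gt = toy_table({f"i{k}": {"A": (1, 2), "B": (1, 2)} for k in range(6)})
        with pytest.raises(GenodataError):
            ld_permutation_test(gt, "A", "B", n_perm=0)

    def test_insufficient_overlap_is_error(self):
        gt = toy_table({"i1": {"A": (1, 2), "B": (1, 2)},
                        "i2": {"A": (1, 2)}})
        with pytest.raises(GenodataError):
            ld_permutation_test(gt, "A", "B")


class TestLocusStatsTable:
    def test_report_shape_and_ranges(self, truth_default):
        gt = truth_default.genotype_table(include_sexing=False)
        df = locus_stats_table(gt, rarefaction_g=8, hwe_mode="mc", seed=0)
        body = df.drop(index="mean")
        assert (body["n_alleles"] >= 1).all()
        assert body["ho"].between(0, 1).all()
        assert body["he"].between(0, 1).all()
        assert (body["ar"] <= body["n_alleles"] + 1e-9).all()
        assert df.loc["mean", "he"] == pytest.approx(body["he"].mean())
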