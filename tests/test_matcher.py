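import itertools
import math

import numpy as np
import pytest

from scatpop.genodata import allele_frequencies
from scatpop.matcher import (MatchConfig, SexRule, assign_sex,
                             cluster_individuals, pairwise_mismatch,
                             pid_naive_locus, pid_sib_locus,
                             pid_unbiased_locus, shared_allele_count)
from scatpop import synthsim as sim
from .conftest import toy_table


class TestPairwiseMismatch:
    def test_identical(self):
        g = {f"L{i}": (100, 104) for i in range(10)}
        assert pairwise_mismatch(g, g) == (0, 10)

    def test_one_allele_size_shift(self):
        g1 = {"A": (120, 124), "B": (1, 2)}
        g2 = {"A": (120, 126), "B": (1, 2)}
        assert pairwise_mismatch(g1, g2) == (1, 2)

    def test_disjoint_homozygote_vs_heterozygote_counts_two(self):
        assert pairwise_mismatch({"A": (120, 120)}, {"A": (124, 126)}) == (2, 1)

    def test_missing_loci_skipped(self):
        g1 = {"A": (1, 2), "B": (3, 4)}
        g2 = {"A": (1, 2)}
        assert pairwise_mismatch(g1, g2) == (0, 1)

    def test_symmetry_and_zero_iff_identical(self, truth_default):
        gt = truth_default.genotype_table(include_sexing=False)
        ids = sorted(gt.rows)[:8]
        for a, b in itertools.combinations(ids, 2):
            m_ab = pairwise_mismatch(gt.rows[a], gt.rows[b])
            m_ba = pairwise_mismatch(gt.rows[b], gt.rows[a])
            assert m_ab == m_ba
            if m_ab[0] == 0:
                shared = [l for l in gt.locus_names
                          if gt.rows[a].get(l) and gt.rows[b].get(l)]
                assert all(gt.rows[a][l] == gt.rows[b][l] for l in shared)

    def test_shared_allele_count_multiset(self):
        assert shared_allele_count((1, 1), (1, 2)) == 1
        assert shared_allele_count((1, 2), (1, 2)) == 2
        assert shared_allele_count((1, 1), (2, 2)) == 0
        assert shared_allele_count((1, 2), (2, 3)) == 1


class TestClustering:
    def g(self, *alleles):
        return {f"L{i}": (a, a + 2) for i, a in enumerate(alleles)}

    def test_duplicates_merge_distinct_split(self):
        a = self.g(*(100,) * 8)
        b = self.g(*(200,) * 8)   # mismatch 16 from a
        gt = toy_table({"s1": a, "s2": dict(a), "s3": b})
        inds = cluster_individuals(gt, MatchConfig(max_mismatch=2, min_shared_loci=4))
        assert len(inds) == 2
        members = sorted(tuple(i.sample_ids) for i in inds)
        assert members == [("s1", "s2"), ("s3",)]

    def test_one_allele_shift_merges_within_tolerance(self):
        a = self.g(*(100,) * 8)
        shifted = dict(a, L0=(100, 104))
        gt = toy_table({"s1": a, "s2": shifted})
        inds = cluster_individuals(gt, MatchConfig(max_mismatch=2, min_shared_loci=4))
        assert len(inds) == 1

    def test_zero_tolerance_partitions_exact_genotypes(self):
        a = self.g(*(100,) * 8)
        shifted = dict(a, L0=(100, 104))
        gt = toy_table({"s1": a, "s2": shifted})
        inds = cluster_individuals(gt, MatchConfig(max_mismatch=0, min_shared_loci=4))
        assert len(inds) == 2

    def test_order_invariance(self, truth_default):
        gt = truth_default.genotype_table(include_sexing=False)
        ids = sorted(gt.rows)
        fwd = cluster_individuals(gt)
        rev_gt = gt.subset(ids=list(reversed(ids)))
        rev = cluster_individuals(rev_gt)
        assert sorted(tuple(i.sample_ids) for i in fwd) == \
            sorted(tuple(i.sample_ids) for i in rev)

    def test_mostly_missing_pairs_not_merged(self):
        a = {"L0": (1, 2)}
        b = {"L0": (1, 2)}
        gt = toy_table({"s1": a, "s2": b})
        inds = cluster_individuals(gt, MatchConfig(max_mismatch=2, min_shared_loci=6))
        assert len(inds) == 2  # only one shared locus: incomparable


def sib_pid_bruteforce(freqs: dict[int, float]) -> float:
    """Enumerate P(two full sibs share a genotype) at one locus under HWE."""
    alleles = list(freqs)
    total = 0.0
    for m in itertools.product(alleles, repeat=2):       # mother's genes
        for f in itertools.product(alleles, repeat=2):   # father's genes
            p_par = freqs[m[0]] * freqs[m[1]] * freqs[f[0]] * freqs[f[1]]
            # each child draws one maternal + one paternal gene
            share = 0.0
            for c1 in itertools.product(m, f):
                for c2 in itertools.product(m, f):
                    if tuple(sorted(c1)) == tuple(sorted(c2)):
                        share += (0.25) * (0.25)
            total += p_par * share
    return total


class TestPid:
    def test_sib_matches_bruteforce_biallelic(self):
        f = {1: 0.5, 2: 0.5}
        assert sib_pid_bruteforce(f) == pytest.approx(0.59375)
        assert pid_sib_locus(f) == pytest.approx(0.59375)

    def test_sib_matches_bruteforce_triallelic(self):
        f = {1: 0.5, 2: 0.3, 3: 0.2}
        assert pid_sib_locus(f) == pytest.approx(sib_pid_bruteforce(f), abs=1e-12)

    def test_naive_direct_evaluation(self):
        f = {1: 0.5, 2: 0.5}
        # sum p^4 + sum (2 p_i p_j)^2 = 2*(1/16) + (1/2)^2
        assert pid_naive_locus(f) == pytest.approx(0.375)

    def test_monomorphic_locus_has_pid_one(self):
        f = {1: 1.0}
        assert pid_sib_locus(f) == pytest.approx(1.0)
        assert pid_naive_locus(f) == pytest.approx(1.0)

    def test_unbiased_tends_to_naive(self):
        f = {1: 0.4, 2: 0.35, 3: 0.25}
        naive = pid_naive_locus(f)
        diffs = [abs(pid_unbiased_locus(f, n) - naive) for n in (10, 100, 10000)]
        assert diffs[0] > diffs[1] > diffs[2]
        assert diffs[2] < 1e-3

    def test_unbiased_undefined_below_four(self):
        with pytest.raises(Exception):
            pid_unbiased_locus({1: 0.5, 2: 0.5}, 3)

    def test_sib_bounds_naive_and_cumulative_decreases(self, truth_default):
        gt = truth_default.genotype_table(include_sexing=False)
        freq = allele_frequencies(gt)
        cum = 1.0
        for l in gt.locus_names:
            f = freq.freqs(l)
            sib = pid_sib_locus(f)
            naive = pid_naive_locus(f)
            assert sib >= naive
            assert 0 < sib <= 1
            if len(f) > 1:
                assert cum * naive < cum  # adding a polymorphic locus shrinks PID
            cum *= naive


class TestSexAssignment:
    RULE = SexRule(y_alleles={"F-AMEL": frozenset({110}), "Z-Zf": frozenset({160})})

    def test_y_allele_means_male(self):
        assert assign_sex({"F-AMEL": (100, 110)}, self.RULE) == "M"

    def test_no_y_with_both_called_means_female(self):
        calls = {"F-AMEL": (100, 100), "Z-Zf": (150, 150)}
        assert assign_sex(calls, self.RULE) == "F"

    def test_missing_loci_unknown(self):
        assert assign_sex({}, self.RULE) == "unknown"
        assert assign_sex({"F-AMEL": (100, 100)}, self.RULE) == "unknown"

    def test_contradiction_warns_and_returns_unknown(self):
        calls = {"F-AMEL": (100, 110), "Z-Zf": (150, 150)}
        with pytest.warns(UserWarning):
            assert assign_sex(calls, self.RULE) == "unknown"

    def test_simulated_sexes_recovered(self, truth_default):
        for t in truth_default.individuals.values():
            assert assign_sex(t.genotype, sim.SEX_RULE) == t.sex


class TestTrueIndividualRecovery:
    def test_error_free_clustering_recovers_distinct_individuals(self, truth_default):
        gt = truth_default.genotype_table(include_sexing=False)
        # restrict to individuals whose true genotypes are separated by more
        # than the mismatch tolerance (close relatives can sit within it)
        keep: list[str] = []
        for i in sorted(gt.rows):
            if all(pairwise_mismatch(gt.rows[i], gt.rows[j])[0] > 2 for j in keep):
                keep.append(i)
        assert len(keep) >= 10
        rows = {}
        for i in keep:
            rows[f"{i}a"] = dict(gt.rows[i])
            rows[f"{i}b"] = dict(gt.rows[i])
        inds = cluster_individuals(toy_table(rows), MatchConfig(max_mismatch=2))
        assert len(inds) == len(keep)
        assert all(len(i.sample_ids) == 2 for i in inds)
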