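"""Per-locus and multilocus microsatellite diversity statistics.

Implements the standard single-population toolkit: observed heterozygosity,
Nei's unbiased expected heterozygosity, the Weir–Cockerham inbreeding
coefficient f (per locus and as a multilocus ratio of summed variance
components), rarefied allelic richness, null-allele frequency estimators,
the Levene/Haldane exact test of Hardy–Weinberg proportions (full
enumeration or Monte-Carlo), and a G-statistic permutation test of
two-locus linkage disequilibrium.

Every statistic uses the per-locus number of genotyped individuals n_l,
not the global sample size: missingness varies by locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genodata import (AlleleFrequencyTable, GenodataError, GenotypeTable,
                       allele_frequencies)


# ---------------------------------------------------------------------------
# heterozygosity

def obs_het(gt: GenotypeTable, locus: str) -> float:
    """Fraction of non-missing genotypes with two distinct alleles."""
    calls = [c for r in gt.rows.values() if (c := r.get(locus)) is not None]
    if not calls:
        raise GenodataError(f"locus {locus}: no genotypes")
    return sum(1 for a, b in calls if a != b) / len(calls)


def exp_het_unbiased(freqs: Mapping[int, float], n: int) -> float:
    """Nei's unbiased gene diversity: (2n / (2n - 1)) * (1 - sum p_i^2)."""
    if n < 2:
        raise GenodataError("unbiased H_E needs n >= 2 genotyped individuals")
    s2 = sum(p ** 2 for p in freqs.values())
    return (2 * n / (2 * n - 1)) * (1.0 - s2)


# ---------------------------------------------------------------------------
# Weir–Cockerham inbreeding coefficient (single population)

def _wc_components_locus(gt: GenotypeTable, locus: str) -> Optional[tuple[float, float]]:
    """Summed (b, c) variance components over alleles at one locus.

    b is the among-individual, c the within-individual (heterozygote)
    component; f = 1 - sum c / sum (b + c).  Returns None for loci that are
    monomorphic or genotyped in < 2 individuals.
    """
    calls = [c for r in gt.rows.values() if (c := r.get(locus)) is not None]
    n = len(calls)
    if n < 2:
        return None
    alleles = sorted({a for c in calls for a in c})
    if len(alleles) < 2:
        return None
    b_sum = 0.0
    c_sum = 0.0
    for al in alleles:
        p = sum(int(a == al) + int(b == al) for a, b in calls) / (2 * n)
        hbar = sum(1 for a, b in calls if (a == al) != (b == al)) / n
        b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * hbar)
        b_sum += b
        c_sum += hbar / 2
    return b_sum, c_sum


def fis_wc(gt: GenotypeTable,
           loci: Optional[Iterable[str]] = None) -> tuple[dict[str, float], float]:
    """Weir–Cockerham f per locus and the multilocus F_IS.

    The multilocus value is the ratio of variance components summed across
    loci (not a mean of per-locus ratios); monomorphic loci are excluded.
    """
    loci = list(loci) if loci is not None else gt.locus_names
    per_locus: dict[str, float] = {}
    B = C = 0.0
    any_def = False
    for l in loci:
        comp = _wc_components_locus(gt, l)
        if comp is None:
            per_locus[l] = float("nan")
            continue
        b, c = comp
        per_locus[l] = 1.0 - c / (b + c) if (b + c) != 0 else float("nan")
        B += b
        C += c
        any_def = True
    if not any_def or (B + C) == 0:
        return per_locus, float("nan")
    return per_locus, 1.0 - C / (B + C)


def fis_simple(he: float, ho: float) -> float:
    """Heuristic 1 - H_O/H_E variant, for sensitivity checks only."""
    if he == 0:
        return float("nan")
    return 1.0 - ho / he


# ---------------------------------------------------------------------------
# rarefied allelic richness

def allelic_richness(allele_counts: Mapping[int, int], g: int) -> float:
    """Expected number of distinct alleles in a random draw of 2g genes.

    ``allele_counts`` are the observed gene counts N_i at a locus genotyped
    in N = (sum N_i)/2 individuals; hypergeometric rarefaction gives
    A_R(g) = sum_i [1 - C(2N - N_i, 2g) / C(2N, 2g)].
    """
    counts = [c for c in allele_counts.values() if c > 0]
    total = sum(counts)
    if total % 2 != 0:
        raise GenodataError("gene counts must sum to an even number")
    N = total // 2
    if not (1 <= g <= N):
        raise GenodataError(f"rarefaction size g={g} outside 1..{N}")
    denom = math.comb(2 * N, 2 * g)
    return sum(1.0 - math.comb(2 * N - c, 2 * g) / denom for c in counts)


# ---------------------------------------------------------------------------
# null alleles

def null_allele_freq(he: float, ho: float, method: str = "chakraborty") -> float:
    """Heterozygote-deficit null-allele frequency estimate.

    chakraborty: (H_E - H_O) / (H_E + H_O); brookfield1: (H_E - H_O) / (1 + H_E).
    Negative values indicate heterozygote excess.
    """
    if not (0 <= he <= 1 and 0 <= ho <= 1):
        raise GenodataError("heterozygosities must lie in [0, 1]")
    if method == "chakraborty":
        if he + ho == 0:
            raise GenodataError("f_null undefined when H_E = H_O = 0")
        return (he - ho) / (he + ho)
    if method == "brookfield1":
        return (he - ho) / (1.0 + he)
    raise GenodataError(f"unknown null-allele method {method!r}")


# ---------------------------------------------------------------------------
# exact test of Hardy-Weinberg proportions

def _genotype_counts(gt: GenotypeTable, locus: str) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = {}
    for r in gt.rows.values():
        c = r.get(locus)
        if c is not None:
            counts[c] = counts.get(c, 0) + 1
    return counts


def _log_table_prob(geno_counts: Mapping[tuple[int, int], int],
                    allele_counts: Mapping[int, int]) -> float:
    """Levene's conditional log-probability of a genotype array given allele counts."""
    n = sum(geno_counts.values())
    h = sum(c for (a, b), c in geno_counts.items() if a != b)
    lp = (math.lgamma(n + 1) + sum(math.lgamma(m + 1) for m in allele_counts.values())
          + h * math.log(2) - math.lgamma(2 * n + 1)
          - sum(math.lgamma(c + 1) for c in geno_counts.values()))
    return lp


def hwe_exact_test(gt: GenotypeTable, locus: str, mode: str = "enumerate",
                   n_mc: int = 10000, seed: Optional[int] = None,
                   max_tables: int = 200_000) -> float:
    """Exact conditional test of Hardy-Weinberg proportions at one locus.

    The p-value sums Levene conditional probabilities of all genotype
    arrays with the observed allele counts that are no more probable than
    the observed array.  ``mode='mc'`` estimates the same quantity by
    random gene pairings.
    """
    obs = _genotype_counts(gt, locus)
    if not obs:
        raise GenodataError(f"locus {locus}: no genotypes")
    alleles = sorted({a for g in obs for a in g})
    if len(alleles) < 2:
        raise GenodataError(f"locus {locus}: monomorphic, HWE test undefined")
    m = {al: sum(c * (int(a == al) + int(b == al)) for (a, b), c in obs.items())
         for al in alleles}
    lp_obs = _log_table_prob(obs, m)
    tol = 1e-9

    if mode == "enumerate":
        acc = 0.0
        count = 0
        for table in _enumerate_tables(alleles, m):
            count += 1
            if count > max_tables:
                raise GenodataError(
                    f"locus {locus}: > {max_tables} genotype tables; use mode='mc'")
            lp = _log_table_prob(table, m)
            if lp <= lp_obs + tol:
                acc += math.exp(lp)
        return min(acc, 1.0)

    if mode == "mc":
        if n_mc < 1:
            raise GenodataError("n_mc must be >= 1")
        rng = np.random.default_rng(seed)
        genes = np.repeat(alleles, [m[a] for a in alleles])
        hits = 0
        for _ in range(n_mc):
            rng.shuffle(genes)
            pairs = genes.reshape(-1, 2)
            table: dict[tuple[int, int], int] = {}
            for a, b in pairs:
                key = (int(a), int(b)) if a <= b else (int(b), int(a))
                table[key] = table.get(key, 0) + 1
            if _log_table_prob(table, m) <= lp_obs + tol:
                hits += 1
        return (1 + hits) / (1 + n_mc)

    raise GenodataError(f"unknown HWE mode {mode!r}")


def _enumerate_tables(alleles: Sequence[int], allele_counts: Mapping[int, int]):
    """Yield all genotype-count tables with the given allele-count margins."""
    k = len(alleles)

    def rec(i: int, remaining: dict[int, int], table: dict[tuple[int, int], int]):
        if i == k:
            if all(v == 0 for v in remaining.values()):
                yield dict(table)
            return
        al = alleles[i]
        r = remaining[al]
        if r == 0:
            yield from rec(i + 1, remaining, table)
            return
        partners = alleles[i:]

        def fill(j: int, left: int):
            if j == len(partners):
                if left == 0:
                    yield from rec(i + 1, remaining, table)
                return
            p = partners[j]
            if p == al:
                max_h = left // 2
                for nh in range(max_h + 1):
                    if nh:
                        table[(al, al)] = nh
                    yield from fill(j + 1, left - 2 * nh)
                    table.pop((al, al), None)
            else:
                cap = min(left, remaining[p])
                for nij in range(cap + 1):
                    key = (al, p) if al <= p else (p, al)
                    if nij:
                        table[key] = nij
                    remaining[p] -= nij
                    yield from fill(j + 1, left - nij)
                    remaining[p] += nij
                    table.pop(key, None)

        remaining[al] = 0
        yield from fill(0, r)
        remaining[al] = r

    yield from rec(0, dict(allele_counts), {})


# ---------------------------------------------------------------------------
# linkage disequilibrium

def ld_permutation_test(gt: GenotypeTable, locus_a: str, locus_b: str,
                        n_perm: int = 999, seed: Optional[int] = None,
                        min_common: int = 5) -> float:
    """Permutation test of genotypic association between two loci.

    The statistic is the log-likelihood-ratio G on the two-locus genotype
    contingency table; the null is built by permuting one locus's genotypes
    across individuals.  p = (1 + #{G_perm >= G_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise GenodataError("n_perm must be >= 1")
    pairs = [(r[locus_a], r[locus_b]) for r in gt.rows.values()
             if r.get(locus_a) is not None and r.get(locus_b) is not None]
    if len(pairs) < min_common:
        raise GenodataError(
            f"{locus_a}/{locus_b}: only {len(pairs)} individuals genotyped at both")
    ga = pd.factorize(pd.Series([p[0] for p in pairs]))[0]
    gb = pd.factorize(pd.Series([p[1] for p in pairs]))[0]
    g_obs = _g_stat(ga, gb)
    rng = np.random.default_rng(seed)
    hits = 0
    gb_perm = gb.copy()
    for _ in range(n_perm):
        rng.shuffle(gb_perm)
        if _g_stat(ga, gb_perm) >= g_obs - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def _g_stat(ga: np.ndarray, gb: np.ndarray) -> float:
    obs = pd.crosstab(ga, gb).to_numpy().astype(float)
    tot = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / tot
    mask = obs > 0
    return float(2.0 * (obs[mask] * np.log(obs[mask] / exp[mask])).sum())


# ---------------------------------------------------------------------------
# per-locus summary (Table-2 style)

@dataclass
class LocusStats:
    locus: str
    n: int
    n_alleles: int
    ho: float
    he: float
    fis: float
    p_hwe: float
    f_null: float
    ar: float


def locus_stats_table(gt: GenotypeTable, loci: Optional[Sequence[str]] = None,
                      rarefaction_g: int = 8, null_method: str = "chakraborty",
                      hwe_mode: str = "enumerate", seed: Optional[int] = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per-locus diversity report plus a mean row across polymorphic loci.

    Mirrors the conventional per-locus summary table: N_A, H_E, H_O, p_HWE
    (with a Bonferroni-adjusted significance flag), F_IS and f_null, plus
    rarefied allelic richness A_R(g).
    """
    loci = list(loci) if loci is not None else gt.autosomal_loci
    freq = allele_frequencies(gt, loci)
    per_locus_f, multi_f = fis_wc(gt, loci)
    rows = []
    n_tests = 0
    for l in loci:
        n = freq.n_ind[l]
        f = freq.freqs(l)
        na = len(f)
        ho = obs_het(gt, l)
        he = exp_het_unbiased(f, n) if n >= 2 else float("nan")
        if na > 1:
            try:
                p = hwe_exact_test(gt, l, mode=hwe_mode, seed=seed)
            except GenodataError:
                p = hwe_exact_test(gt, l, mode="mc", seed=seed)
            n_tests += 1
        else:
            p = float("nan")
        g = min(rarefaction_g, n)
        fn = null_allele_freq(he, ho, null_method) if (he + ho) > 0 else 0.0
        rows.append(dict(locus=l, n=n, n_alleles=na, ho=ho, he=he,
                         fis=per_locus_f[l], p_hwe=p, f_null=fn,
                         ar=allelic_richness(freq.counts[l], g)))
    df = pd.DataFrame(rows).set_index("locus")
    df["hwe_bonferroni_sig"] = df["p_hwe"] < (alpha / max(n_tests, 1))
    poly = df[df["n_alleles"] > 1]
    mean_row = dict(n=poly["n"].mean(), n_alleles=poly["n_alleles"].mean(),
                    ho=poly["ho"].mean(), he=poly["he"].mean(), fis=multi_f,
                    p_hwe=float("nan"), f_null=float("nan"),
                    ar=poly["ar"].mean(), hwe_bonferroni_sig=False)
    df.loc["mean"] = mean_row
    return df
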