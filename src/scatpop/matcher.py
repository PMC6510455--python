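"""Individual identification from multilocus genotypes.

Repeated non-invasive sampling yields several genotypes per animal, and
genotyping error yields near-duplicates.  Samples are clustered into
individuals by single-linkage over pairs whose allele mismatch count (over
loci called in both) does not exceed a tolerance — the tolerant-matching
behaviour of ``alleleMismatch = 2`` style software.  The discriminatory
power of the locus panel is quantified by the probability of identity:
the naive PID, a small-sample unbiased PID, and the sibling-conditioned
PID_sib, each per locus and as a cumulative product across loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .genodata import AlleleFrequencyTable, Call, GenodataError, GenotypeTable

Genotype = Mapping[str, Call]


@dataclass(frozen=True)
class MatchConfig:
    max_mismatch: int = 2
    min_shared_loci: int = 6

    def __post_init__(self):
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.min_shared_loci < 1:
            raise ValueError("min_shared_loci must be >= 1")


@dataclass
class Individual:
    individual_id: str
    sample_ids: list[str]
    calls: dict[str, Call]
    sex: str = "unknown"  # F | M | unknown
    source_profile: dict[str, int] = field(default_factory=dict)


@dataclass
class PidResult:
    loci: list[str]
    pid_sib: dict[str, float]
    pid_unbiased: dict[str, float]
    pid_naive: dict[str, float]

    @property
    def cumulative_sib(self) -> float:
        return _prod(self.pid_sib[l] for l in self.loci)

    @property
    def cumulative_unbiased(self) -> float:
        return _prod(self.pid_unbiased[l] for l in self.loci)

    @property
    def cumulative_naive(self) -> float:
        return _prod(self.pid_naive[l] for l in self.loci)


def _prod(xs) -> float:
    out = 1.0
    for x in xs:
        out *= x
    return out


def shared_allele_count(c1: Call, c2: Call) -> int:
    """Size of the multiset intersection of two diploid calls (0, 1 or 2)."""
    (a1, b1), (a2, b2) = c1, c2  # type: ignore[misc]
    if a1 == a2:
        return 2 if b1 == b2 else 1
    # calls are sorted; count matched alleles greedily over the two slots
    n = 0
    avail = [a2, b2]
    for x in (a1, b1):
        if x in avail:
            avail.remove(x)
            n += 1
    return n


def pairwise_mismatch(g1: Genotype, g2: Genotype,
                      loci: Optional[Iterable[str]] = None) -> tuple[int, int]:
    """(allele mismatch count, number of loci called in both genotypes).

    Loci missing in either genotype are skipped and counted in neither.
    """
    if loci is None:
        loci = set(g1) | set(g2)
    mism = 0
    shared = 0
    for l in loci:
        c1, c2 = g1.get(l), g2.get(l)
        if c1 is None or c2 is None:
            continue
        shared += 1
        mism += 2 - shared_allele_count(c1, c2)
    return mism, shared


def cluster_individuals(gt: GenotypeTable,
                        cfg: MatchConfig = MatchConfig(),
                        sources: Optional[Mapping[str, str]] = None,
                        sex_rule: Optional["SexRule"] = None,
                        loci: Optional[Sequence[str]] = None) -> list[Individual]:
    """Single-linkage clustering of samples into individuals.

    Edges connect comparable pairs (>= min_shared_loci loci called in both)
    with mismatch count <= max_mismatch.  The per-individual consensus call
    at each locus is the majority non-missing call among members; ties go to
    the most complete member's call, then to the lowest sample id.  The
    result is invariant to input order.
    """
    ids = sorted(gt.rows)
    if not ids:
        raise GenodataError("no genotypes to cluster")
    loci = list(loci) if loci is not None else gt.locus_names
    comp_loci = [l for l in loci if l in {x.name for x in gt.panel}]

    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            mism, shared = pairwise_mismatch(gt.rows[a], gt.rows[b], comp_loci)
            if shared >= cfg.min_shared_loci and mism <= cfg.max_mismatch:
                g.add_edge(a, b)

    individuals = []
    clusters = sorted(nx.connected_components(g), key=lambda c: min(c))
    for k, members in enumerate(clusters, start=1):
        members = sorted(members)
        calls = _majority_calls(gt, members)
        ind = Individual(
            individual_id=f"IND{k:03d}",
            sample_ids=members,
            calls=calls,
            source_profile=_source_profile(members, sources),
        )
        if sex_rule is not None:
            ind.sex = assign_sex(calls, sex_rule)
        individuals.append(ind)
    return individuals


def _majority_calls(gt: GenotypeTable, members: Sequence[str]) -> dict[str, Call]:
    completeness = {m: sum(1 for c in gt.rows[m].values() if c is not None)
                    for m in members}
    calls: dict[str, Call] = {}
    for l in gt.locus_names:
        votes: dict[tuple, list[str]] = {}
        for m in members:
            c = gt.rows[m].get(l)
            if c is not None:
                votes.setdefault(c, []).append(m)
        if not votes:
            continue
        best = max(votes.values(), key=len)
        top = [c for c, ms in votes.items() if len(ms) == len(best)]
        if len(top) == 1:
            calls[l] = top[0]
        else:
            # tie: call of the most complete member, then lowest sample id
            def rank(c):
                ms = votes[c]
                return (-max(completeness[m] for m in ms),
                        min(ms for ms in votes[c]))
            calls[l] = sorted(top, key=rank)[0]
    return calls


def _source_profile(members, sources) -> dict[str, int]:
    prof: dict[str, int] = {}
    if sources:
        for m in members:
            s = sources.get(m)
            if s:
                prof[s] = prof.get(s, 0) + 1
    return prof


# ---------------------------------------------------------------------------
# probability of identity

def _moments(freqs: Mapping[int, float]) -> tuple[float, float, float]:
    a2 = sum(p ** 2 for p in freqs.values())
    a3 = sum(p ** 3 for p in freqs.values())
    a4 = sum(p ** 4 for p in freqs.values())
    return a2, a3, a4


def pid_naive_locus(freqs: Mapping[int, float]) -> float:
    """Naive PID: probability two random HWE genotypes are identical.

    Sum of p_i^4 over homozygotes plus (2 p_i p_j)^2 over heterozygotes,
    which collapses to 2*a2^2 - a4.
    """
    a2, _, a4 = _moments(freqs)
    return 2.0 * a2 ** 2 - a4


def pid_unbiased_locus(freqs: Mapping[int, float], n: int) -> float:
    """Small-sample unbiased PID (Paetkau-style correction).

    ``n`` is the number of genotyped individuals behind the frequency
    estimates at this locus; the correction is undefined below n = 4.
    """
    if n < 4:
        raise GenodataError("unbiased PID undefined for n < 4 individuals")
    a2, a3, a4 = _moments(freqs)
    num = (n ** 3 * (2 * a2 ** 2 - a4)
           - 2 * n ** 2 * (a3 + 2 * a2)
           + n * (9 * a2 + 2) - 6)
    return num / ((n - 1) * (n - 2) * (n - 3))


def pid_sib_locus(freqs: Mapping[int, float]) -> float:
    """PID conditioned on the pair being full siblings (HWE parents)."""
    a2, _, a4 = _moments(freqs)
    return 0.25 + 0.5 * a2 + 0.5 * a2 ** 2 - 0.25 * a4


def pid_report(freq_table: AlleleFrequencyTable,
               loci: Optional[Sequence[str]] = None) -> PidResult:
    loci = list(loci) if loci is not None else list(freq_table.counts)
    sib, unb, naive = {}, {}, {}
    for l in loci:
        f = freq_table.freqs(l)
        sib[l] = pid_sib_locus(f)
        unb[l] = pid_unbiased_locus(f, freq_table.n_ind[l])
        naive[l] = pid_naive_locus(f)
    return PidResult(loci=loci, pid_sib=sib, pid_unbiased=unb, pid_naive=naive)


# ---------------------------------------------------------------------------
# sex assignment

@dataclass(frozen=True)
class SexRule:
    """Maps Y-specific allele sizes per sexing locus.

    A genotype showing a Y allele at either locus is male; both sexing loci
    called with no Y allele is female; anything else is unknown.
    """

    y_alleles: Mapping[str, frozenset[int]]


def assign_sex(calls: Genotype, rule: SexRule) -> str:
    saw_y = []
    called = []
    for locus, ys in rule.y_alleles.items():
        c = calls.get(locus)
        if c is None:
            continue
        called.append(locus)
        saw_y.append(any(a in ys for a in c))
    if not called:
        return "unknown"
    if any(saw_y):
        if len(called) == len(rule.y_alleles) and not all(saw_y):
            warnings.warn("contradictory sexing loci (Y allele at one locus only)")
            return "unknown"
        return "M"
    if len(called) == len(rule.y_alleles):
        return "F"
    return "unknown"
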