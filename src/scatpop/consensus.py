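"""Replicate-consistency consensus genotyping of non-invasive samples.

Faecal DNA genotypes suffer allelic dropout and false alleles, so a call is
accepted only where two independent amplifications agree.  Each sample is
genotyped in duplicate (round 1); if any locus disagrees and material for a
second extraction exists, a second duplicate round is run and must itself be
conflict-free at the previously conflicting loci, otherwise the sample is
discarded.  A consensus genotype is retained when it carries consistent
calls at at least ``min_consistent_loci`` loci.

A one-called/one-missing replicate pair is treated as a conflict, not as a
pass-through call: it is exactly the signature of dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .genodata import Call, GenodataError, GenotypeTable, SampleRecord, SampleTable

CONFLICT = "conflict"


@dataclass(frozen=True)
class ConsensusPolicy:
    min_consistent_loci: int = 12
    max_rounds: int = 2

    def __post_init__(self):
        if self.min_consistent_loci < 1:
            raise ValueError("min_consistent_loci must be >= 1")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass
class ConsensusGenotype:
    sample_id: str
    calls: dict[str, Call] = field(default_factory=dict)
    n_consistent_loci: int = 0
    status: str = "discarded"  # retained | discarded
    rounds_used: int = 1
    conflict_loci: list[str] = field(default_factory=list)


def consensus_locus(call_r1: Call, call_r2: Call):
    """Consensus of two replicate calls at one locus.

    Returns the shared call, ``None`` (both missing) or ``CONFLICT``.
    """
    if call_r1 is None and call_r2 is None:
        return None
    if call_r1 is None or call_r2 is None:
        return CONFLICT
    return call_r1 if call_r1 == call_r2 else CONFLICT


def consensus_sample(replicates: Sequence[SampleRecord],
                     policy: ConsensusPolicy = ConsensusPolicy(),
                     loci: Optional[Iterable[str]] = None) -> ConsensusGenotype:
    """Consensus genotype for one sample from its replicate amplifications.

    Replicates are consumed in replicate_id order, two per round.  Loci
    consistent in an accepted round enter the consensus; a conflict that the
    second round does not resolve discards the sample.
    """
    reps = sorted(replicates, key=lambda r: r.replicate_id)
    if len(reps) < 2:
        raise GenodataError("consensus requires at least 2 replicate amplifications")
    sid = reps[0].sample_id
    if any(r.sample_id != sid for r in reps):
        raise GenodataError("replicates from different samples")
    if loci is None:
        seen: list[str] = []
        for r in reps:
            for l in r.calls:
                if l not in seen:
                    seen.append(l)
        loci = seen
    loci = list(loci)

    round1 = {l: consensus_locus(reps[0].calls.get(l), reps[1].calls.get(l)) for l in loci}
    conflicts = [l for l, c in round1.items() if c == CONFLICT]
    calls = {l: c for l, c in round1.items() if c is not None and c != CONFLICT}
    rounds_used = 1
    status = "retained"

    if conflicts:
        n_rounds_avail = len(reps) // 2
        if n_rounds_avail >= 2 and policy.max_rounds >= 2:
            rounds_used = 2
            r3, r4 = reps[2], reps[3]
            unresolved = []
            for l in conflicts:
                c = consensus_locus(r3.calls.get(l), r4.calls.get(l))
                if c == CONFLICT:
                    unresolved.append(l)
                elif c is not None:
                    calls[l] = c
            if unresolved:
                status = "discarded"
                conflicts = unresolved
        else:
            status = "discarded"

    n_consistent = len(calls)
    if n_consistent < policy.min_consistent_loci:
        status = "discarded"
    return ConsensusGenotype(
        sample_id=sid,
        calls=calls,
        n_consistent_loci=n_consistent,
        status=status,
        rounds_used=rounds_used,
        conflict_loci=conflicts if status == "discarded" else [],
    )


def consensus_table(samples: SampleTable,
                    policy: ConsensusPolicy = ConsensusPolicy(),
                    loci: Optional[Iterable[str]] = None) -> tuple[GenotypeTable, list[ConsensusGenotype]]:
    """Run the consensus protocol over every sample; retained ones form a table."""
    loci = list(loci) if loci is not None else samples.locus_names
    results = [consensus_sample(reps, policy, loci)
               for sid, reps in samples.by_sample().items()]
    panel = [l for l in samples.panel if l.name in set(loci)]
    rows = {r.sample_id: dict(r.calls) for r in results if r.status == "retained"}
    return GenotypeTable(rows=rows, panel=panel), results


def amplification_success(samples: SampleTable,
                          loci: Optional[Iterable[str]] = None) -> float:
    """Fraction of (sample, locus) cells with a non-missing call.

    Counted over unique samples using their first replicate, mirroring a
    per-PCR success rate over the requested locus subset.
    """
    loci = list(loci) if loci is not None else samples.locus_names
    by_sample = samples.by_sample()
    if not by_sample or not loci:
        raise GenodataError("amplification_success needs >= 1 sample and >= 1 locus")
    total = 0
    called = 0
    for reps in by_sample.values():
        for l in loci:
            total += 1
            if reps[0].calls.get(l) is not None:
                called += 1
    return called / total
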