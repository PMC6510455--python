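"""Pairwise allele-sharing relatedness (M_xy) and sibship classification.

M_xy is the Blouin-type allele-sharing index: at each locus called in both
individuals the similarity is half the number of shared alleles (0, 0.5 or
1), and M_xy is the mean over those loci.  Pairs are classified against
empirical sibship thresholds (full-sibling/parent-offspring vs half-sibling
vs unrelated), and an offspring-candidate rule assigns a juvenile genotype
to a resident female when relatedness exceeds a threshold and independent
field evidence (small faecal diameter) supports a juvenile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genodata import Call, GenodataError, GenotypeTable
from .matcher import shared_allele_count

Genotype = Mapping[str, Call]

LOW_CONFIDENCE_LOCI = 5  # pairs with fewer comparable loci are flagged


@dataclass(frozen=True)
class SibshipThresholds:
    full_sib: float = 0.59
    half_sib: float = 0.43

    def __post_init__(self):
        if not (0 < self.half_sib < self.full_sib < 1):
            raise ValueError("need 0 < half_sib < full_sib < 1")


def mxy(g1: Genotype, g2: Genotype,
        loci: Optional[Iterable[str]] = None) -> float:
    """Mean allele-sharing over loci called in both genotypes."""
    val, n = _mxy_n(g1, g2, loci)
    if n == 0:
        raise GenodataError("no comparable loci")
    return val


def _mxy_n(g1: Genotype, g2: Genotype,
           loci: Optional[Iterable[str]] = None) -> tuple[float, int]:
    if loci is None:
        loci = set(g1) | set(g2)
    tot = 0.0
    n = 0
    for l in loci:
        c1, c2 = g1.get(l), g2.get(l)
        if c1 is None or c2 is None:
            continue
        tot += shared_allele_count(c1, c2) / 2.0
        n += 1
    return (tot / n if n else float("nan")), n


@dataclass
class RelatednessMatrix:
    ids: list[str]
    values: pd.DataFrame       # symmetric, diagonal 1, NaN where undefined
    n_loci: pd.DataFrame       # comparable loci per pair

    def pairs(self) -> pd.DataFrame:
        """Long-form table of unordered pairs with defined M_xy."""
        rows = []
        for i, a in enumerate(self.ids):
            for b in self.ids[i + 1:]:
                v = self.values.loc[a, b]
                rows.append(dict(id1=a, id2=b, mxy=v,
                                 n_loci=int(self.n_loci.loc[a, b]),
                                 low_confidence=self.n_loci.loc[a, b] < LOW_CONFIDENCE_LOCI))
        return pd.DataFrame(rows)


def relatedness_matrix(gt: GenotypeTable,
                       loci: Optional[Sequence[str]] = None) -> RelatednessMatrix:
    ids = list(gt.rows)
    if len(ids) < 2:
        raise GenodataError("relatedness needs >= 2 individuals")
    loci = list(loci) if loci is not None else gt.locus_names
    k = len(ids)
    vals = np.full((k, k), np.nan)
    nl = np.zeros((k, k))
    np.fill_diagonal(vals, 1.0)
    for i in range(k):
        nl[i, i] = sum(1 for l in loci if gt.rows[ids[i]].get(l) is not None)
        for j in range(i + 1, k):
            v, n = _mxy_n(gt.rows[ids[i]], gt.rows[ids[j]], loci)
            vals[i, j] = vals[j, i] = v
            nl[i, j] = nl[j, i] = n
    return RelatednessMatrix(
        ids=ids,
        values=pd.DataFrame(vals, index=ids, columns=ids),
        n_loci=pd.DataFrame(nl, index=ids, columns=ids),
    )


def classify_pairs(rm: RelatednessMatrix,
                   thr: SibshipThresholds = SibshipThresholds()) -> dict[str, int]:
    """Count pairs per sibship class; threshold comparisons are inclusive."""
    counts = {"full_sib_or_PO": 0, "half_sib": 0, "unrelated": 0}
    p = rm.pairs()
    for v in p["mxy"]:
        if np.isnan(v):
            continue
        if v >= thr.full_sib:
            counts["full_sib_or_PO"] += 1
        elif v >= thr.half_sib:
            counts["half_sib"] += 1
        else:
            counts["unrelated"] += 1
    return counts


def mean_relatedness(rm: RelatednessMatrix) -> dict[str, float]:
    """Mean and quartiles of defined off-diagonal M_xy values."""
    v = rm.pairs()["mxy"].dropna()
    if v.empty:
        raise GenodataError("no defined pairs")
    q1, q2, q3 = v.quantile([0.25, 0.5, 0.75])
    return dict(mean=float(v.mean()), q1=float(q1), median=float(q2),
                q3=float(q3), n_pairs=int(v.size))


def offspring_candidate(genotype: Genotype, candidate_mothers: GenotypeTable,
                        threshold: float = 0.5,
                        small_diameter_flag: bool = False,
                        loci: Optional[Sequence[str]] = None) -> Optional[str]:
    """Assign a juvenile genotype to the most related resident female.

    Returns the female id whose M_xy to the genotype is maximal, provided
    that value exceeds ``threshold`` AND the independent juvenile evidence
    flag is set; ties or failures return None.
    """
    if not small_diameter_flag:
        return None
    best: list[str] = []
    best_v = -1.0
    for f_id, calls in candidate_mothers.rows.items():
        try:
            v = mxy(genotype, calls, loci)
        except GenodataError:
            continue
        if v > best_v + 1e-12:
            best, best_v = [f_id], v
        elif abs(v - best_v) <= 1e-12:
            best.append(f_id)
    if best_v <= threshold or not best:
        return None
    if len(best) > 1:
        import warnings
        warnings.warn(f"tied candidate mothers {best}; none assigned")
        return None
    return best[0]
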