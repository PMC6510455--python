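"""Sampling-source comparison of genetic-diversity estimates.

Box-trap (invasive) sampling of a territorial, philopatric population tends
to capture residents and their kittens, i.e. clusters of relatives, while
systematic faecal (non-invasive) sampling covers the population more
evenly.  To compare the two on equal footing, diversity accumulation
curves are built by repeatedly drawing genotype subsamples of increasing
size from each group and recomputing the mean number of alleles (N-bar)
and mean expected heterozygosity across loci.  Per subsample size the
groups are compared by one-way ANOVA followed by Tukey's HSD, with a
Bonferroni-adjusted significance threshold over all (size x group-pair)
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import exp_het_unbiased
from .genodata import GenodataError, GenotypeTable


@dataclass
class SubsampleCurve:
    group: str
    sizes: list[int]
    nbar: np.ndarray   # shape (len(sizes), n_iter)
    he: np.ndarray     # shape (len(sizes), n_iter)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(dict(
            size=self.sizes,
            nbar_mean=self.nbar.mean(axis=1), nbar_sd=self.nbar.std(axis=1, ddof=1),
            he_mean=self.he.mean(axis=1), he_sd=self.he.std(axis=1, ddof=1),
        ))


@dataclass
class SizeComparison:
    size: int
    measure: str                  # nbar | he
    results: pd.DataFrame         # pair, diff, p, significant
    adjusted_alpha: float


def subsample_diversity(gt: GenotypeTable,
                        sizes: Sequence[int],
                        n_iter: int = 100,
                        loci: Optional[Sequence[str]] = None,
                        seed: Optional[int] = None,
                        group: str = "all",
                        unbiased: bool = True) -> SubsampleCurve:
    """Diversity accumulation curve for one group of genotypes.

    For each size g and iteration, g genotypes are drawn without
    replacement; the per-locus number of distinct alleles and expected
    heterozygosity (unbiased by default, computed with the subsample's own
    per-locus n) are averaged across loci into one (N-bar, H_E) pair.
    """
    ids = list(gt.rows)
    loci = list(loci) if loci is not None else gt.locus_names
    sizes = list(sizes)
    if min(sizes) < 2:
        raise GenodataError("subsample sizes must be >= 2")
    if max(sizes) > len(ids):
        raise GenodataError(f"subsample size {max(sizes)} exceeds group size {len(ids)}")
    rng = np.random.default_rng(seed)
    nbar = np.empty((len(sizes), n_iter))
    he = np.empty((len(sizes), n_iter))
    for si, g in enumerate(sizes):
        for it in range(n_iter):
            take = rng.choice(ids, size=g, replace=False)
            na_vals = []
            he_vals = []
            for l in loci:
                calls = [gt.rows[i].get(l) for i in take]
                calls = [c for c in calls if c is not None]
                if not calls:
                    continue
                cnt: dict[int, int] = {}
                for a, b in calls:
                    cnt[a] = cnt.get(a, 0) + 1
                    cnt[b] = cnt.get(b, 0) + 1
                n = len(calls)
                tot = 2 * n
                freqs = {a: c / tot for a, c in cnt.items()}
                na_vals.append(len(cnt))
                if n >= 2:
                    if unbiased:
                        he_vals.append(exp_het_unbiased(freqs, n))
                    else:
                        he_vals.append(1.0 - sum(p ** 2 for p in freqs.values()))
            nbar[si, it] = float(np.mean(na_vals))
            he[si, it] = float(np.mean(he_vals))
    return SubsampleCurve(group=group, sizes=sizes, nbar=nbar, he=he)


def compare_sources(curves: dict[str, SubsampleCurve],
                    sizes: Optional[Sequence[int]] = None,
                    base_alpha: float = 0.05) -> list[SizeComparison]:
    """Tukey HSD comparisons of groups per subsample size and measure.

    The adjusted alpha is base_alpha divided by (#sizes x #group pairs);
    with 11 sizes and 3 pairs this reproduces the conventional 0.05/33 ~
    0.0015 threshold.
    """
    groups = list(curves)
    if len(groups) < 2:
        raise GenodataError("need >= 2 groups to compare")
    if sizes is None:
        sizes = sorted(set.intersection(*(set(c.sizes) for c in curves.values())))
    sizes = list(sizes)
    for g, c in curves.items():
        if not set(sizes) <= set(c.sizes):
            raise GenodataError(f"group {g} lacks requested sizes")
    n_pairs = len(groups) * (len(groups) - 1) // 2
    adj = base_alpha / (len(sizes) * n_pairs)
    out = []
    for measure in ("nbar", "he"):
        for s in sizes:
            data = [getattr(curves[g], measure)[curves[g].sizes.index(s)] for g in groups]
            if all(np.ptp(d) == 0 for d in data) and len({d[0] for d in data}) == 1:
                # identical constant groups: nothing to test
                res = _constant_result(groups)
            else:
                tuk = stats.tukey_hsd(*data)
                rows = []
                for i in range(len(groups)):
                    for j in range(i + 1, len(groups)):
                        rows.append(dict(
                            pair=f"{groups[i]} vs {groups[j]}",
                            diff=float(np.mean(data[i]) - np.mean(data[j])),
                            p=float(tuk.pvalue[i, j]),
                        ))
                res = pd.DataFrame(rows)
            res["significant"] = res["p"] < adj
            out.append(SizeComparison(size=s, measure=measure, results=res,
                                      adjusted_alpha=adj))
    return out


def _constant_result(groups: list[str]) -> pd.DataFrame:
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(dict(pair=f"{groups[i]} vs {groups[j]}", diff=0.0, p=1.0))
    return pd.DataFrame(rows)


def plot_accumulation(curves: dict[str, SubsampleCurve], path) -> None:
    """Two-panel mean +/- SD accumulation plot (N-bar and H_E)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
    for g, c in curves.items():
        s = c.summary()
        axes[0].errorbar(s["size"], s["nbar_mean"], yerr=s["nbar_sd"],
                         label=g, capsize=2, marker="o", markersize=3)
        axes[1].errorbar(s["size"], s["he_mean"], yerr=s["he_sd"],
                         label=g, capsize=2, marker="o", markersize=3)
    axes[0].set_xlabel("genotypes subsampled")
    axes[1].set_xlabel("genotypes subsampled")
    axes[0].set_ylabel(r"mean number of alleles $\bar{N}$")
    axes[1].set_ylabel(r"expected heterozygosity $H_E$")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": None})
    plt.close(fig)
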