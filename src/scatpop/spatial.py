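"""Spatial genetic structure at the individual scale.

Territory centroids (GPS home-range centroid where available, otherwise the
centroid of the minimum convex polygon of observation locations) give each
individual one planar coordinate.  On top of these the module provides
Kosman–Leonard genetic dissimilarity versus geographic distance curves and
a multivariate spatial autocorrelogram: per-locus codominant squared
distances are double-centered into a covariance form, and the
autocorrelation r per distance class is tested against a permutation null
(random reassignment of genotypes to locations) with bootstrap confidence
intervals over pairs.  Distance classes can be chosen so every class holds
an equal number of pairs ("even classes").

All coordinates are projected planar meters; distances are reported in km.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .genodata import Call, GenodataError, GenotypeTable
from .relatedness import _mxy_n

Genotype = Mapping[str, Call]


@dataclass(frozen=True)
class TerritoryPoint:
    individual_id: str
    x: float
    y: float
    provenance: str = "mcp_centroid"  # gps_centroid | mcp_centroid

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise GenodataError("territory point coordinates must be finite")


def mcp_centroid(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Centroid of the minimum convex polygon of the points.

    Fewer than three points, or collinear points, degrade to the arithmetic
    mean of the locations.
    """
    if not points:
        raise GenodataError("mcp_centroid needs >= 1 point")
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    if hull.geom_type == "Polygon" and hull.area > 0:
        c = hull.centroid
        return (c.x, c.y)
    arr = np.asarray(points, dtype=float)
    return (float(arr[:, 0].mean()), float(arr[:, 1].mean()))


def kl_dissimilarity(g1: Genotype, g2: Genotype,
                     loci: Optional[Iterable[str]] = None) -> float:
    """Kosman–Leonard codominant dissimilarity: mean over comparable loci of
    1 - (shared alleles)/2.  Equals 1 - M_xy by construction."""
    v, n = _mxy_n(g1, g2, loci)
    if n == 0:
        raise GenodataError("no comparable loci")
    return 1.0 - v


def genotype_distance_squared(g1: Genotype, g2: Genotype,
                              loci: Optional[Iterable[str]] = None) -> float:
    """Codominant squared genetic distance summed over comparable loci.

    Per locus: 0 for identical genotypes, 1 for one shared allele with one
    substitution (ii/ij or ij/ik), 2 for disjoint heterozygotes, 3 for a
    homozygote against a disjoint heterozygote, 4 for different homozygotes.
    """
    if loci is None:
        loci = set(g1) | set(g2)
    tot = 0.0
    n = 0
    for l in loci:
        c1, c2 = g1.get(l), g2.get(l)
        if c1 is None or c2 is None:
            continue
        n += 1
        tot += _d2_locus(c1, c2)
    if n == 0:
        raise GenodataError("no comparable loci")
    return tot


def _d2_locus(c1: tuple[int, int], c2: tuple[int, int]) -> int:
    hom1 = c1[0] == c1[1]
    hom2 = c2[0] == c2[1]
    s1, s2 = set(c1), set(c2)
    if hom1 and hom2:
        return 0 if c1 == c2 else 4
    if hom1 != hom2:
        hom_allele = c1[0] if hom1 else c2[0]
        het = s2 if hom1 else s1
        return 1 if hom_allele in het else 3
    if c1 == c2:
        return 0
    return 1 if s1 & s2 else 2


# ---------------------------------------------------------------------------
# dissimilarity vs distance

@dataclass
class DissimilarityCurve:
    pairs: pd.DataFrame        # id1, id2, distance_km, dissimilarity
    binned: pd.DataFrame       # bin_mid_km, mean_dissimilarity, n_pairs


def dissimilarity_vs_distance(gt: GenotypeTable,
                              points: Mapping[str, TerritoryPoint],
                              bin_width_km: float = 2.0,
                              loci: Optional[Sequence[str]] = None,
                              subset: Optional[Iterable[str]] = None) -> DissimilarityCurve:
    ids = [i for i in gt.rows if i in points]
    if subset is not None:
        keep = set(subset)
        ids = [i for i in ids if i in keep]
    if len(ids) < 2:
        raise GenodataError("need >= 2 located individuals")
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            d_km = np.hypot(points[a].x - points[b].x, points[a].y - points[b].y) / 1000.0
            try:
                dis = kl_dissimilarity(gt.rows[a], gt.rows[b], loci)
            except GenodataError:
                continue
            rows.append(dict(id1=a, id2=b, distance_km=d_km, dissimilarity=dis))
    pairs = pd.DataFrame(rows)
    idx = np.floor(pairs["distance_km"] / bin_width_km).astype(int)
    binned = (pairs.assign(bin=idx)
              .groupby("bin")
              .agg(mean_dissimilarity=("dissimilarity", "mean"),
                   n_pairs=("dissimilarity", "size"))
              .reset_index())
    binned["bin_mid_km"] = (binned.pop("bin") + 0.5) * bin_width_km
    return DissimilarityCurve(pairs=pairs, binned=binned)


# ---------------------------------------------------------------------------
# spatial autocorrelogram

@dataclass
class Correlogram:
    classes: pd.DataFrame
    # columns: upper_km, r, perm_lo, perm_hi, boot_lo, boot_hi, n_pairs, p


def double_centered_covariance(d2: np.ndarray) -> np.ndarray:
    """Convert a squared-distance matrix to covariance form: -0.5 J D J."""
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def spatial_autocorrelogram(gt: GenotypeTable,
                            points: Mapping[str, TerritoryPoint],
                            n_classes: int,
                            even_classes: bool = True,
                            n_perm: int = 999,
                            n_boot: int = 999,
                            seed: Optional[int] = 20190510,
                            loci: Optional[Sequence[str]] = None) -> Correlogram:
    """Individual-based spatial autocorrelogram with permutation null.

    r per distance class is the ratio of summed off-diagonal covariance
    terms over the class's pairs to the summed diagonal terms over the
    individuals involved in those pairs.  The permutation null shuffles the
    genotype-to-location assignment; the bootstrap resamples pairs within
    class.  One-tailed p per class, on the side of the observed sign.
    """
    ids = [i for i in gt.rows if i in points]
    if len(ids) < 5:
        raise GenodataError("autocorrelogram needs >= 5 located individuals")
    k = len(ids)
    n_pairs_tot = k * (k - 1) // 2
    if n_classes > n_pairs_tot:
        raise GenodataError("more distance classes than pairs")
    loci = list(loci) if loci is not None else gt.locus_names

    d2 = np.zeros((k, k))
    geo = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d2[i, j] = d2[j, i] = genotype_distance_squared(
                gt.rows[ids[i]], gt.rows[ids[j]], loci)
            geo[i, j] = geo[j, i] = np.hypot(
                points[ids[i]].x - points[ids[j]].x,
                points[ids[i]].y - points[ids[j]].y) / 1000.0
    cov = double_centered_covariance(d2)

    iu = np.triu_indices(k, 1)
    pair_d = geo[iu]
    order = np.argsort(pair_d, kind="stable")
    if even_classes:
        chunks = np.array_split(order, n_classes)
    else:
        edges = np.linspace(0, pair_d.max(), n_classes + 1)[1:]
        bins = np.minimum(np.searchsorted(edges, pair_d, side="left"), n_classes - 1)
        chunks = [np.where(bins == c)[0] for c in range(n_classes)]
    classes = [(np.asarray(iu[0])[c], np.asarray(iu[1])[c]) for c in chunks]

    def r_of(cmat: np.ndarray, xi: np.ndarray, yi: np.ndarray) -> float:
        members = np.unique(np.concatenate([xi, yi]))
        denom = cmat[members, members].sum()
        if denom == 0:
            return float("nan")
        return float(cmat[xi, yi].sum() / denom)

    r_obs = [r_of(cov, xi, yi) for xi, yi in classes]

    rng = np.random.default_rng(seed)
    perm_r = np.empty((n_perm, n_classes))
    for p in range(n_perm):
        perm = rng.permutation(k)
        cp = cov[np.ix_(perm, perm)]
        perm_r[p] = [r_of(cp, xi, yi) for xi, yi in classes]
    perm_lo = np.nanpercentile(perm_r, 2.5, axis=0)
    perm_hi = np.nanpercentile(perm_r, 97.5, axis=0)
    pvals = []
    for c in range(n_classes):
        if r_obs[c] >= 0:
            hits = int(np.sum(perm_r[:, c] >= r_obs[c] - 1e-12))
        else:
            hits = int(np.sum(perm_r[:, c] <= r_obs[c] + 1e-12))
        pvals.append((1 + hits) / (1 + n_perm))

    boot_lo = np.full(n_classes, np.nan)
    boot_hi = np.full(n_classes, np.nan)
    if n_boot > 0:
        for c, (xi, yi) in enumerate(classes):
            m = len(xi)
            if m < 2:
                continue
            stats = np.empty(n_boot)
            for b in range(n_boot):
                take = rng.integers(0, m, size=m)
                stats[b] = r_of(cov, xi[take], yi[take])
            boot_lo[c] = np.nanpercentile(stats, 2.5)
            boot_hi[c] = np.nanpercentile(stats, 97.5)

    table = pd.DataFrame(dict(
        upper_km=[pair_d[c].max() for c in chunks],
        r=r_obs, perm_lo=perm_lo, perm_hi=perm_hi,
        boot_lo=boot_lo, boot_hi=boot_hi,
        n_pairs=[len(c) for c in chunks], p=pvals,
    ))
    return Correlogram(classes=table)


def territory_points(gps_centroids: Mapping[str, tuple[float, float]],
                     observations: Mapping[str, Sequence[tuple[float, float]]]) -> dict[str, TerritoryPoint]:
    """One point per individual: GPS home-range centroid when available,
    otherwise the MCP centroid of its observation locations."""
    out: dict[str, TerritoryPoint] = {}
    for ind, (x, y) in gps_centroids.items():
        out[ind] = TerritoryPoint(ind, x, y, "gps_centroid")
    for ind, obs in observations.items():
        if ind not in out and obs:
            x, y = mcp_centroid(obs)
            out[ind] = TerritoryPoint(ind, x, y, "mcp_centroid")
    return out
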