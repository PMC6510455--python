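"""Domain types and I/O for diploid microsatellite genotype tables.

Alleles are integer fragment sizes in base pairs.  A diploid call is an
unordered pair stored sorted ascending, or ``None`` when the locus failed
to amplify.  Missing alleles are coded ``0`` (or empty) in the native CSV
dialect and ``000`` in GENEPOP exports.

Coordinates, where present, are projected planar meters (e.g. UTM);
distances derived from them are reported in kilometers.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

Call = Optional[tuple[int, int]]

SOURCES = ("faecal", "tissue", "hair", "mouth_swab")


class GenodataError(ValueError):
    """Malformed genotype/sample input."""


def make_call(a, b) -> Call:
    """Build a canonical (sorted) diploid call; both alleles or neither.

    ``0``/``None``/empty strings code a missing allele.  A half-missing
    pair is rejected: it cannot be distinguished from a dropout artefact.
    """
    a = _parse_allele(a)
    b = _parse_allele(b)
    if a is None and b is None:
        return None
    if a is None or b is None:
        raise GenodataError(f"half-missing call ({a!r}, {b!r})")
    if a <= 0 or b <= 0:
        raise GenodataError(f"allele sizes must be positive integers, got ({a}, {b})")
    return (a, b) if a <= b else (b, a)


def _parse_allele(v) -> Optional[int]:
    if v is None:
        return None
    if isinstance(v, str):
        v = v.strip()
        if v == "" or v == "0":
            return None
        return int(v)
    v = int(v)
    return None if v == 0 else v


@dataclass(frozen=True)
class Locus:
    name: str
    kind: str = "autosomal"  # autosomal | sexing
    allele_universe: frozenset[int] = frozenset()

    def __post_init__(self):
        if self.kind not in ("autosomal", "sexing"):
            raise GenodataError(f"unknown locus kind {self.kind!r}")


@dataclass
class SampleRecord:
    """One replicate amplification of one sample."""

    sample_id: str
    source: str
    replicate_id: int = 1
    station_id: Optional[str] = None
    x: Optional[float] = None
    y: Optional[float] = None
    date: Optional[str] = None
    calls: dict[str, Call] = field(default_factory=dict)

    def __post_init__(self):
        if self.replicate_id < 1:
            raise GenodataError("replicate_id must be >= 1")
        if (self.x is None) != (self.y is None):
            raise GenodataError("coordinates must be both present or both absent")


@dataclass
class SampleTable:
    records: list[SampleRecord]
    panel: list[Locus]

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.panel]

    def by_sample(self) -> dict[str, list[SampleRecord]]:
        """Replicates grouped per sample, ordered by replicate_id."""
        out: dict[str, list[SampleRecord]] = {}
        for r in self.records:
            out.setdefault(r.sample_id, []).append(r)
        for reps in out.values():
            reps.sort(key=lambda r: r.replicate_id)
        return out


@dataclass
class GenotypeTable:
    """Consensus multilocus genotypes, one row per sample or individual."""

    rows: dict[str, dict[str, Call]]
    panel: list[Locus]
    groups: Optional[dict[str, str]] = None

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.panel]

    @property
    def autosomal_loci(self) -> list[str]:
        return [l.name for l in self.panel if l.kind == "autosomal"]

    def call(self, ind: str, locus: str) -> Call:
        return self.rows[ind].get(locus)

    def n_nonmissing(self, locus: str) -> int:
        return sum(1 for r in self.rows.values() if r.get(locus) is not None)

    def subset(self, ids: Optional[Sequence[str]] = None,
               loci: Optional[Sequence[str]] = None) -> "GenotypeTable":
        ids = list(self.rows) if ids is None else list(ids)
        loci = self.locus_names if loci is None else list(loci)
        known = {l.name: l for l in self.panel}
        missing = [l for l in loci if l not in known]
        if missing:
            raise GenodataError(f"unknown loci {missing}")
        rows = {i: {l: self.rows[i].get(l) for l in loci if self.rows[i].get(l) is not None}
                for i in ids}
        groups = None
        if self.groups is not None:
            groups = {i: self.groups[i] for i in ids if i in self.groups}
        return GenotypeTable(rows=rows, panel=[known[l] for l in loci], groups=groups)


# ---------------------------------------------------------------------------
# native CSV dialect

_META_COLS = ["sample_id", "source", "replicate_id", "station_id", "x", "y", "date"]


def read_sample_table(path, panel: Sequence[Locus]) -> SampleTable:
    """Read per-amplification allele calls from the native CSV schema.

    Columns: sample_id, source, replicate_id, station_id, x, y, date, then
    two columns per locus named ``<locus>_1`` and ``<locus>_2``.
    """
    panel = list(panel)
    names = {l.name for l in panel}
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        loci_in_file = _loci_from_header(header)
        unknown = [l for l in loci_in_file if l not in names]
        if unknown:
            raise GenodataError(f"unknown loci in {path}: {unknown}")
        for i, row in enumerate(reader, start=2):
            try:
                records.append(_record_from_row(row, loci_in_file))
            except (GenodataError, ValueError, KeyError) as e:
                raise GenodataError(f"{path} row {i}: {e}") from e
    return SampleTable(records=records, panel=panel)


def _loci_from_header(header: Sequence[str]) -> list[str]:
    loci = []
    for col in header:
        m = re.fullmatch(r"(.+)_1", col)
        if m and f"{m.group(1)}_2" in header:
            loci.append(m.group(1))
    return loci


def _record_from_row(row: Mapping[str, str], loci: Sequence[str]) -> SampleRecord:
    def opt(col):
        v = (row.get(col) or "").strip()
        return v or None

    x, y = opt("x"), opt("y")
    calls = {}
    for l in loci:
        try:
            c = make_call(row[f"{l}_1"], row[f"{l}_2"])
        except GenodataError as e:
            raise GenodataError(f"locus {l}: {e}") from e
        if c is not None:
            calls[l] = c
    return SampleRecord(
        sample_id=row["sample_id"].strip(),
        source=row["source"].strip(),
        replicate_id=int(row.get("replicate_id") or 1),
        station_id=opt("station_id"),
        x=float(x) if x is not None else None,
        y=float(y) if y is not None else None,
        date=opt("date"),
        calls=calls,
    )


def write_sample_table(table: SampleTable, path) -> None:
    loci = table.locus_names
    cols = _META_COLS + [f"{l}_{i}" for l in loci for i in (1, 2)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for r in table.records:
            row = [r.sample_id, r.source, r.replicate_id, r.station_id or "",
                   "" if r.x is None else r.x, "" if r.y is None else r.y, r.date or ""]
            for l in loci:
                c = r.calls.get(l)
                row += [0, 0] if c is None else [c[0], c[1]]
            w.writerow(row)


def read_genotype_table(path, panel: Sequence[Locus]) -> GenotypeTable:
    """Read one-row-per-individual genotypes (id, group, then <locus>_1/_2)."""
    panel = list(panel)
    names = {l.name for l in panel}
    rows: dict[str, dict[str, Call]] = {}
    groups: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        loci_in_file = _loci_from_header(reader.fieldnames or [])
        unknown = [l for l in loci_in_file if l not in names]
        if unknown:
            raise GenodataError(f"unknown loci in {path}: {unknown}")
        for i, row in enumerate(reader, start=2):
            ind = row["id"].strip()
            if ind in rows:
                raise GenodataError(f"{path} row {i}: duplicate id {ind!r}")
            calls = {}
            for l in loci_in_file:
                try:
                    c = make_call(row[f"{l}_1"], row[f"{l}_2"])
                except GenodataError as e:
                    raise GenodataError(f"{path} row {i}, locus {l}: {e}") from e
                if c is not None:
                    calls[l] = c
            rows[ind] = calls
            g = (row.get("group") or "").strip()
            if g:
                groups[ind] = g
    return GenotypeTable(rows=rows, panel=panel, groups=groups or None)


def write_genotype_table(gt: GenotypeTable, path) -> None:
    loci = gt.locus_names
    cols = ["id", "group"] + [f"{l}_{i}" for l in loci for i in (1, 2)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for ind, calls in gt.rows.items():
            row = [ind, (gt.groups or {}).get(ind, "")]
            for l in loci:
                c = calls.get(l)
                row += [0, 0] if c is None else [c[0], c[1]]
            w.writerow(row)


# ---------------------------------------------------------------------------
# allele frequencies

@dataclass
class AlleleFrequencyTable:
    """Per-locus allele counts and relative frequencies from non-missing rows."""

    counts: dict[str, dict[int, int]]      # locus -> allele -> gene count
    n_ind: dict[str, int]                  # locus -> genotyped individuals n_l

    def freqs(self, locus: str) -> dict[int, float]:
        tot = 2 * self.n_ind[locus]
        return {a: c / tot for a, c in self.counts[locus].items()}

    def n_alleles(self, locus: str) -> int:
        return len(self.counts[locus])

    def gene_count(self, locus: str) -> int:
        return 2 * self.n_ind[locus]


def allele_frequencies(gt: GenotypeTable,
                       loci: Optional[Iterable[str]] = None) -> AlleleFrequencyTable:
    loci = list(loci) if loci is not None else gt.locus_names
    counts: dict[str, dict[int, int]] = {}
    n_ind: dict[str, int] = {}
    for l in loci:
        cnt: dict[int, int] = {}
        n = 0
        for calls in gt.rows.values():
            c = calls.get(l)
            if c is None:
                continue
            n += 1
            for a in c:
                cnt[a] = cnt.get(a, 0) + 1
        if n == 0:
            raise GenodataError(f"locus {l}: no non-missing genotypes")
        counts[l] = dict(sorted(cnt.items()))
        n_ind[l] = n
    return AlleleFrequencyTable(counts=counts, n_ind=n_ind)


# ---------------------------------------------------------------------------
# GENEPOP dialect

def write_genepop(gt: GenotypeTable, path, title: str = "scatpop export") -> None:
    """Write autosomal loci in the GENEPOP dialect (3-digit alleles, 000 = missing)."""
    loci = gt.autosomal_loci
    for l in loci:
        for calls in gt.rows.values():
            c = calls.get(l)
            if c and max(c) > 999:
                raise GenodataError(
                    f"locus {l}: allele size {max(c)} > 999; offset-recode alleles "
                    "(e.g. subtract a locus-wise constant) before GENEPOP export")
    groups = gt.groups or {i: "pop" for i in gt.rows}
    order: list[str] = []
    for i in gt.rows:
        g = groups.get(i, "pop")
        if g not in order:
            order.append(g)
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for l in loci:
            fh.write(l + "\n")
        for g in order:
            fh.write("Pop\n")
            for ind, calls in gt.rows.items():
                if groups.get(ind, "pop") != g:
                    continue
                codes = []
                for l in loci:
                    c = calls.get(l)
                    codes.append("000000" if c is None else f"{c[0]:03d}{c[1]:03d}")
                fh.write(f"{ind} ,  " + " ".join(codes) + "\n")


def read_genepop(path) -> GenotypeTable:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenodataError("empty GENEPOP file")
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        # locus names may be one per line or comma-separated
        loci += [t.strip() for t in body[i].split(",") if t.strip()]
        i += 1
    rows: dict[str, dict[str, Call]] = {}
    groups: dict[str, str] = {}
    pop = 0
    for line in body[i:]:
        s = line.strip()
        if not s:
            continue
        if s.lower() == "pop":
            pop += 1
            continue
        if "," not in s:
            raise GenodataError(f"malformed GENEPOP genotype line: {s!r}")
        ind, geno = s.split(",", 1)
        ind = ind.strip()
        codes = geno.split()
        if len(codes) != len(loci):
            raise GenodataError(f"{ind}: expected {len(loci)} genotypes, got {len(codes)}")
        calls: dict[str, Call] = {}
        for l, code in zip(loci, codes):
            if len(code) not in (4, 6):
                raise GenodataError(f"{ind}/{l}: bad genotype code {code!r}")
            k = len(code) // 2
            a, b = int(code[:k]), int(code[k:])
            c = make_call(a, b)
            if c is not None:
                calls[l] = c
        rows[ind] = calls
        groups[ind] = f"pop{pop}"
    panel = [Locus(name=l) for l in loci]
    return GenotypeTable(rows=rows, panel=panel, groups=groups)
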