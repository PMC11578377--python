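"""Genomic coordinate primitives and plain-text format I/O.

Everything downstream works on a single coordinate convention: 0-based,
half-open intervals (BED-native). GTF gene records (1-based, inclusive) are
converted on read. Coverage is held run-length encoded per chromosome with a
prefix-integral index so that interval counts and RPKM are O(log runs).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ParseError",
    "ValidationError",
    "Factor",
    "Condition",
    "GenomeLayout",
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "CoverageTrack",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_genes",
    "write_genes",
    "rpkm",
    "quantify",
]


class ParseError(ValueError):
    """A malformed line in an input file (carries the 1-based line number)."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


class ValidationError(ValueError):
    """Input violates a coordinate or consistency invariant."""


class Factor(str, Enum):
    SIN3B = "SIN3B"
    HDAC1 = "HDAC1"
    H3K27AC = "H3K27Ac"


class Condition(str, Enum):
    CONTROL = "control"
    KO = "KO"


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths: the coordinate universe."""

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in layout")
        for name, length in self.chroms:
            if length <= 0:
                raise ValidationError(f"chromosome {name} has non-positive length")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chroms]

    def length(self, chrom: str) -> int:
        for name, length in self.chroms:
            if name == chrom:
                return length
        raise ValidationError(f"unknown chromosome {chrom!r}")

    def order(self, chrom: str) -> int:
        for i, (name, _) in enumerate(self.chroms):
            if name == chrom:
                return i
        raise ValidationError(f"unknown chromosome {chrom!r}")

    @property
    def genome_size(self) -> int:
        return sum(length for _, length in self.chroms)

    @classmethod
    def from_sizes(cls, sizes: Iterable[tuple[str, int]]) -> "GenomeLayout":
        return cls(tuple((str(n), int(l)) for n, l in sizes))


_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in _STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called peak for one factor in one condition."""

    interval: GenomicInterval
    factor: Factor
    condition: Condition

    def __post_init__(self):
        object.__setattr__(self, "factor", Factor(self.factor))
        object.__setattr__(self, "condition", Condition(self.condition))


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware transcription start site."""

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        # half-open: the 5' basepair of a - strand gene is end - 1
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


def _validate_in_layout(iv: GenomicInterval, layout: GenomeLayout, where: str = "") -> None:
    length = layout.length(iv.chrom)
    if iv.end > length:
        raise ValidationError(
            f"{where}interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length {length}"
        )


def sort_intervals(
    intervals: Iterable[GenomicInterval], layout: GenomeLayout
) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (layout.order(iv.chrom), iv.start, iv.end))


# ---------------------------------------------------------------------------
# BED


def read_bed(path, layout: GenomeLayout) -> list[GenomicInterval]:
    """Read BED3/BED6 into validated, sorted intervals (strand '.' if absent)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, f"expected >=3 tab-separated fields, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric score {fields[4]!r}") from None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                iv = GenomicInterval(chrom, start, end, strand, name, score)
                _validate_in_layout(iv, layout)
            except ValidationError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            out.append(iv)
    return sort_intervals(out, layout)


def write_bed(path, intervals: Sequence[GenomicInterval], layout: GenomeLayout) -> None:
    """Write sorted BED6."""
    with open(path, "w") as fh:
        for iv in sort_intervals(intervals, layout):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Coverage


class CoverageTrack:
    """Run-length encoded, non-negative coverage over a genome layout.

    Per chromosome the runs are stored as ``bounds`` (run boundaries,
    bounds[0] == 0, bounds[-1] == chromosome length) and ``values``
    (len(bounds) - 1 read densities in reads per basepair). ``total_mapped``
    is the RPKM denominator.
    """

    def __init__(
        self,
        layout: GenomeLayout,
        data: dict[str, tuple[np.ndarray, np.ndarray]],
        total_mapped: float | None = None,
    ):
        self.layout = layout
        self._bounds: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, length in layout.chroms:
            if chrom in data:
                bounds, values = data[chrom]
                bounds = np.asarray(bounds, dtype=np.int64)
                values = np.asarray(values, dtype=np.float64)
            else:
                bounds = np.array([0, length], dtype=np.int64)
                values = np.zeros(1)
            if bounds[0] != 0 or bounds[-1] != length or len(values) != len(bounds) - 1:
                raise ValidationError(f"runs do not tile chromosome {chrom}")
            if np.any(np.diff(bounds) <= 0):
                raise ValidationError(f"non-increasing run boundaries on {chrom}")
            if np.any(values < 0):
                raise ValidationError(f"negative coverage on {chrom}")
            self._bounds[chrom] = bounds
            self._values[chrom] = values
            self._cum[chrom] = np.concatenate(
                [[0.0], np.cumsum(values * np.diff(bounds))]
            )
        inferred = sum(float(self._cum[c][-1]) for c in self._cum)
        if total_mapped is None:
            total_mapped = round(inferred)
        if total_mapped <= 0:
            raise ValidationError("total_mapped must be > 0")
        self.total_mapped = float(total_mapped)

    @classmethod
    def from_binned(
        cls,
        layout: GenomeLayout,
        binned: dict[str, np.ndarray],
        bin_size: int,
        total_mapped: float | None = None,
    ) -> "CoverageTrack":
        """Build from per-bin read counts; values become counts / bin_size."""
        data = {}
        for chrom, length in layout.chroms:
            counts = np.asarray(binned[chrom], dtype=np.float64)
            n_bins = int(np.ceil(length / bin_size))
            if len(counts) != n_bins:
                raise ValidationError(f"{chrom}: expected {n_bins} bins, got {len(counts)}")
            widths = np.full(n_bins, bin_size, dtype=np.int64)
            widths[-1] = length - bin_size * (n_bins - 1)
            values = counts / widths
            # merge equal adjacent runs
            keep = np.concatenate([[True], values[1:] != values[:-1]])
            starts = np.concatenate([[0], np.cumsum(widths)])[:-1][keep]
            bounds = np.concatenate([starts, [length]])
            data[chrom] = (bounds, values[keep])
        return cls(layout, data, total_mapped=total_mapped)

    def _integral(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of coverage density over [0, pos)."""
        bounds, values, cum = self._bounds[chrom], self._values[chrom], self._cum[chrom]
        pos = np.asarray(pos, dtype=np.int64)
        idx = np.searchsorted(bounds, pos, side="right") - 1
        idx = np.clip(idx, 0, len(values) - 1)
        return cum[idx] + values[idx] * (pos - bounds[idx])

    def count(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-basepair coverage over the half-open interval."""
        if chrom not in self._bounds:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        length = self.layout.length(chrom)
        if not (0 <= start <= end <= length):
            raise ValidationError(f"interval {chrom}:{start}-{end} outside layout")
        if start == end:
            return 0.0
        lo, hi = self._integral(chrom, np.array([start, end]))
        return float(hi - lo)

    def counts(self, intervals: Sequence[GenomicInterval]) -> np.ndarray:
        out = np.empty(len(intervals))
        for i, iv in enumerate(intervals):
            out[i] = self.count(iv.chrom, iv.start, iv.end)
        return out

    def values_per_bp(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-basepair densities over a (small) interval."""
        bounds, values = self._bounds[chrom], self._values[chrom]
        pos = np.arange(start, end, dtype=np.int64)
        idx = np.searchsorted(bounds, pos, side="right") - 1
        return values[np.clip(idx, 0, len(values) - 1)]

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._bounds[chrom].copy(), self._values[chrom].copy()


def read_bedgraph(
    path, layout: GenomeLayout, total_mapped: float | None = None
) -> CoverageTrack:
    """Read 4-column bedGraph; uncovered basepairs are zero-filled.

    Records must not overlap. ``total_mapped`` defaults to
    round(sum(value * length)) over all records.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(path, lineno, f"expected 4 fields, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise ParseError(path, lineno, "malformed bedGraph record") from None
            if value < 0:
                raise ParseError(path, lineno, f"negative coverage value {value}")
            try:
                length = layout.length(chrom)
            except ValidationError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            if not (0 <= start < end <= length):
                raise ParseError(path, lineno, f"coordinates outside {chrom} (length {length})")
            per_chrom.setdefault(chrom, []).append((start, end, value))
    data = {}
    for chrom, length in layout.chroms:
        recs = sorted(per_chrom.get(chrom, []))
        bounds = [0]
        values = []
        cursor = 0
        for start, end, value in recs:
            if start < cursor:
                raise ValidationError(
                    f"overlapping bedGraph records on {chrom} near {start}"
                )
            if start > cursor:
                values.append(0.0)
                bounds.append(start)
            values.append(value)
            bounds.append(end)
            cursor = end
        if cursor < length:
            values.append(0.0)
            bounds.append(length)
        data[chrom] = (np.array(bounds, dtype=np.int64), np.array(values))
    return CoverageTrack(layout, data, total_mapped=total_mapped)


def write_bedgraph(path, track: CoverageTrack, include_zero: bool = False) -> None:
    """Write sorted bedGraph (zero runs omitted unless include_zero)."""
    with open(path, "w") as fh:
        for chrom in track.layout.names:
            bounds, values = track.runs(chrom)
            for i, v in enumerate(values):
                if v == 0 and not include_zero:
                    continue
                fh.write(f"{chrom}\t{bounds[i]}\t{bounds[i + 1]}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Genes

_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def read_genes(path, layout: GenomeLayout, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from BED6 (strand required) or GTF "gene" records.

    Format is inferred from the extension unless ``fmt`` ("bed" or "gtf") is
    given. Duplicate gene ids are rejected; TSS is strand-aware.
    """
    if fmt is None:
        fmt = "gtf" if str(path).endswith((".gtf", ".gff")) else "bed"
    genes: list[GeneModel] = []
    seen: set[str] = set()

    def _add(gene_id, chrom, start, end, strand, lineno):
        if gene_id in seen:
            raise ParseError(path, lineno, f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        try:
            iv = GenomicInterval(chrom, start, end, strand, gene_id)
            _validate_in_layout(iv, layout)
            genes.append(GeneModel(gene_id, iv))
        except ValidationError as exc:
            raise ParseError(path, lineno, str(exc)) from None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "bed":
                if len(fields) < 6:
                    raise ParseError(path, lineno, "gene BED requires 6 columns (strand)")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError:
                    raise ParseError(path, lineno, "non-integer coordinates") from None
                _add(fields[3], fields[0], start, end, fields[5], lineno)
            else:
                if len(fields) < 9:
                    raise ParseError(path, lineno, "GTF requires 9 columns")
                if fields[2] != "gene":
                    continue
                m = _GTF_GENE_ID.search(fields[8])
                if not m:
                    raise ParseError(path, lineno, "gene record without gene_id attribute")
                try:
                    start, end = int(fields[3]), int(fields[4])
                except ValueError:
                    raise ParseError(path, lineno, "non-integer coordinates") from None
                # GTF is 1-based inclusive
                _add(m.group(1), fields[0], start - 1, end, fields[6], lineno)
    genes.sort(key=lambda g: (layout.order(g.interval.chrom), g.interval.start))
    return genes


def write_genes(path, genes: Sequence[GeneModel], layout: GenomeLayout) -> None:
    write_bed(path, [g.interval for g in genes], layout)


# ---------------------------------------------------------------------------
# Normalization


def rpkm(count: float, length: int, total_mapped: float) -> float:
    """Reads per kilobase per million mapped reads."""
    if length <= 0:
        raise ValidationError("rpkm: length must be > 0")
    if total_mapped <= 0:
        raise ValidationError("rpkm: total_mapped must be > 0")
    return count / ((length / 1e3) * (total_mapped / 1e6))


def quantify(
    track: CoverageTrack, intervals: Sequence[GenomicInterval]
) -> list[tuple[float, float]]:
    """Per-interval (count, RPKM) under the track's library size."""
    out = []
    for iv in intervals:
        c = track.count(iv.chrom, iv.start, iv.end)
        out.append((c, rpkm(c, len(iv), track.total_mapped)))
    return out


def quantify_union(track: CoverageTrack, intervals: Sequence[GenomicInterval]) -> tuple[float, float]:
    """(count, RPKM) over the union of intervals (assumed disjoint)."""
    total_len = sum(len(iv) for iv in intervals)
    if total_len == 0:
        raise ValidationError("empty region")
    count = sum(track.count(iv.chrom, iv.start, iv.end) for iv in intervals)
    return count, rpkm(count, total_len, track.total_mapped)
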