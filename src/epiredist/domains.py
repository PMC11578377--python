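"""Condition-lost binding-domain calling on a genome-wide window grid.

A binding domain is the merge of 6-kb windows that contain at least one
control-condition peak and no knockout-condition peak — i.e. where the
factor's occupancy disappears after knockout. Co-occupancy of two factors
over the called domains is summarised as a Pearson correlation of per-domain
log10 RPKM.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .genomic_io import (
    CoverageTrack,
    GenomeLayout,
    GenomicInterval,
    Peak,
    ValidationError,
    quantify,
)

__all__ = [
    "WindowGrid",
    "BindingDomainSet",
    "CorrelationReport",
    "tile",
    "call_lost_domains",
    "select_peaks_in_domains",
    "domain_correlation",
    "signal_matrix",
    "match_domains",
]


@dataclass(frozen=True)
class WindowGrid:
    """Windows of fixed size tiling each chromosome (last one truncated)."""

    layout: GenomeLayout
    window_size: int
    step: int
    windows: tuple[GenomicInterval, ...]

    def chrom_indices(self, chrom: str) -> tuple[int, int]:
        """Half-open index range of this chromosome's windows."""
        lo = None
        hi = 0
        for i, w in enumerate(self.windows):
            if w.chrom == chrom:
                if lo is None:
                    lo = i
                hi = i + 1
        return (0, 0) if lo is None else (lo, hi)


@dataclass(frozen=True)
class BindingDomainSet:
    """Merged qualifying windows, with contributing window indices."""

    domains: tuple[GenomicInterval, ...]
    provenance: tuple[tuple[int, ...], ...]

    def __len__(self) -> int:
        return len(self.domains)


@dataclass(frozen=True)
class CorrelationReport:
    n_domains: int
    log10_a: np.ndarray
    log10_b: np.ndarray
    r: float
    p: float
    undefined: bool = False


def tile(layout: GenomeLayout, window_size: int = 6000, step: int | None = None) -> WindowGrid:
    """Tile every chromosome with windows [k*step, k*step + window_size)."""
    if step is None:
        step = window_size
    if step <= 0:
        raise ValidationError("step must be > 0")
    if window_size <= 0 or step > window_size:
        raise ValidationError("need 0 < step <= window_size")
    windows: list[GenomicInterval] = []
    for chrom, length in layout.chroms:
        k = 0
        while k * step < length:
            start = k * step
            windows.append(GenomicInterval(chrom, start, min(start + window_size, length)))
            k += 1
    return WindowGrid(layout, window_size, step, tuple(windows))


def _mark_hits(
    grid: WindowGrid, peaks: Sequence[Peak], layout: GenomeLayout
) -> np.ndarray:
    """Boolean per-window flag: does any peak overlap the window by >=1 bp?"""
    hit = np.zeros(len(grid.windows), dtype=bool)
    starts = np.array([w.start for w in grid.windows])
    ends = np.array([w.end for w in grid.windows])
    for chrom in layout.names:
        lo, hi = grid.chrom_indices(chrom)
        if hi == lo:
            continue
        cs, ce = starts[lo:hi], ends[lo:hi]
        for pk in peaks:
            iv = pk.interval
            if iv.chrom != chrom:
                continue
            # windows with start < iv.end and end > iv.start
            first = int(np.searchsorted(ce, iv.start, side="right"))
            last = int(np.searchsorted(cs, iv.end, side="left"))
            if last > first:
                hit[lo + first : lo + last] = True
    return hit


def call_lost_domains(
    control_peaks: Sequence[Peak], ko_peaks: Sequence[Peak], grid: WindowGrid
) -> BindingDomainSet:
    """Merge windows that a control peak overlaps and no KO peak touches.

    Qualification is binary presence/absence at >=1 bp overlap; overlapping
    and book-ended qualifying windows are merged into maximal domains.
    """
    factors = {p.factor for p in control_peaks} | {p.factor for p in ko_peaks}
    if len(factors) > 1:
        raise ValidationError(f"mixed factors in peak lists: {sorted(f.value for f in factors)}")
    ctrl_hit = _mark_hits(grid, control_peaks, grid.layout)
    ko_hit = _mark_hits(grid, ko_peaks, grid.layout)
    qualifying = ctrl_hit & ~ko_hit

    domains: list[GenomicInterval] = []
    provenance: list[tuple[int, ...]] = []
    cur: list[int] = []

    def _flush():
        if not cur:
            return
        ws = [grid.windows[i] for i in cur]
        domains.append(
            GenomicInterval(
                ws[0].chrom,
                min(w.start for w in ws),
                max(w.end for w in ws),
                name=f"domain_{len(domains) + 1}",
                score=float(len(ws)),
            )
        )
        provenance.append(tuple(cur))
        cur.clear()

    for i, q in enumerate(qualifying):
        if not q:
            continue
        if cur:
            prev = grid.windows[cur[-1]]
            w = grid.windows[i]
            if w.chrom != prev.chrom or w.start > prev.end:
                _flush()
        cur.append(i)
    _flush()
    return BindingDomainSet(tuple(domains), tuple(provenance))


def select_peaks_in_domains(
    peaks: Sequence[Peak], domains: BindingDomainSet
) -> list[Peak]:
    """Peaks overlapping any domain by >=1 bp, in input order."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for d in domains.domains:
        by_chrom.setdefault(d.chrom, []).append((d.start, d.end))
    starts = {c: np.array([s for s, _ in ivs]) for c, ivs in by_chrom.items()}
    ends = {c: np.array([e for _, e in ivs]) for c, ivs in by_chrom.items()}
    out = []
    for pk in peaks:
        iv = pk.interval
        if iv.chrom not in starts:
            continue
        s, e = starts[iv.chrom], ends[iv.chrom]
        # domains are sorted and disjoint: overlap iff some start < iv.end and end > iv.start
        first = int(np.searchsorted(e, iv.start, side="right"))
        if first < len(s) and s[first] < iv.end:
            out.append(pk)
    return out


def domain_correlation(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    domains: BindingDomainSet,
    pseudocount: float = 0.01,
) -> CorrelationReport:
    """Pearson correlation of per-domain log10(RPKM + pseudocount).

    The p-value is the two-sided t transform with n - 2 degrees of freedom.
    Zero variance in either axis yields an explicit undefined report.
    """
    if len(domains) < 3:
        raise ValidationError("need >= 3 domains for a correlation")
    qa = quantify(track_a, domains.domains)
    qb = quantify(track_b, domains.domains)
    x = np.log10(np.array([r for _, r in qa]) + pseudocount)
    y = np.log10(np.array([r for _, r in qb]) + pseudocount)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationReport(len(domains), x, y, float("nan"), float("nan"), undefined=True)
    res = stats.pearsonr(x, y)
    return CorrelationReport(len(domains), x, y, float(res.statistic), float(res.pvalue))


def signal_matrix(
    track: CoverageTrack,
    anchors: Sequence[tuple[str, int, str]],
    flank: int,
    n_bins: int,
) -> np.ndarray:
    """Mean coverage in n_bins equal bins over [anchor - flank, anchor + flank).

    Each anchor is (chrom, position, strand); rows of minus-strand anchors are
    reversed so that bin 0 is always the 5' side. Bins falling outside the
    chromosome contribute their in-bounds part (0 if fully outside).
    """
    if flank <= 0 or n_bins <= 0:
        raise ValidationError("flank and n_bins must be > 0")
    mat = np.zeros((len(anchors), n_bins))
    edges_rel = np.rint(np.linspace(-flank, flank, n_bins + 1)).astype(np.int64)
    for i, (chrom, pos, strand) in enumerate(anchors):
        length = track.layout.length(chrom)
        edges = np.clip(edges_rel + pos, 0, length)
        for j in range(n_bins):
            lo, hi = int(edges[j]), int(edges[j + 1])
            if hi > lo:
                mat[i, j] = track.count(chrom, lo, hi) / (hi - lo)
        if strand == "-":
            mat[i] = mat[i, ::-1]
    return mat


def match_domains(
    called: Sequence[GenomicInterval],
    planted: Sequence[GenomicInterval],
    min_jaccard: float = 0.5,
) -> tuple[float, float]:
    """(recall, precision) of called vs planted domains at a Jaccard cutoff.

    A planted domain is recovered if some called domain reaches the Jaccard
    threshold against it; a called domain is correct if it reaches the
    threshold against some planted domain.
    """

    def jac(a: GenomicInterval, b: GenomicInterval) -> float:
        if a.chrom != b.chrom:
            return 0.0
        inter = min(a.end, b.end) - max(a.start, b.start)
        if inter <= 0:
            return 0.0
        union = (a.end - a.start) + (b.end - b.start) - inter
        return inter / union

    recovered = sum(1 for p in planted if any(jac(c, p) >= min_jaccard for c in called))
    correct = sum(1 for c in called if any(jac(c, p) >= min_jaccard for p in planted))
    recall = recovered / len(planted) if planted else 1.0
    precision = correct / len(called) if called else 1.0
    return recall, precision
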