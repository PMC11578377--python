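"""Region-level histone-mark quantification and super-enhancer calling.

Signal is assigned to four strand-aware region classes per gene — promoter
(TSS +/- flank), super-enhancer (stitched high-signal enhancer clusters
assigned to the nearest TSS), gene body (gene minus promoter) and the whole
gene (gene union promoter). Per-region RPKM fold changes between conditions
are flagged as gained (FC >= threshold) or lost (FC <= 1/threshold).

Super-enhancers follow the community-standard rank-signal procedure:
promoter-overlapping peaks are removed, remaining peaks within a stitch gap
are merged, stitched regions are ranked by total signal, rank and signal are
scaled to [0, 1], and the knee is the point past which the discrete tangent
slope of the scaled curve exceeds 1.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Peak,
    ValidationError,
    quantify_union,
)

__all__ = [
    "RegionClass",
    "SuperEnhancerSet",
    "gene_regions",
    "call_super_enhancers",
    "region_gain",
    "gain_gene_sets",
]

log = logging.getLogger(__name__)


class RegionClass(str, Enum):
    PRO = "Pro"
    SE = "SE"
    GB = "GB"
    ALL = "All"


@dataclass(frozen=True)
class SuperEnhancerSet:
    """Stitched enhancers ranked by total signal, split at the knee."""

    stitched: tuple[GenomicInterval, ...]  # ascending total signal
    signals: tuple[float, ...]
    cutoff_index: int  # stitched[cutoff_index:] are super-enhancers
    gene_assignment: dict[int, str]  # stitched index -> gene_id

    @property
    def super_enhancers(self) -> tuple[GenomicInterval, ...]:
        return self.stitched[self.cutoff_index :]

    def gene_se_intervals(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for i in range(self.cutoff_index, len(self.stitched)):
            gid = self.gene_assignment.get(i)
            if gid is not None:
                out.setdefault(gid, []).append(self.stitched[i])
        return out

    @classmethod
    def empty(cls) -> "SuperEnhancerSet":
        return cls((), (), 0, {})


def gene_regions(
    genes: Sequence[GeneModel],
    promoter_flank: int = 3000,
    ses: SuperEnhancerSet | None = None,
) -> dict[str, dict[RegionClass, list[GenomicInterval]]]:
    """Per-gene intervals for each region class.

    Pro = [tss - flank, tss + flank) clipped to the chromosome; GB = gene
    minus Pro; All = gene union Pro; SE = stitched super-enhancers assigned
    to the gene (possibly none).
    """
    se_by_gene = ses.gene_se_intervals() if ses is not None else {}
    out: dict[str, dict[RegionClass, list[GenomicInterval]]] = {}
    for g in genes:
        iv = g.interval
        pro_start = max(0, g.tss - promoter_flank)
        pro_end = g.tss + promoter_flank
        pro = GenomicInterval(iv.chrom, pro_start, pro_end, iv.strand, g.gene_id)
        gb: list[GenomicInterval] = []
        if iv.start < pro.start:
            gb.append(GenomicInterval(iv.chrom, iv.start, min(iv.end, pro.start), iv.strand, g.gene_id))
        if iv.end > pro.end:
            gb.append(GenomicInterval(iv.chrom, max(iv.start, pro.end), iv.end, iv.strand, g.gene_id))
        all_start = min(iv.start, pro.start)
        all_end = max(iv.end, pro.end)
        out[g.gene_id] = {
            RegionClass.PRO: [pro],
            RegionClass.GB: gb,
            RegionClass.ALL: [GenomicInterval(iv.chrom, all_start, all_end, iv.strand, g.gene_id)],
            RegionClass.SE: list(se_by_gene.get(g.gene_id, [])),
        }
    return out


def _merge_within(intervals: list[GenomicInterval], gap: int) -> list[GenomicInterval]:
    merged: list[list] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start)):
        if merged and merged[-1][0] == iv.chrom and iv.start <= merged[-1][2] + gap:
            merged[-1][2] = max(merged[-1][2], iv.end)
        else:
            merged.append([iv.chrom, iv.start, iv.end])
    return [GenomicInterval(c, s, e) for c, s, e in merged]


def call_super_enhancers(
    h3k27ac_peaks: Sequence[Peak],
    track: CoverageTrack,
    promoters: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    stitch_gap: int = 12500,
    assignment_radius: int = 50000,
) -> SuperEnhancerSet:
    """Rank-signal super-enhancer calling on promoter-distal stitched peaks."""
    pro_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in promoters:
        pro_by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    for c in pro_by_chrom:
        pro_by_chrom[c].sort()

    def in_promoter(iv: GenomicInterval) -> bool:
        for s, e in pro_by_chrom.get(iv.chrom, []):
            if s < iv.end and iv.start < e:
                return True
        return False

    distal = [pk.interval for pk in h3k27ac_peaks if not in_promoter(pk.interval)]
    stitched = _merge_within(distal, stitch_gap)
    if len(stitched) < 3:
        warnings.warn("fewer than 3 stitched enhancer regions: no super-enhancers called")
        return SuperEnhancerSet.empty()

    signals = np.array([track.count(iv.chrom, iv.start, iv.end) for iv in stitched])
    order = np.argsort(signals, kind="stable")
    stitched = [stitched[i] for i in order]
    signals = signals[order]

    n = len(signals)
    span = signals[-1] - signals[0]
    if span == 0:
        cutoff = n  # flat curve: no region stands out
    else:
        y = (signals - signals[0]) / span
        x = np.arange(n) / (n - 1)
        slopes = np.diff(y) / np.diff(x)
        # knee: where the scaled curve's tangent slope first exceeds 1;
        # everything above is disproportionately strong. A curve never
        # steeper than the diagonal has no knee and yields no SEs.
        above = np.nonzero(slopes > 1)[0]
        cutoff = int(above[0]) + 1 if len(above) else n

    tss = [(g.interval.chrom, g.tss, g.gene_id) for g in genes]
    assignment: dict[int, str] = {}
    for idx in range(cutoff, n):
        iv = stitched[idx]
        mid = (iv.start + iv.end) // 2
        best, best_d = None, None
        for chrom, pos, gid in tss:
            if chrom != iv.chrom:
                continue
            d = abs(pos - mid)
            if best_d is None or d < best_d:
                best, best_d = gid, d
        if best is not None and best_d is not None and best_d <= assignment_radius:
            assignment[idx] = best
    return SuperEnhancerSet(
        tuple(stitched), tuple(float(s) for s in signals), cutoff, assignment
    )


def region_gain(
    ctrl_track: CoverageTrack,
    ko_track: CoverageTrack,
    regions: dict[str, dict[RegionClass, list[GenomicInterval]]],
    threshold: float = 1.3,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Per (gene, region class) RPKM fold change with gain/loss flags.

    FC = (KO RPKM + pc) / (control RPKM + pc); gained iff FC >= threshold
    (inclusive), lost iff FC <= 1/threshold. Genes with an empty region are
    omitted for that class with a log notice.
    """
    if threshold <= 1:
        raise ValidationError("threshold must exceed 1")
    rows = []
    for gene_id, classes in regions.items():
        for cls, ivs in classes.items():
            total = sum(len(iv) for iv in ivs)
            if total == 0:
                log.info("region %s/%s empty: row omitted", gene_id, cls.value)
                continue
            _, ctrl = quantify_union(ctrl_track, ivs)
            _, ko = quantify_union(ko_track, ivs)
            fc = (ko + pseudocount) / (ctrl + pseudocount)
            rows.append(
                {
                    "gene_id": gene_id,
                    "region_class": cls.value,
                    "ctrl_rpkm": ctrl,
                    "ko_rpkm": ko,
                    "fc": fc,
                    "gained": fc >= threshold,
                    "lost": fc <= 1.0 / threshold,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "region_class", "ctrl_rpkm", "ko_rpkm", "fc", "gained", "lost"],
    )


def gain_gene_sets(table: pd.DataFrame) -> dict[RegionClass, set[str]]:
    """Genes flagged gained, per region class."""
    out: dict[RegionClass, set[str]] = {cls: set() for cls in RegionClass}
    if table.empty:
        return out
    for cls in RegionClass:
        sub = table[(table["region_class"] == cls.value) & table["gained"]]
        out[cls] = set(sub["gene_id"])
    return out


def loss_gene_sets(table: pd.DataFrame) -> dict[RegionClass, set[str]]:
    """Genes flagged lost, per region class."""
    out: dict[RegionClass, set[str]] = {cls: set() for cls in RegionClass}
    if table.empty:
        return out
    for cls in RegionClass:
        sub = table[(table["region_class"] == cls.value) & table["lost"]]
        out[cls] = set(sub["gene_id"])
    return out
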