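"""Gene-set integration of differential expression with mark redistribution.

Combines up-regulated DEGs with per-region-class mark gain/loss sets into
Venn-style overlap counts, both-direction overlap fractions and one-sided
hypergeometric enrichment p-values, plus the headline pairwise statistic:
the fraction of mark-gained genes that also lost the co-repressor signal.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
from scipy import stats

from .genomic_io import ValidationError
from .marks import RegionClass

__all__ = [
    "OverlapStats",
    "IntegrationReport",
    "overlap",
    "gain_loss_fraction",
    "region_gain_counts",
    "build_report",
]


@dataclass(frozen=True)
class OverlapStats:
    n_a: int
    n_b: int
    n_intersection: int
    n_universe: int
    frac_of_a: float
    frac_of_b: float
    p_enrichment: float

    def as_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_intersection": self.n_intersection,
            "n_a_only": self.n_a - self.n_intersection,
            "n_b_only": self.n_b - self.n_intersection,
            "n_universe": self.n_universe,
            "frac_of_a": self.frac_of_a,
            "frac_of_b": self.frac_of_b,
            "p_enrichment": self.p_enrichment,
        }


def overlap(set_a: set[str], set_b: set[str], universe: set[str]) -> OverlapStats:
    """Venn counts, both-direction fractions and hypergeometric upper-tail p.

    p = P(X >= |a n b|) for X ~ Hypergeometric(N=|universe|, K=|a|, n=|b|).
    """
    if not set_a <= universe or not set_b <= universe:
        raise ValidationError("sets must be subsets of the universe")
    k = len(set_a & set_b)
    n_a, n_b, n_u = len(set_a), len(set_b), len(universe)
    p = float(stats.hypergeom.sf(k - 1, n_u, n_a, n_b)) if n_u else 1.0
    return OverlapStats(
        n_a=n_a,
        n_b=n_b,
        n_intersection=k,
        n_universe=n_u,
        frac_of_a=k / n_a if n_a else 0.0,
        frac_of_b=k / n_b if n_b else 0.0,
        p_enrichment=min(p, 1.0),
    )


def gain_loss_fraction(gain_genes: set[str], loss_genes: set[str]) -> float:
    """|gain n loss| / |gain| (0, flagged via log, when gain is empty)."""
    if not gain_genes:
        return 0.0
    return len(gain_genes & loss_genes) / len(gain_genes)


def region_gain_counts(
    up_degs: set[str], table: pd.DataFrame
) -> dict[RegionClass, int]:
    """Per region class, how many up-DEGs carry a mark gain in that class."""
    out: dict[RegionClass, int] = {}
    for cls in RegionClass:
        if table.empty:
            out[cls] = 0
            continue
        gained = set(
            table[(table["region_class"] == cls.value) & table["gained"]]["gene_id"]
        )
        out[cls] = len(up_degs & gained)
    return out


@dataclass
class IntegrationReport:
    """All integration statistics of one pipeline run."""

    universe_size: int
    n_up_degs: int
    per_class: dict[str, OverlapStats]  # region class -> up-DEGs vs gain set
    up_deg_gain_counts: dict[str, int]
    mark_pair: dict  # H3K27Ac-gained vs HDAC1-lost statistics
    meta: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "universe_size": self.universe_size,
            "n_up_degs": self.n_up_degs,
            "per_class": {c: s.as_dict() for c, s in self.per_class.items()},
            "up_deg_gain_counts": self.up_deg_gain_counts,
            "mark_pair": self.mark_pair,
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        rows = []
        for cls, s in self.per_class.items():
            row = {"section": "up_degs_vs_gain", "region_class": cls}
            row.update(s.as_dict())
            rows.append(row)
        mp = {"section": "h3k27ac_gain_vs_hdac1_loss", "region_class": "."}
        mp.update(self.mark_pair)
        rows.append(mp)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_report(
    up_degs: set[str],
    gain_sets: Mapping[RegionClass, set[str]],
    hdac1_loss_genes: set[str],
    universe: set[str],
    gain_table: pd.DataFrame | None = None,
    gain_class_for_pair: RegionClass = RegionClass.PRO,
    meta: dict | None = None,
) -> IntegrationReport:
    """Assemble the overlap/Venn statistics from upstream stage outputs."""
    per_class = {
        cls.value: overlap(up_degs, gain_sets.get(cls, set()), universe)
        for cls in RegionClass
    }
    gained = gain_sets.get(gain_class_for_pair, set())
    pair_stats = overlap(gained, hdac1_loss_genes & universe, universe)
    mark_pair = pair_stats.as_dict()
    mark_pair["gain_class"] = gain_class_for_pair.value
    mark_pair["frac_gained_also_lost"] = gain_loss_fraction(gained, hdac1_loss_genes)
    if gain_table is not None:
        counts = {
            cls.value: n for cls, n in region_gain_counts(up_degs, gain_table).items()
        }
    else:
        counts = {
            cls.value: len(up_degs & gain_sets.get(cls, set())) for cls in RegionClass
        }
    return IntegrationReport(
        universe_size=len(universe),
        n_up_degs=len(up_degs),
        per_class=per_class,
        up_deg_gain_counts=counts,
        mark_pair=mark_pair,
        meta=meta or {},
    )
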