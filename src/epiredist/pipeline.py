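"""Stage orchestration: file-based pipeline stages and in-memory analysis.

Each stage reads the standard-format inputs named in the flat config, writes
its outputs into the run directory, and can be run individually or via
``run_all`` in dependency order. ``analyze`` runs the same logic on an
in-memory simulation result and returns the headline measured quantities —
used by the end-to-end recovery checks.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import MissingInputError, PipelineConfig
from .domains import (
    BindingDomainSet,
    call_lost_domains,
    domain_correlation,
    match_domains,
    tile,
)
from .expression import DEResult, ExpressionMatrix, de_test, tpm, up_gene_set
from .genomic_io import (
    Condition,
    Factor,
    GenomeLayout,
    GenomicInterval,
    Peak,
    read_bed,
    read_bedgraph,
    read_genes,
    write_bed,
)
from .integrate import IntegrationReport, build_report, gain_loss_fraction
from .marks import (
    RegionClass,
    SuperEnhancerSet,
    call_super_enhancers,
    gain_gene_sets,
    gene_regions,
    loss_gene_sets,
    region_gain,
)
from .simulate import SimConfig, SimResult, simulate, write_fixture

log = logging.getLogger(__name__)

_FACTOR_SLUG = {Factor.SIN3B: "sin3b", Factor.HDAC1: "hdac1", Factor.H3K27AC: "h3k27ac"}


def load_layout(cfg: PipelineConfig, stage: str) -> GenomeLayout:
    path = cfg.require_path("chrom_sizes", stage)
    sizes = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, length = line.split("\t")[:2]
                sizes.append((name, int(length)))
    return GenomeLayout.from_sizes(sizes)


def _read_peaks(cfg: PipelineConfig, layout, factor: Factor, cond: Condition, stage: str):
    key = f"peaks_{_FACTOR_SLUG[factor]}_{cond.value.lower()}"
    path = cfg.require_path(key, stage)
    return [Peak(iv, factor, cond) for iv in read_bed(path, layout)]

def _read_track(cfg: PipelineConfig, layout, factor: Factor, cond: Condition, stage: str):
    key = f"track_{_FACTOR_SLUG[factor]}_{cond.value.lower()}"
    path = cfg.require_path(key, stage)
    return read_bedgraph(path, layout, total_mapped=cfg.total_mapped(key))


# ---------------------------------------------------------------------------
# file-based stages


def stage_simulate(outdir, seed: int = 42, sim_config: SimConfig | None = None):
    """Generate the synthetic fixture and write it under outdir."""
    cfg = sim_config if sim_config is not None else SimConfig(seed=seed)
    result = simulate(cfg)
    manifest = write_fixture(result, outdir)
    log.info("simulate: wrote %d files to %s", len(manifest), outdir)
    return result


def stage_call_domains(cfg: PipelineConfig, outdir: Path) -> BindingDomainSet:
    stage = "call-domains"
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = load_layout(cfg, stage)
    ctrl = _read_peaks(cfg, layout, Factor.SIN3B, Condition.CONTROL, stage)
    ko = _read_peaks(cfg, layout, Factor.SIN3B, Condition.KO, stage)
    grid = tile(layout, int(cfg.get("window_size")), int(cfg.get("step")))
    domains = call_lost_domains(ctrl, ko, grid)
    write_bed(outdir / "domains.bed", domains.domains, layout)

    track_a = _read_track(cfg, layout, Factor.SIN3B, Condition.CONTROL, stage)
    track_b = _read_track(cfg, layout, Factor.HDAC1, Condition.CONTROL, stage)
    if len(domains) >= 3:
        rep = domain_correlation(track_a, track_b, domains, float(cfg.get("log_pseudocount")))
        pd.DataFrame(
            [{"n_domains": rep.n_domains, "r": rep.r, "p": rep.p, "undefined": rep.undefined}]
        ).to_csv(outdir / "correlation.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "domain": [d.name for d in domains.domains],
                "log10_sin3b": rep.log10_a,
                "log10_hdac1": rep.log10_b,
            }
        ).to_csv(outdir / "correlation_scatter.tsv", sep="\t", index=False)
    else:
        log.warning("%s: fewer than 3 domains, correlation skipped", stage)
    log.info("%s: %d domains", stage, len(domains))
    return domains


def stage_call_se(cfg: PipelineConfig, outdir: Path) -> SuperEnhancerSet:
    stage = "call-se"
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = load_layout(cfg, stage)
    genes = read_genes(cfg.require_path("genes", stage), layout)
    cond = Condition(cfg.get("se_condition"))
    peaks = _read_peaks(cfg, layout, Factor.H3K27AC, cond, stage)
    track = _read_track(cfg, layout, Factor.H3K27AC, cond, stage)
    flank = int(cfg.get("promoter_flank"))
    promoters = [
        GenomicInterval(g.interval.chrom, max(0, g.tss - flank), g.tss + flank)
        for g in genes
    ]
    ses = call_super_enhancers(
        peaks,
        track,
        promoters,
        genes,
        stitch_gap=int(cfg.get("stitch_gap")),
        assignment_radius=int(cfg.get("se_assignment_radius")),
    )
    rows = [
        GenomicInterval(
            iv.chrom,
            iv.start,
            iv.end,
            ".",
            ses.gene_assignment.get(i, "."),
            float(i),
        )
        for i, iv in enumerate(ses.stitched)
        if i >= ses.cutoff_index
    ]
    write_bed(outdir / "se.bed", rows, layout)
    pd.DataFrame(
        {
            "rank": np.arange(len(ses.signals)),
            "signal": ses.signals,
            "is_se": [i >= ses.cutoff_index for i in range(len(ses.signals))],
        }
    ).to_csv(outdir / "se_rank_curve.tsv", sep="\t", index=False)
    log.info("%s: %d super-enhancers of %d stitched", stage, len(rows), len(ses.stitched))
    return ses


def _ses_from_bed(path, layout) -> SuperEnhancerSet:
    ivs = read_bed(path, layout)
    assignment = {i: iv.name for i, iv in enumerate(ivs) if iv.name != "."}
    return SuperEnhancerSet(tuple(ivs), tuple(iv.score for iv in ivs), 0, assignment)


def stage_quantify_marks(cfg: PipelineConfig, outdir: Path) -> dict[str, pd.DataFrame]:
    stage = "quantify-marks"
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = load_layout(cfg, stage)
    genes = read_genes(cfg.require_path("genes", stage), layout)
    se_path = outdir / "se.bed"
    if not se_path.exists():
        raise MissingInputError(stage, str(se_path), hint="call-se")
    ses = _ses_from_bed(se_path, layout)
    regions = gene_regions(genes, int(cfg.get("promoter_flank")), ses)
    tables = {}
    for slug, factor in (("h3k27ac", Factor.H3K27AC), ("hdac1", Factor.HDAC1)):
        ctrl = _read_track(cfg, layout, factor, Condition.CONTROL, stage)
        ko = _read_track(cfg, layout, factor, Condition.KO, stage)
        table = region_gain(
            ctrl,
            ko,
            regions,
            threshold=float(cfg.get("fc_threshold")),
            pseudocount=float(cfg.get("fc_pseudocount")),
        )
        table.to_csv(outdir / f"gain_{slug}.tsv", sep="\t", index=False)
        tables[slug] = table
    return tables


def stage_de(cfg: PipelineConfig, outdir: Path) -> DEResult:
    stage = "de"
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_path = cfg.require_path("counts", stage)
    conditions = {}
    for s in str(cfg.get("control_samples")).split(","):
        if s:
            conditions[s] = "control"
    for s in str(cfg.get("ko_samples")).split(","):
        if s:
            conditions[s] = "KO"
    matrix = ExpressionMatrix.read_tsv(counts_path, conditions)
    result = de_test(
        matrix,
        fc_cutoff=float(cfg.get("fc_cutoff")),
        alpha=float(cfg.get("alpha")),
        pseudocount=float(cfg.get("tpm_pseudocount")),
        adjust=bool(cfg.get("adjust_p")),
    )
    result.table.to_csv(outdir / "de.tsv", sep="\t", index_label="gene_id")
    return result


def stage_integrate(cfg: PipelineConfig, outdir: Path) -> IntegrationReport:
    stage = "integrate"
    outdir = Path(outdir)
    layout = load_layout(cfg, stage)
    genes = read_genes(cfg.require_path("genes", stage), layout)
    universe = {g.gene_id for g in genes}

    de_path = outdir / "de.tsv"
    if not de_path.exists():
        raise MissingInputError(stage, str(de_path), hint="de")
    de_table = pd.read_csv(de_path, sep="\t").set_index("gene_id")
    for slug in ("h3k27ac", "hdac1"):
        if not (outdir / f"gain_{slug}.tsv").exists():
            raise MissingInputError(stage, str(outdir / f"gain_{slug}.tsv"), hint="quantify-marks")
    ac_table = pd.read_csv(outdir / "gain_h3k27ac.tsv", sep="\t")
    hd_table = pd.read_csv(outdir / "gain_hdac1.tsv", sep="\t")

    if bool(cfg.get("expressed_only")):
        counts_path = cfg.require_path("counts", stage)
        conditions = {}
        for s in str(cfg.get("control_samples")).split(","):
            if s:
                conditions[s] = "control"
        for s in str(cfg.get("ko_samples")).split(","):
            if s:
                conditions[s] = "KO"
        matrix = ExpressionMatrix.read_tsv(counts_path, conditions)
        expressed = set(tpm(matrix).mean(axis=1).loc[lambda s: s > 1.0].index)
        universe = universe & expressed

    up = set(de_table.index[de_table["flag"] == "up"]) & universe
    gain_sets = {c: s & universe for c, s in gain_gene_sets(ac_table).items()}
    loss_all = loss_gene_sets(hd_table)[RegionClass.ALL] & universe
    report = build_report(
        up,
        gain_sets,
        loss_all,
        universe,
        gain_table=ac_table,
        gain_class_for_pair=RegionClass(cfg.get("pair_gain_class")),
        meta={"config_sha256": cfg.sha256(), "seed": int(cfg.get("seed"))},
    )
    report.to_json(outdir / "report.json")
    report.to_tsv(outdir / "report.tsv")
    return report


_STAGES = ("call-domains", "call-se", "quantify-marks", "de", "integrate")


def run_all(cfg: PipelineConfig, outdir: Path) -> IntegrationReport:
    """Run every analysis stage in dependency order."""
    stage_call_domains(cfg, outdir)
    stage_call_se(cfg, outdir)
    stage_quantify_marks(cfg, outdir)
    stage_de(cfg, outdir)
    return stage_integrate(cfg, outdir)


# ---------------------------------------------------------------------------
# in-memory end-to-end analysis (recovery of planted parameters)


def analyze(result: SimResult) -> dict:
    """Run the full analysis on an in-memory simulation and score recovery.

    Returns the measured headline quantities together with their planted
    values: called-domain recall/precision (Jaccard >= 0.5), co-occupancy
    Pearson r over the called domains, the fraction of promoter-H3K27Ac-
    gained genes that also lost whole-gene HDAC1 signal, and up-DEG recall.
    """
    cfg = result.config
    layout = cfg.layout
    grid = tile(layout, 6000, 6000)
    domains = call_lost_domains(
        result.peaks[(Factor.SIN3B, Condition.CONTROL)],
        result.peaks[(Factor.SIN3B, Condition.KO)],
        grid,
    )
    recall, precision = match_domains(
        domains.domains, result.truth.planted_domains, min_jaccard=0.5
    )
    corr = domain_correlation(
        result.tracks[(Factor.SIN3B, Condition.CONTROL)],
        result.tracks[(Factor.HDAC1, Condition.CONTROL)],
        domains,
    )

    genes = result.genes
    flank = cfg.promoter_flank
    promoters = [
        GenomicInterval(g.interval.chrom, max(0, g.tss - flank), g.tss + flank)
        for g in genes
    ]
    ses = call_super_enhancers(
        result.peaks[(Factor.H3K27AC, Condition.KO)],
        result.tracks[(Factor.H3K27AC, Condition.KO)],
        promoters,
        genes,
    )
    regions = gene_regions(genes, flank, ses)
    ac_table = region_gain(
        result.tracks[(Factor.H3K27AC, Condition.CONTROL)],
        result.tracks[(Factor.H3K27AC, Condition.KO)],
        regions,
    )
    hd_table = region_gain(
        result.tracks[(Factor.HDAC1, Condition.CONTROL)],
        result.tracks[(Factor.HDAC1, Condition.KO)],
        regions,
    )
    gain_sets = gain_gene_sets(ac_table)
    loss_all = loss_gene_sets(hd_table)[RegionClass.ALL]
    frac = gain_loss_fraction(gain_sets[RegionClass.PRO], loss_all)

    de = de_test(result.counts)
    up = up_gene_set(de)
    truth_up = result.truth.up_genes
    up_recall = len(up & truth_up) / len(truth_up) if truth_up else 1.0

    universe = {g.gene_id for g in genes}
    report = build_report(up, gain_sets, loss_all, universe, gain_table=ac_table)

    truth_se = result.truth.gain_genes[RegionClass.SE]
    se_assigned = set(ses.gene_assignment.values())
    se_recall = len(se_assigned & truth_se) / len(truth_se) if truth_se else 1.0

    return {
        "n_domains_called": len(domains),
        "domain_recall": recall,
        "domain_precision": precision,
        "cooccupancy_r": corr.r,
        "cooccupancy_p": corr.p,
        "gain_loss_fraction": frac,
        "planted_gain_loss_fraction": result.truth.achieved_gain_loss_fraction,
        "up_deg_recall": up_recall,
        "n_up_degs": len(up),
        "se_gene_recall": se_recall,
        "report": report,
        "gain_sets": gain_sets,
        "hdac1_loss_genes": loss_all,
        "domains": domains,
        "de": de,
    }
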