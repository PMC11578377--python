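"""Synthetic two-condition, three-factor epigenome with planted ground truth.

The generator emulates the statistical structure of a knockout experiment on
a chromatin co-repressor complex: SIN3B peaks present in control vanish in
KO at planted domains, HDAC1 log-signal over those domains tracks SIN3B
log-signal at a chosen Pearson correlation, H3K27Ac coverage gains at the
promoters/super-enhancers of a planted gene subset, HDAC1 gene-level signal
drops for a planted subset overlapping the gainers at a chosen fraction,
and RNA-seq counts are negative-binomial with a planted log2 fold change
for an upregulated subset linked to the gainers.

Layout: genes live in fixed-pitch slots (enhancers upstream, promoter at the
TSS); planted domains and condition-shared background peaks are placed in
intergenic free space on disjoint 4x-domain-length cells, which guarantees
the >= 2x-domain-length spacing that keeps window merging unambiguous.

Coverage is sampled as Poisson counts per fixed-size bin, with expected
counts integrated exactly over the piecewise-constant rate profile, then
run-length encoded. All randomness flows from one seeded generator.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .genomic_io import (
    Condition,
    CoverageTrack,
    Factor,
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    Peak,
    ValidationError,
    write_bed,
    write_bedgraph,
    write_genes,
)
from .marks import RegionClass

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "simulate",
    "simulate_counts",
    "sample_cooccupancy_latents",
    "write_fixture",
]

_DEFAULT_LAYOUT = GenomeLayout((("chr1", 10_000_000), ("chr2", 10_000_000)))

# fixed offsets inside a gene slot (basepairs from slot start)
_SE_PEAK_OFFSETS = (500, 2000, 3500)
_SE_PEAK_WIDTH = 1200
_TYP_ENH_OFFSET = 2000
_TYP_ENH_WIDTH = 1500
_GENE_OFFSET = 8000
_SLOT_OCCUPIED = 30_000  # slot prefix reserved for gene features + margin
_MIN_SLOT = 40_000


@dataclass
class SimConfig:
    """All knobs of the synthetic epigenome; defaults are the study conditions."""

    seed: int = 42
    layout: GenomeLayout = field(default_factory=lambda: _DEFAULT_LAYOUT)
    n_genes: int = 500
    n_domains: int = 50
    domain_length: int = 6000
    cooccupancy_r: float = 0.87
    frac_gain_with_hdac1_loss: float = 0.494
    n_up_genes: int = 60
    up_log2fc: float = 1.0
    nb_dispersion: float = 0.01
    reads_per_track: int = 5_000_000  # expected background reads per track
    n_reps: int = 3
    # shape parameters of the planted signal
    bin_size: int = 100
    promoter_flank: int = 3000
    n_gain_pro: int = 120
    n_gain_se: int = 40
    n_hdac1_loss: int = 100
    n_shared_peaks: int = 200
    domain_signal_scale: float = 2.0  # reads/bp at the mean planted domain
    domain_log10_sd: float = 0.35
    h3k27ac_gain_fc: float = 2.0
    hdac1_loss_frac: float = 0.5  # KO/control HDAC1 ratio at loss genes
    hdac1_domain_ko_frac: float = 0.3
    base_mean: float = 800.0  # NB mean counts, log-normal across genes
    base_log_sd: float = 0.8
    frac_up_from_gain: float = 0.75

    def __post_init__(self):
        if not 0 < self.cooccupancy_r < 1:
            raise ValidationError("cooccupancy_r must be in (0, 1)")
        if not 0 <= self.frac_gain_with_hdac1_loss <= 1:
            raise ValidationError("frac_gain_with_hdac1_loss must be in [0, 1]")
        if self.n_domains * self.domain_length >= self.layout.genome_size / 10:
            raise ValidationError(
                "domains would cover >= 1/10 of the genome: enlarge the layout"
            )
        if self.n_gain_pro + self.n_gain_se > self.n_genes:
            raise ValidationError("gain sets exceed gene count")
        if self.n_up_genes > self.n_genes:
            raise ValidationError("n_up_genes exceeds gene count")
        if self.n_reps < 2:
            raise ValidationError("need >= 2 replicates per condition")


@dataclass
class GroundTruth:
    planted_domains: tuple[GenomicInterval, ...]
    latent_log10_sin3b: np.ndarray
    latent_log10_hdac1: np.ndarray
    gain_genes: dict[RegionClass, frozenset[str]]
    hdac1_loss_genes: frozenset[str]
    up_genes: frozenset[str]
    achieved_gain_loss_fraction: float
    se_constituents: dict[str, tuple[GenomicInterval, ...]]


@dataclass
class SimResult:
    config: SimConfig
    genes: list[GeneModel]
    peaks: dict[tuple[Factor, Condition], list[Peak]]
    tracks: dict[tuple[Factor, Condition], CoverageTrack]
    counts: ExpressionMatrix
    truth: GroundTruth


def sample_cooccupancy_latents(
    rng: np.random.Generator,
    n: int,
    r: float,
    mean: float = 0.0,
    sd: float = 0.35,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent log10 signal pairs with population Pearson correlation r.

    y = x + noise with var_noise = var_x * (1 - r^2) / r^2, so that
    corr(x, y) = var_x / (sd_x * sd_x / r) = r.
    """
    x = rng.normal(mean, sd, n)
    noise_sd = sd * np.sqrt(1.0 - r * r) / r
    y = x + rng.normal(0.0, noise_sd, n)
    return x, y


def simulate_counts(
    rng: np.random.Generator,
    gene_ids: list[str],
    lengths: np.ndarray,
    up_genes: set[str],
    up_log2fc: float = 1.0,
    dispersion: float = 0.01,
    n_reps: int = 3,
    base_mean: float = 800.0,
    base_log_sd: float = 0.8,
) -> ExpressionMatrix:
    """NB gene x sample counts with a planted fold change for up_genes.

    Mean counts are log-normal across genes; replicates are i.i.d.
    NB(mean mu, variance mu + dispersion * mu^2) via Gamma-Poisson mixing.
    """
    n = len(gene_ids)
    mu = np.exp(rng.normal(np.log(base_mean), base_log_sd, n))
    up_mask = np.array([g in up_genes for g in gene_ids])
    mu_ko = mu * np.where(up_mask, 2.0 ** up_log2fc, 1.0)

    def _nb(mean_vec: np.ndarray, reps: int) -> np.ndarray:
        m = np.tile(mean_vec[:, None], (1, reps))
        if dispersion > 0:
            lam = rng.gamma(1.0 / dispersion, m * dispersion)
        else:
            lam = m
        return rng.poisson(lam)

    ctrl = _nb(mu, n_reps)
    ko = _nb(mu_ko, n_reps)
    cols = [f"control_{i + 1}" for i in range(n_reps)] + [f"KO_{i + 1}" for i in range(n_reps)]
    counts = pd.DataFrame(np.hstack([ctrl, ko]), index=gene_ids, columns=cols)
    conditions = {c: ("control" if c.startswith("control") else "KO") for c in cols}
    return ExpressionMatrix(counts, pd.Series(lengths, index=gene_ids), conditions)


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    chroms = cfg.layout.chroms
    per_chrom = [cfg.n_genes // len(chroms)] * len(chroms)
    for i in range(cfg.n_genes % len(chroms)):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    gid = 0
    for (chrom, length), n_c in zip(chroms, per_chrom):
        if n_c == 0:
            continue
        pitch = length // n_c
        if pitch < _MIN_SLOT:
            raise ValidationError(
                f"infeasible placement: {n_c} genes need {_MIN_SLOT} bp slots on {chrom}"
            )
        for i in range(n_c):
            gid += 1
            slot = i * pitch
            glen = int(np.clip(np.exp(rng.normal(np.log(5000), 0.4)), 1000, 12000))
            strand = "+" if rng.random() < 0.5 else "-"
            start = slot + _GENE_OFFSET
            genes.append(
                GeneModel(
                    f"gene{gid:04d}",
                    GenomicInterval(chrom, start, start + glen, strand, f"gene{gid:04d}"),
                )
            )
    return genes


def _slot_start(g: GeneModel) -> int:
    return g.interval.start - _GENE_OFFSET


def _free_cells(cfg: SimConfig, genes: list[GeneModel]) -> list[tuple[str, int, int]]:
    """Disjoint placement cells (chrom, start, max_jitter) in intergenic space.

    Large gaps are chopped into 4x-domain-length cells with up to one
    domain-length of jitter, which keeps any two placements >= 2 domain
    lengths apart; gaps that fit only one domain become a single low-jitter
    cell. Gaps themselves are separated by the occupied gene slots, so
    placements in different gaps are always far apart.
    """
    L = cfg.domain_length
    big = 4 * L
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.layout.names}
    for g in genes:
        s = _slot_start(g)
        occupied[g.interval.chrom].append((s, s + _SLOT_OCCUPIED))
    cells: list[tuple[str, int, int]] = []
    for chrom, length in cfg.layout.chroms:
        ivs = sorted(occupied[chrom])
        cursor = 0
        gaps = []
        for s, e in ivs + [(length, length)]:
            if s > cursor:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        for gs, ge in gaps:
            glen = ge - gs
            n_big = glen // big
            if n_big:
                for k in range(n_big):
                    cells.append((chrom, gs + k * big, L))
            elif glen >= L:
                cells.append((chrom, gs, min(4000, glen - L)))
    return cells


def simulate(config: SimConfig) -> SimResult:
    """Run the generator; deterministic given config (including its seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    layout = cfg.layout
    genes = _place_genes(cfg, rng)
    gene_ids = [g.gene_id for g in genes]
    gene_by_id = {g.gene_id: g for g in genes}

    # --- planted gene sets -------------------------------------------------
    perm = list(rng.permutation(gene_ids))
    gain_pro = set(perm[: cfg.n_gain_pro])
    gain_se = set(perm[cfg.n_gain_pro : cfg.n_gain_pro + cfg.n_gain_se])
    others = perm[cfg.n_gain_pro + cfg.n_gain_se :]
    k_overlap = int(round(cfg.frac_gain_with_hdac1_loss * cfg.n_gain_pro))
    loss_from_gain = set(rng.choice(sorted(gain_pro), k_overlap, replace=False))
    n_loss_extra = max(0, cfg.n_hdac1_loss - k_overlap)
    if n_loss_extra > len(others):
        raise ValidationError("not enough genes outside the gain sets for HDAC1-loss genes")
    loss_extra = set(rng.choice(others, n_loss_extra, replace=False))
    hdac1_loss = loss_from_gain | loss_extra
    achieved_frac = len(gain_pro & hdac1_loss) / len(gain_pro) if gain_pro else 0.0

    n_from_gain = min(int(round(cfg.frac_up_from_gain * cfg.n_up_genes)), cfg.n_gain_pro + cfg.n_gain_se)
    up_from_gain = set(rng.choice(sorted(gain_pro | gain_se), n_from_gain, replace=False))
    up_rest_pool = [g for g in others if g not in loss_extra]
    up_rest = set(rng.choice(up_rest_pool, cfg.n_up_genes - n_from_gain, replace=False))
    up_genes = up_from_gain | up_rest

    # --- planted domains and shared peaks ----------------------------------
    cells = _free_cells(cfg, genes)
    need = cfg.n_domains + cfg.n_shared_peaks
    if len(cells) < need:
        raise ValidationError(
            f"infeasible placement: {need} cells needed, {len(cells)} intergenic cells available"
        )
    chosen = rng.choice(len(cells), need, replace=False)
    domain_cells = [cells[i] for i in chosen[: cfg.n_domains]]
    shared_cells = [cells[i] for i in chosen[cfg.n_domains :]]
    placed = []
    for chrom, start, jitter in domain_cells:
        off = int(rng.integers(0, jitter + 1))
        placed.append(GenomicInterval(chrom, start + off, start + off + cfg.domain_length))
    placed.sort(key=lambda iv: (layout.order(iv.chrom), iv.start))
    domains = [
        GenomicInterval(iv.chrom, iv.start, iv.end, ".", f"planted_{i + 1}")
        for i, iv in enumerate(placed)
    ]
    shared = []
    for i, (chrom, start, jitter) in enumerate(shared_cells):
        off = int(rng.integers(0, jitter + 1))
        width = int(rng.integers(500, 2001))
        shared.append(
            GenomicInterval(chrom, start + off, start + off + width, ".", f"shared_{i + 1}")
        )

    lat_x, lat_y = sample_cooccupancy_latents(
        rng,
        cfg.n_domains,
        cfg.cooccupancy_r,
        mean=np.log10(cfg.domain_signal_scale),
        sd=cfg.domain_log10_sd,
    )

    # --- per-gene fixture features ------------------------------------------
    pro_rate = np.exp(rng.normal(np.log(0.8), 0.3, len(genes)))
    se_by_gene: dict[str, tuple[GenomicInterval, ...]] = {}
    typ_enh: list[GenomicInterval] = []
    for g in genes:
        s = _slot_start(g)
        chrom = g.interval.chrom
        if g.gene_id in gain_se:
            se_by_gene[g.gene_id] = tuple(
                GenomicInterval(chrom, s + off, s + off + _SE_PEAK_WIDTH, ".", g.gene_id)
                for off in _SE_PEAK_OFFSETS
            )
        else:
            typ_enh.append(
                GenomicInterval(chrom, s + _TYP_ENH_OFFSET, s + _TYP_ENH_OFFSET + _TYP_ENH_WIDTH)
            )

    def promoter(g: GeneModel) -> GenomicInterval:
        return GenomicInterval(
            g.interval.chrom,
            max(0, g.tss - cfg.promoter_flank),
            g.tss + cfg.promoter_flank,
            g.interval.strand,
            g.gene_id,
        )

    def whole(g: GeneModel) -> GenomicInterval:
        p = promoter(g)
        return GenomicInterval(
            g.interval.chrom,
            min(g.interval.start, p.start),
            max(g.interval.end, p.end),
            g.interval.strand,
            g.gene_id,
        )

    # --- rate profiles -------------------------------------------------------
    bg = cfg.reads_per_track / layout.genome_size
    # H3K27Ac is a broad mark: its genome-wide background runs higher, which
    # also keeps the planted gains a small fraction of the library so that
    # RPKM fold changes at unchanged genes stay near 1
    bg_by_factor = {Factor.SIN3B: bg, Factor.HDAC1: bg, Factor.H3K27AC: 2.0 * bg}
    shared_rate = 1.0
    hdac1_gene_rate = 1.5
    gb_rate = 0.1
    typ_rate = 0.3
    base_se_rate = 1.5
    # super-enhancer strengths are log-spread (5x-30x typical enhancers),
    # giving the convex rank-signal curve the knee rule expects
    se_rate_by_gene = {
        gid: base_se_rate * 10.0 ** rng.uniform(0.0, 0.8) for gid in sorted(gain_se)
    }

    def ops_for(factor: Factor, cond: Condition) -> list[tuple[str, int, int, float]]:
        ops: list[tuple[str, int, int, float]] = []
        if factor is Factor.SIN3B:
            for iv in shared:
                ops.append((iv.chrom, iv.start, iv.end, shared_rate))
            if cond is Condition.CONTROL:
                for iv, x in zip(domains, lat_x):
                    ops.append((iv.chrom, iv.start, iv.end, 10.0 ** x - bg))
        elif factor is Factor.HDAC1:
            for g in genes:
                iv = whole(g)
                rate = hdac1_gene_rate
                if cond is Condition.KO and g.gene_id in hdac1_loss:
                    rate *= cfg.hdac1_loss_frac
                ops.append((iv.chrom, iv.start, iv.end, rate))
            for iv, y in zip(domains, lat_y):
                r = 10.0 ** y
                if cond is Condition.KO:
                    r *= cfg.hdac1_domain_ko_frac
                ops.append((iv.chrom, iv.start, iv.end, r - bg))
        else:  # H3K27Ac
            for g, pr in zip(genes, pro_rate):
                rate = pr
                if cond is Condition.KO and g.gene_id in gain_pro:
                    rate *= cfg.h3k27ac_gain_fc
                p = promoter(g)
                ops.append((p.chrom, p.start, p.end, rate))
                ops.append((g.interval.chrom, g.interval.start, g.interval.end, gb_rate))
            for iv in typ_enh:
                ops.append((iv.chrom, iv.start, iv.end, typ_rate))
            for gid, ivs in se_by_gene.items():
                rate = se_rate_by_gene[gid]
                if cond is Condition.KO:
                    rate *= cfg.h3k27ac_gain_fc
                for iv in ivs:
                    ops.append((iv.chrom, iv.start, iv.end, rate))
        return ops

    def build_track(ops: list[tuple[str, int, int, float]], bg_rate: float) -> CoverageTrack:
        binned = {}
        for chrom, length in layout.chroms:
            n_bins = int(np.ceil(length / cfg.bin_size))
            widths = np.full(n_bins, cfg.bin_size, dtype=np.int64)
            widths[-1] = length - cfg.bin_size * (n_bins - 1)
            lam = bg_rate * widths.astype(float)
            for c, s, e, rate in ops:
                if c != chrom:
                    continue
                b0 = s // cfg.bin_size
                b1 = (e - 1) // cfg.bin_size
                if b0 == b1:
                    lam[b0] += rate * (e - s)
                else:
                    lam[b0] += rate * ((b0 + 1) * cfg.bin_size - s)
                    lam[b1] += rate * (e - b1 * cfg.bin_size)
                    if b1 > b0 + 1:
                        lam[b0 + 1 : b1] += rate * cfg.bin_size
            binned[chrom] = rng.poisson(np.maximum(lam, 0.0))
        return CoverageTrack.from_binned(layout, binned, cfg.bin_size)

    tracks: dict[tuple[Factor, Condition], CoverageTrack] = {}
    for factor in (Factor.SIN3B, Factor.HDAC1, Factor.H3K27AC):
        for cond in (Condition.CONTROL, Condition.KO):
            tracks[(factor, cond)] = build_track(ops_for(factor, cond), bg_by_factor[factor])

    # --- peak calls (inputs to the pipeline, not derived from the tracks) ---
    peaks: dict[tuple[Factor, Condition], list[Peak]] = {}
    sin_ctrl = [Peak(iv, Factor.SIN3B, Condition.CONTROL) for iv in domains + shared]
    sin_ko = [Peak(iv, Factor.SIN3B, Condition.KO) for iv in shared]
    peaks[(Factor.SIN3B, Condition.CONTROL)] = sorted(
        sin_ctrl, key=lambda p: (layout.order(p.interval.chrom), p.interval.start)
    )
    peaks[(Factor.SIN3B, Condition.KO)] = sorted(
        sin_ko, key=lambda p: (layout.order(p.interval.chrom), p.interval.start)
    )
    hdac_regions = [whole(g) for g in genes]
    peaks[(Factor.HDAC1, Condition.CONTROL)] = [
        Peak(iv, Factor.HDAC1, Condition.CONTROL) for iv in hdac_regions + domains
    ]
    peaks[(Factor.HDAC1, Condition.KO)] = [
        Peak(iv, Factor.HDAC1, Condition.KO) for iv in hdac_regions
    ]
    ac_regions = (
        [promoter(g) for g in genes]
        + typ_enh
        + [iv for ivs in se_by_gene.values() for iv in ivs]
    )
    for cond in (Condition.CONTROL, Condition.KO):
        peaks[(Factor.H3K27AC, cond)] = [Peak(iv, Factor.H3K27AC, cond) for iv in ac_regions]
    for key in peaks:
        peaks[key] = sorted(
            peaks[key], key=lambda p: (layout.order(p.interval.chrom), p.interval.start)
        )

    # --- RNA-seq counts ------------------------------------------------------
    lengths = np.array([len(g.interval) for g in genes])
    counts = simulate_counts(
        rng,
        gene_ids,
        lengths,
        up_genes,
        up_log2fc=cfg.up_log2fc,
        dispersion=cfg.nb_dispersion,
        n_reps=cfg.n_reps,
        base_mean=cfg.base_mean,
        base_log_sd=cfg.base_log_sd,
    )

    truth = GroundTruth(
        planted_domains=tuple(domains),
        latent_log10_sin3b=lat_x,
        latent_log10_hdac1=lat_y,
        gain_genes={
            RegionClass.PRO: frozenset(gain_pro),
            RegionClass.SE: frozenset(gain_se),
            RegionClass.GB: frozenset(),
            RegionClass.ALL: frozenset(gain_pro | gain_se),
        },
        hdac1_loss_genes=frozenset(hdac1_loss),
        up_genes=frozenset(up_genes),
        achieved_gain_loss_fraction=achieved_frac,
        se_constituents=se_by_gene,
    )
    return SimResult(cfg, genes, peaks, tracks, counts, truth)


# ---------------------------------------------------------------------------
# fixture serialization


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture(result: SimResult, outdir) -> pd.DataFrame:
    """Write the fixture in pipeline input formats; returns the manifest.

    Inputs (peaks, tracks, genes, counts, config) are listed in the manifest
    under section "input"; the ground truth is serialized separately under
    section "truth" so that analyses cannot accidentally consume it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    cfg = result.config
    layout = cfg.layout
    files: list[tuple[str, Path]] = []

    sizes = outdir / "chrom_sizes.tsv"
    with open(sizes, "w") as fh:
        for chrom, length in layout.chroms:
            fh.write(f"{chrom}\t{length}\n")
    files.append(("input", sizes))

    genes_path = outdir / "genes.bed"
    write_genes(genes_path, result.genes, layout)
    files.append(("input", genes_path))

    counts_path = outdir / "counts.tsv"
    result.counts.write_tsv(counts_path)
    files.append(("input", counts_path))

    conf: dict[str, object] = {
        "chrom_sizes": sizes.name,
        "genes": genes_path.name,
        "counts": counts_path.name,
        "control_samples": ",".join(result.counts.samples("control")),
        "ko_samples": ",".join(result.counts.samples("KO")),
        "window_size": 6000,
        "step": 6000,
        "promoter_flank": cfg.promoter_flank,
        "stitch_gap": 12500,
        "se_assignment_radius": 50000,
        "fc_threshold": 1.3,
        "fc_pseudocount": 0.1,
        "log_pseudocount": 0.01,
        "fc_cutoff": 1.3,
        "alpha": 0.05,
        "tpm_pseudocount": 1.0,
        "se_condition": "KO",
        "pair_gain_class": "Pro",
        "seed": cfg.seed,
    }
    slug = {Factor.SIN3B: "sin3b", Factor.HDAC1: "hdac1", Factor.H3K27AC: "h3k27ac"}
    for factor, cond in result.peaks:
        name = f"peaks_{slug[factor]}_{cond.value.lower()}"
        path = outdir / f"{name}.bed"
        write_bed(path, [p.interval for p in result.peaks[(factor, cond)]], layout)
        conf[name] = path.name
        files.append(("input", path))
    for factor, cond in result.tracks:
        name = f"track_{slug[factor]}_{cond.value.lower()}"
        path = outdir / f"{name}.bedgraph"
        track = result.tracks[(factor, cond)]
        write_bedgraph(path, track)
        conf[name] = path.name
        conf[f"total_mapped_{name}"] = int(track.total_mapped)
        files.append(("input", path))

    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(conf, fh, sort_keys=True)
    files.append(("input", config_path))

    truth_path = truth_dir / "ground_truth.json"
    import json

    truth = result.truth
    payload = {
        "planted_domains": [
            [iv.chrom, iv.start, iv.end, iv.name] for iv in truth.planted_domains
        ],
        "latent_log10_sin3b": [float(v) for v in truth.latent_log10_sin3b],
        "latent_log10_hdac1": [float(v) for v in truth.latent_log10_hdac1],
        "gain_genes": {cls.value: sorted(s) for cls, s in truth.gain_genes.items()},
        "hdac1_loss_genes": sorted(truth.hdac1_loss_genes),
        "up_genes": sorted(truth.up_genes),
        "achieved_gain_loss_fraction": truth.achieved_gain_loss_fraction,
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files.append(("truth", truth_path))

    manifest = pd.DataFrame(
        [
            {"section": section, "path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
            for section, p in files
        ]
    )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
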