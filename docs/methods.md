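# Methods

## Coordinate model and normalisation

All intervals are 0-based, half-open (BED-native); GTF gene records are
converted on read. A gene's TSS is its strand-aware 5' basepair (`start`
on +, `end − 1` on −). Coverage is stored run-length encoded per
chromosome with a prefix-integral index, so interval counts are exact
integrals of the piecewise-constant density and additive over any
partition. RPKM = count / ((length/1e3) · (total_mapped/1e6)); the library
size comes from a per-track config entry when given, otherwise it is
inferred as round(Σ value·length) of the bedGraph. TPM is
1e6 · (c/L) / Σ(c/L) per sample, so each sample column sums to 1e6.

## Lost binding domains

The genome is tiled with windows of `window_size` (default 6000 bp) at
`step` (default = window size; `window_size/2` gives a half-overlapping
sliding grid). A window qualifies when ≥ 1 control peak overlaps it by
≥ 1 bp and no knockout peak overlaps it; qualifying windows that overlap
or are book-ended merge into domains, with contributing window indices
kept as provenance. Qualification is deliberately binary
(presence/absence), matching a "unique/lost peaks" definition rather than
a signal fold-change test; the overlap rule is ≥ 1 bp, not containment.
Monotonicity follows: adding knockout peaks can only shrink the domain
set, adding control peaks can only grow it.

Co-occupancy over a domain set is Pearson's r between per-domain
log10(RPKM + pseudocount) of two tracks, with the two-sided p from the
t transform on n − 2 df. The pseudocount (default 0.01 RPKM) only guards
against log(0) on empty domains; with no pseudocount the statistic is
invariant to library-size rescaling of either track (a pure log-shift).
Zero variance on either axis yields an explicit `undefined` flag rather
than NaN propagation. Fewer than 3 domains is an error.

## Gene regions and super-enhancers

Per gene: Pro = [TSS − flank, TSS + flank) clipped to the chromosome
(flank default 3000 bp, matching the TSS ± 3 kb profiling window);
GB = gene minus Pro; All = gene ∪ Pro (the promoter flank is included in
the whole-gene class); SE = the super-enhancers assigned to the gene.

Super-enhancers follow the community-standard rank–signal procedure:
promoter-overlapping peaks are removed; remaining peaks within
`stitch_gap` (default 12.5 kb) are stitched; stitched regions are ranked
ascending by total signal; rank and signal are scaled to [0, 1]; the
cutoff is the first rank at which the discrete tangent slope of the
scaled curve exceeds 1, and all higher-ranked regions are super-enhancers.
A flat curve (or one never steeper than the diagonal) yields none; fewer
than 3 stitched regions yields none with a warning. Because the rule is
rank/scale based it is invariant to uniform signal scaling. Each SE is
assigned to the gene with the nearest TSS within `se_assignment_radius`
(default 50 kb), else left unassigned. The ranking condition defaults to
the knockout (where gained SEs are active); it is a config key.

## Gain/loss calling and differential expression

Per (gene, region class): FC = (KO RPKM + pc) / (control RPKM + pc) with
pc = 0.1 RPKM to bound fold changes on near-empty regions. Gained means
FC ≥ threshold (inclusive, default 1.3); lost means FC ≤ 1/threshold.
Empty regions (e.g. GB of a gene shorter than the flank, SE of a gene
without one) are omitted with a log notice.

Differential expression uses the fold-change-plus-p-value scheme: FC of
mean TPM (pseudocount 1 TPM) and a two-sample t-test on log2(TPM + 1).
The pooled-variance (Student) form is used rather than the
unequal-variance (Welch) form: at 3 vs 3 replicates Welch is badly
conservative (empirical size ≈ 0.035 at nominal 0.05 even for ideal
normal data), while the pooled test is calibrated (≈ 0.050 on the
negative-binomial null) and its equal-variance assumption holds when both
conditions share a dispersion. No multiple-testing correction is applied
by default (the thresholding scheme is raw-p based); Benjamini–Hochberg
is available behind `adjust_p`. `up` means FC ≥ cutoff (inclusive) and
p < alpha (strict); `down` is symmetric at 1/cutoff. The default cutoff
is 1.3; 1.5 is selectable.

## Integration

Gene-set overlaps are reported with counts, both-direction fractions
(each set as denominator, since published figures alternate between
them), and a one-sided hypergeometric enrichment p,
P(X ≥ |A∩B|) with N = |universe|, K = |A|, n = |B|. The universe defaults
to all annotated genes; `expressed_only` restricts it to mean TPM > 1.
The pairwise mark statistic — the fraction of H3K27Ac-gained genes that
also lost HDAC1 — uses the promoter-class gain set and the whole-gene
HDAC1 loss set by default (`pair_gain_class` config key), as promoter
signal dominates this mark.

## The synthetic epigenome

The generator emulates the statistical structure of a co-repressor
knockout experiment on a configurable genome (default 2 × 10 Mb). It is
fully deterministic given one seed, and its defaults are the study
conditions the tests assert against.

* **Genes.** `n_genes` (500) in fixed-pitch slots (≥ 40 kb), lengths
  log-normal (median 5 kb, clipped 1–12 kb), random strand. Enhancers sit
  upstream of the slot's gene, outside its promoter.
* **Domains.** `n_domains` 6-kb lost domains placed on disjoint intergenic
  cells that guarantee ≥ 2 domain-lengths of spacing (large gaps are
  chopped into 4×-length cells with jittered offsets; single-domain gaps
  get one low-jitter cell). Control SIN3B peaks span each domain exactly;
  knockout peaks omit them; condition-shared background peaks live in
  other cells, at least a window-length away, so window qualification is
  unambiguous. Infeasible placements raise an error.
* **Co-occupancy.** Per-domain latent log10 signals: X ~ N(log10(scale),
  0.35²) for SIN3B and Y = X + N(0, var_X·(1 − r²)/r²) for HDAC1, giving
  population Pearson correlation exactly r (default 0.87). Domain rates
  replace the background inside the domain, so measured log10 RPKM tracks
  the latent values up to Poisson noise (< 0.01 log10 units at default
  depth); over 5000 domains the sample r recovers the target within
  ± 0.03.
* **Coverage.** Expected counts are integrated exactly over the
  piecewise-constant rate profile and sampled as Poisson counts per
  100-bp bin, then run-length encoded. Background is
  `reads_per_track`/genome (0.25 reads/bp by default); H3K27Ac carries a
  2× background, as fits a broad mark — this also keeps planted gains a
  small fraction of its library, so that RPKM fold changes of unchanged
  genes stay inside [0.9, 1.1] despite the compositional shift between
  libraries (KO/control total ≈ 1.08 at defaults).
* **Mark redistribution.** All promoters are H3K27Ac-enriched (log-normal
  rates around 0.8 reads/bp); `n_gain_pro` genes double their promoter
  rate in knockout. `n_gain_se` genes carry a 3-constituent enhancer
  cluster with log-spread strength (5–30× typical enhancers — the convex
  top the rank-curve knee expects) that doubles in knockout. HDAC1 covers
  every gene at 1.5 reads/bp and halves in knockout for the
  `n_hdac1_loss` genes, of which round(frac · n_gain_pro) are drawn from
  the promoter-gain set so that |gain ∩ loss| / |gain| equals the target
  fraction (default 0.494) up to integer rounding; the achieved fraction
  is recorded in the ground truth.
* **Counts.** Negative binomial via Gamma–Poisson, means log-normal
  (median 800, log-sd 0.8), dispersion 0.01 — typical for cell-line
  replicates and chosen, before the recovery tests were frozen, so that
  the planted log2FC = 1 at 3 vs 3 is detected with ~95% power by the
  pooled t at FC ≥ 1.3. Of `n_up_genes` (60) upregulated genes, 75% are
  drawn from the mark-gain sets, linking acetylation gain to
  upregulation.

What the generator does **not** emulate: read-level artefacts (FASTQ,
alignment, duplicates), fragment-size effects, peak-caller behaviour
(peak sets are inputs by construction), copy-number or mappability
structure, correlated replicates, and inter-gene count correlation.
Passing tests therefore demonstrate the correctness and calibration of
the analysis logic under the stated statistical model, not robustness to
upstream artefacts of real sequencing data.

## Problem sizes and numerical choices

The default fixture is 2 × 10 Mb with 50 domains; the co-occupancy
recovery check uses 2 × 160 Mb with 5000 domains (the config enforces
that planted domains cover < 1/10 of the genome); the null calibration
uses 10,000 genes at 3 vs 3 — sizes at which every check runs in seconds
on one core while estimator noise stays well inside the asserted
tolerances (the SE of r at n = 5000 is ≈ 0.003). Ties and degenerate
inputs are handled explicitly: zero-variance correlations are flagged,
all-identical count rows get p = 1, flat rank curves yield no SEs,
empty gain sets yield an overlap fraction of 0. Report JSON/TSV are
byte-deterministic (sorted keys, no timestamps) so identical seed and
config reproduce identical outputs.

## Known limitations

* The lost-domain rule ignores peak strength; a fold-change variant of
  window qualification is not implemented.
* Super-enhancer calling has no published constant set for this assay;
  the stitch gap, knee rule and assignment radius are config keys with
  community-standard defaults.
* The DE test is a per-gene t on log-TPM, not a count-model GLM with
  dispersion shrinkage; at very low counts or 2 replicates its power is
  limited, and no size-factor normalisation beyond TPM is applied.
* Overlap p-values treat genes as exchangeable; no covariate matching
  (gene length, expression level) is attempted.
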