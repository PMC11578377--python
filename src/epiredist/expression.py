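"""TPM normalization and threshold-based differential expression calling.

The differential call follows the common fold-change-plus-p-value scheme:
per-gene fold change of mean TPM between conditions (with a pseudocount) and
a two-sample t-test on log2(TPM + 1). The pooled-variance (Student) form is
used: at the 2-3 replicates typical of these designs the unequal-variance
(Welch) form is badly conservative (empirical size ~0.035 at nominal 0.05
for n=3 even on normal data) while the pooled form is calibrated, and with
a common dispersion per condition its assumption holds. A gene is "up" iff
FC >= fc_cutoff and p < alpha; "down" symmetrically at 1/fc_cutoff. P-values
are raw by default; Benjamini-Hochberg adjustment is available behind a flag.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import ValidationError

__all__ = ["ExpressionMatrix", "DEResult", "tpm", "de_test", "up_gene_set"]


@dataclass
class ExpressionMatrix:
    """Gene x sample integer counts with gene lengths and a condition map."""

    counts: pd.DataFrame  # index gene_id, columns sample names
    gene_lengths: pd.Series  # index gene_id, basepairs
    conditions: Mapping[str, str]  # sample -> "control" | "KO"

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValidationError("negative counts")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            raise ValidationError("missing gene length for some genes")
        if (self.gene_lengths <= 0).any():
            raise ValidationError("gene lengths must be > 0")
        for s in self.counts.columns:
            if s not in self.conditions:
                raise ValidationError(f"sample {s!r} has no condition")
        groups = {self.conditions[s] for s in self.counts.columns}
        if groups != {"control", "KO"}:
            raise ValidationError("need both control and KO samples")

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    @classmethod
    def read_tsv(cls, path, conditions: Mapping[str, str]) -> "ExpressionMatrix":
        """Read a counts TSV with columns gene_id, length, then samples."""
        df = pd.read_csv(path, sep="\t")
        if df.columns[0] != "gene_id" or df.columns[1] != "length":
            raise ValidationError("counts TSV must start with gene_id and length columns")
        df = df.set_index("gene_id")
        return cls(df.drop(columns=["length"]), df["length"], dict(conditions))

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.gene_lengths)
        out.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class DEResult:
    """Per-gene differential-expression calls at fixed thresholds."""

    table: pd.DataFrame  # gene_id index: mean_tpm_control, mean_tpm_ko, fc, log2fc, p, flag
    fc_cutoff: float
    alpha: float


def tpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Transcripts per million: 1e6 * (c/L) / sum_g(c/L), per sample."""
    rates = matrix.counts.div(matrix.gene_lengths, axis=0)
    col_sums = rates.sum(axis=0)
    if (col_sums == 0).any():
        bad = list(col_sums.index[col_sums == 0])
        raise ValidationError(f"all-zero sample(s): {bad}")
    return rates.div(col_sums, axis=1) * 1e6


def de_test(
    matrix: ExpressionMatrix,
    fc_cutoff: float = 1.3,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    adjust: bool = False,
) -> DEResult:
    """Pooled-variance t on log2(TPM + 1) with mean-TPM fold-change thresholds.

    Genes with zero variance in both groups (identical values) get p = 1 and
    flag "ns". With ``adjust`` the p column is Benjamini-Hochberg adjusted
    before thresholding.
    """
    ctrl = matrix.samples("control")
    ko = matrix.samples("KO")
    if len(ctrl) < 2 or len(ko) < 2:
        raise ValidationError("need >= 2 replicates per condition")
    t = tpm(matrix)
    log_t = np.log2(t + 1.0)
    a = log_t[ko].to_numpy()
    b = log_t[ctrl].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    p[degenerate | np.isnan(p)] = 1.0
    if adjust:
        p = stats.false_discovery_control(p, method="bh")

    mean_ctrl = t[ctrl].mean(axis=1).to_numpy()
    mean_ko = t[ko].mean(axis=1).to_numpy()
    fc = (mean_ko + pseudocount) / (mean_ctrl + pseudocount)
    flag = np.where(
        (fc >= fc_cutoff) & (p < alpha),
        "up",
        np.where((fc <= 1.0 / fc_cutoff) & (p < alpha), "down", "ns"),
    )
    table = pd.DataFrame(
        {
            "mean_tpm_control": mean_ctrl,
            "mean_tpm_ko": mean_ko,
            "fc": fc,
            "log2fc": np.log2(fc),
            "p": p,
            "flag": flag,
        },
        index=matrix.counts.index,
    )
    return DEResult(table, fc_cutoff, alpha)


def up_gene_set(result: DEResult) -> set[str]:
    """Genes flagged up (FC >= cutoff inclusive, p < alpha strict)."""
    return set(result.table.index[result.table["flag"] == "up"])


def down_gene_set(result: DEResult) -> set[str]:
    return set(result.table.index[result.table["flag"] == "down"])
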