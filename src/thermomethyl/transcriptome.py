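"""RNA-seq expression: FPKM and differential expression.

FPKM (fragments per kilobase per million mapped reads) is the reporting
unit for expression level; differential testing always runs on raw counts
through the shared NB engine, never on FPKM. The default screening rule is
BH-FDR q < 0.05 and |log2FC| > 1; the raw-p preset (p < 0.05, same fold
threshold) is available via ``use_fdr=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core_stats


@dataclass
class ExpressionMatrix:
    """Gene x sample raw counts with per-gene lengths (bp).

    Library sizes default to the column totals of `counts`; pass
    `library_sizes` to use externally determined totals instead.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    group_of: dict[str, str]
    library_sizes: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            raise ValueError("every gene needs a length")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")


def compute_fpkm(m: ExpressionMatrix) -> pd.DataFrame:
    """FPKM[g, s] = count[g, s] / (length_kb[g] * library_size_millions[s])."""
    length_kb = m.gene_lengths / 1e3
    lib_m = m.library_sizes / 1e6
    return m.counts.div(lib_m, axis=1).div(length_kb, axis=0)


def expression_differential_analysis(
    m: ExpressionMatrix,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    use_fdr: bool = True,
) -> pd.DataFrame:
    """Call DEGs on raw counts with the shared NB engine and BH-FDR.

    Genes with zero counts in every sample are dropped before testing
    (they cannot move and would only inflate the BH denominator).
    """
    expressed = m.counts.loc[m.counts.sum(axis=1) > 0]
    if expressed.empty:
        raise ValueError("no expressed genes")
    cm = core_stats.CountMatrix(counts=expressed, group_of=m.group_of)
    return core_stats.run_differential(
        cm, alpha=alpha, lfc_threshold=lfc_threshold, use_fdr=use_fdr
    )


def read_expression_matrix(path: str, design: dict[str, str]) -> ExpressionMatrix:
    """Load a count TSV with columns gene_id, length, <one per sample>."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "length"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    df = df.set_index("gene_id")
    lengths = df.pop("length")
    return ExpressionMatrix(
        counts=df, gene_lengths=lengths, group_of=design
    )
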