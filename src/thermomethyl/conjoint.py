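"""Conjoint promoter-methylation x expression quadrant analysis.

Genes called both as promoter DMGs (per methylation context) and as DEGs
are placed in a four-quadrant map by the sign pair (methylation change,
expression change): hyper_up / hyper_down / hypo_up / hypo_down. The
association is positive when both changes share a sign, negative
otherwise. Across-sample Pearson correlation between promoter methylation
level and FPKM supplements the sign-based classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import core_stats

log = logging.getLogger(__name__)


@dataclass
class ConjointRecord:
    gene_id: str
    context: str
    meth_log2fc: float
    expr_log2fc: float
    quadrant: str          # hyper_up | hyper_down | hypo_up | hypo_down
    association: str       # positive | negative
    pearson_r: float = float("nan")
    pearson_p: float = float("nan")
    r_defined: bool = False


def classify_quadrant(meth_lfc: float, expr_lfc: float) -> tuple[str, str]:
    """Quadrant and association labels from the two fold-change signs."""
    assert meth_lfc != 0 and expr_lfc != 0, "zero log2fc cannot pass thresholds"
    meth = "hyper" if meth_lfc > 0 else "hypo"
    expr = "up" if expr_lfc > 0 else "down"
    assoc = "positive" if (meth_lfc > 0) == (expr_lfc > 0) else "negative"
    return f"{meth}_{expr}", assoc


def quadrant_join(
    promoter_dmgs: dict[str, pd.DataFrame],
    degs: pd.DataFrame,
) -> list[ConjointRecord]:
    """Inner-join significant promoter DMGs with significant DEGs.

    `promoter_dmgs` maps context -> differential table (run_differential
    output on promoter-scope gene methylation); `degs` is the expression
    differential table. A gene significant in both contexts yields one
    record per context; cross-context overlaps are logged.
    """
    sig_degs = degs[degs["significant"]]
    records = []
    seen: dict[str, list[str]] = {}
    for context in sorted(promoter_dmgs):
        dm = promoter_dmgs[context]
        sig_dm = dm[dm["significant"]]
        shared = sig_dm.index.intersection(sig_degs.index).sort_values()
        for gid in shared:
            meth_lfc = float(sig_dm.loc[gid, "log2fc"])
            expr_lfc = float(sig_degs.loc[gid, "log2fc"])
            quadrant, assoc = classify_quadrant(meth_lfc, expr_lfc)
            records.append(
                ConjointRecord(str(gid), context, meth_lfc, expr_lfc,
                               quadrant, assoc)
            )
            seen.setdefault(str(gid), []).append(context)
    overlaps = sorted(g for g, ctxs in seen.items() if len(ctxs) > 1)
    if overlaps:
        log.info("genes conjoint in both contexts: %s", ", ".join(overlaps))
    if not records:
        log.warning("conjoint join is empty: no gene is both DMG and DEG")
    return records


def methylation_expression_correlation(
    records: list[ConjointRecord],
    gene_methylation: dict[str, pd.DataFrame],
    fpkm: pd.DataFrame,
) -> list[ConjointRecord]:
    """Attach per-gene Pearson r between promoter methylation and FPKM.

    Correlates across the shared samples (>= 3 required). A gene whose
    methylation or expression is constant across samples is flagged
    ``r_defined=False`` rather than dropped.
    """
    for rec in records:
        gm = gene_methylation[rec.context]
        if rec.gene_id not in gm.index or rec.gene_id not in fpkm.index:
            continue
        samples = [s for s in gm.columns if s in fpkm.columns]
        if len(samples) < 3:
            raise ValueError("need >= 3 shared samples for correlation")
        x = gm.loc[rec.gene_id, samples].to_numpy(dtype=float)
        y = fpkm.loc[rec.gene_id, samples].to_numpy(dtype=float)
        try:
            rec.pearson_r, rec.pearson_p = core_stats.pearson_correlation(x, y)
            rec.r_defined = True
        except core_stats.DegenerateDataError:
            rec.r_defined = False
    return records


def conjoint_frame(records: list[ConjointRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "context": r.context,
                "meth_log2fc": r.meth_log2fc,
                "expr_log2fc": r.expr_log2fc,
                "quadrant": r.quadrant,
                "association": r.association,
                "pearson_r": r.pearson_r,
                "pearson_p": r.pearson_p,
                "r_defined": r.r_defined,
            }
            for r in records
        ],
        columns=[
            "gene_id", "context", "meth_log2fc", "expr_log2fc", "quadrant",
            "association", "pearson_r", "pearson_p", "r_defined",
        ],
    )
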