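"""Site-level and gene-level differential methylation.

MethylRAD read depth at an enzyme recognition site is the proxy for that
site's methylation level. Sites are analysed per context (CG and CWG
separately): depths are normalized by median-of-ratios size factors and
each site is tested with the shared NB exact engine; a differentially
methylated site (DMS) has raw p < 0.05 and |log2FC| > 1. A gene's
methylation level is the sum of its sites' normalized depths; summed
(integer-rounded) gene counts are re-normalized and re-tested to call
differentially methylated genes (DMGs) under the same rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import core_stats
from .annotation import SiteAssignment

CONTEXTS = ("CG", "CWG")

SITE_COLUMNS = ("site_id", "chrom", "position", "context")


@dataclass
class SiteCountMatrix:
    """Methylation sites x samples depth matrix with context labels.

    `sites` holds site_id, chrom, position (0-based), context in
    {CG, CWG}; `depths` is indexed by site_id with one integer column per
    sample.
    """

    sites: pd.DataFrame
    depths: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        bad = set(self.sites["context"]) - set(CONTEXTS)
        if bad:
            raise ValueError(f"unknown contexts: {sorted(bad)}")
        if not self.sites["site_id"].is_unique:
            raise ValueError("duplicate site ids")
        if list(self.depths.index) != list(self.sites["site_id"]):
            self.depths = self.depths.loc[self.sites["site_id"]]
        groups = {self.group_of.get(s) for s in self.depths.columns}
        for g in ("control", "treatment"):
            if g not in groups:
                raise ValueError(f"group '{g}' has no samples")

    def context_counts(self, context: str) -> pd.DataFrame:
        ids = self.sites.loc[self.sites["context"] == context, "site_id"]
        return self.depths.loc[ids]


def site_differential_analysis(
    m: SiteCountMatrix,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    use_fdr: bool = False,
) -> dict[str, pd.DataFrame]:
    """Call DMSs per context with the shared NB engine.

    Size factors and the common dispersion are estimated per context-wide
    matrix, so CG and CWG analyses are fully independent. Significance is
    raw p < `alpha` and |log2FC| > `lfc_threshold` by default (`use_fdr`
    switches the p criterion to the BH q-value).
    """
    results = {}
    for context in CONTEXTS:
        counts = m.context_counts(context)
        if counts.empty:
            results[context] = pd.DataFrame(
                columns=["log2fc", "p_value", "q_value", "significant", "direction"]
            )
            continue
        cm = core_stats.CountMatrix(counts=counts, group_of=m.group_of)
        results[context] = core_stats.run_differential(
            cm, alpha=alpha, lfc_threshold=lfc_threshold, use_fdr=use_fdr
        )
    return results


def aggregate_gene_methylation(
    m: SiteCountMatrix,
    assignments: list[SiteAssignment],
    scope: str = "whole_gene",
    context: str | None = None,
    normalized: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene methylation level: sum of normalized site depths.

    ``scope="whole_gene"`` sums sites falling in the gene body (exons and
    introns); ``scope="promoter"`` sums promoter sites only. A site inside
    two genes' regions contributes to both gene sums. Genes with no
    in-scope sites are omitted. If `normalized` is not given, depths are
    normalized per context with fresh size factors.
    """
    if scope not in ("whole_gene", "promoter"):
        raise ValueError(f"unknown scope: {scope}")
    assigned_ids = {a.site_id for a in assignments}
    site_ids = set(m.sites["site_id"].astype(str))
    if not assigned_ids <= site_ids:
        raise ValueError("assignments refer to site ids absent from the matrix")
    wanted = (
        {"promoter"} if scope == "promoter" else {"exon", "intron"}
    )
    context_of = dict(zip(m.sites["site_id"].astype(str), m.sites["context"]))
    if normalized is None:
        parts = []
        for ctx in CONTEXTS:
            counts = m.context_counts(ctx)
            if counts.empty:
                continue
            parts.append(core_stats.estimate_size_factors(counts).normalized)
        normalized = pd.concat(parts)

    sums: dict[str, np.ndarray] = {}
    n_samples = normalized.shape[1]
    for a in assignments:
        if context is not None and context_of.get(a.site_id) != context:
            continue
        row = None
        for gid, el in a.element_of_gene.items():
            if el in wanted:
                if row is None:
                    row = normalized.loc[a.site_id].to_numpy(dtype=float)
                sums.setdefault(gid, np.zeros(n_samples))
                sums[gid] += row
    if not sums:
        return pd.DataFrame(columns=normalized.columns)
    out = pd.DataFrame.from_dict(sums, orient="index", columns=normalized.columns)
    out.index.name = "gene_id"
    return out.sort_index()


def gene_differential_analysis(
    gene_methylation: pd.DataFrame,
    group_of: dict[str, str],
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    use_fdr: bool = False,
) -> pd.DataFrame:
    """Call DMGs from summed gene methylation levels.

    Sums are rounded to the nearest integer and pushed through the shared
    NB engine with fresh size factors; the DMG rule mirrors the site rule
    (raw p and |log2FC| thresholds).
    """
    if len(gene_methylation) < 2:
        raise ValueError("need >= 2 genes for gene-level analysis")
    counts = gene_methylation.round().astype(int)
    cm = core_stats.CountMatrix(counts=counts, group_of=group_of)
    return core_stats.run_differential(
        cm, alpha=alpha, lfc_threshold=lfc_threshold, use_fdr=use_fdr
    )


def read_site_matrix(path: str, design: dict[str, str]) -> SiteCountMatrix:
    """Load a site depth TSV (site_id, chrom, position, context, <samples>)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sites = df[list(SITE_COLUMNS)].copy()
    sites["site_id"] = sites["site_id"].astype(str)
    sample_cols = [c for c in df.columns if c not in SITE_COLUMNS]
    depths = df[sample_cols].copy()
    depths.index = sites["site_id"]
    return SiteCountMatrix(sites=sites, depths=depths, group_of=design)
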