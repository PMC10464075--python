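"""Hypergeometric term enrichment of gene lists.

Each term is tested with the upper-tail hypergeometric probability of
drawing at least the observed number of term genes when sampling the
selected list from the universe; BH q-values are computed across tested
terms and results are ranked by descending -log10(p) with term-id
tie-break. Terms whose overlap with the selection falls below the
minimum-gene rule are filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_stats import bh_adjust, hypergeometric_tail


@dataclass
class TermAnnotation:
    term_id: str
    term_name: str
    category: str  # BP | CC | MF | pathway
    gene_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"{self.term_id}: empty gene set")


def read_term_annotation(path: str) -> list[TermAnnotation]:
    """Load a term TSV (term_id, term_name, category, gene_id; one row per pair)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    terms = []
    for (tid, name, cat), sub in df.groupby(
        ["term_id", "term_name", "category"], sort=True
    ):
        terms.append(TermAnnotation(tid, name, cat, set(sub["gene_id"])))
    return terms


def enrich_terms(
    selected: set[str] | list[str],
    universe: set[str] | list[str],
    annotation: list[TermAnnotation],
    min_genes: int = 2,
    strict: bool = True,
) -> pd.DataFrame:
    """Ranked hypergeometric enrichment of `selected` within `universe`.

    With ``strict=True`` (the default) a term must have MORE than
    `min_genes` selected genes to be reported (k > min_genes); ``strict=
    False`` relaxes this to k >= min_genes. BH adjustment runs over all
    terms with any overlap in the universe, before the k filter, so
    filtering and testing commute.
    """
    selected = set(selected)
    universe = set(universe)
    offenders = sorted(selected - universe)
    if offenders:
        raise ValueError(f"selected genes outside universe: {offenders}")
    N, n = len(universe), len(selected)
    rows = []
    for term in annotation:
        term_in_universe = term.gene_ids & universe
        K = len(term_in_universe)
        if K == 0:
            continue
        k = len(term_in_universe & selected)
        p = hypergeometric_tail(N, K, n, k)
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "category": term.category,
                "k": k, "n": n, "K": K, "N": N,
                "p_value": p,
                "fold_enrichment": (k / n) / (K / N) if n else 0.0,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_name", "category", "k", "n", "K", "N",
                     "p_value", "q_value", "fold_enrichment", "neg_log10_p"]
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    keep = out["k"] > min_genes if strict else out["k"] >= min_genes
    out = out[keep].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p_value"])
    out = out.sort_values(
        ["neg_log10_p", "term_id"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)
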