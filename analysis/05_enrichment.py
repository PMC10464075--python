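#!/usr/bin/env python
"""Term enrichment of the DEG list against the toy annotation map.

Ranks terms by -log10(p) from the upper-tail hypergeometric test of the
pipeline's DEG list within the expressed-gene universe, keeping terms
with more than two selected genes.

Writes results/enrichment/deg_terms.tsv.
"""

from pathlib import Path

import pandas as pd

from thermomethyl import enrichment as en

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "enrichment"
OUT.mkdir(parents=True, exist_ok=True)

deg = pd.read_csv(ROOT / "pipeline" / "deg.tsv", sep="\t", index_col=0)
universe = set(deg.index.astype(str))
selected = set(deg[deg["significant"]].index.astype(str))
terms = en.read_term_annotation(str(ROOT / "synthetic" / "terms.tsv"))

ranked = en.enrich_terms(selected, universe, terms, min_genes=2)
ranked.to_csv(OUT / "deg_terms.tsv", sep="\t", index=False)
print(
    f"{len(selected)} DEGs against {len(universe)} expressed genes, "
    f"{len(terms)} terms; {len(ranked)} terms pass the >2-gene rule"
)
print(ranked.head(10).to_string(index=False))
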