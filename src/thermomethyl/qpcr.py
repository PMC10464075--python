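"""qPCR primer efficiency and relative quantification (2^-ddCt).

Primer efficiency comes from the standard-curve slope of Ct against
log10(template): E = (10^(-1/slope) - 1) * 100, with the conventional
90-105% acceptance window. Relative expression uses the 2^-ddCt method:
per condition, replicate Ct values of target and reference gene are
averaged, dCt = Ct_target - Ct_reference, ddCt = dCt_treatment -
dCt_control, and the fold change is 2^-ddCt (treatment vs control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EFFICIENCY_WINDOW = (90.0, 105.0)

CONDITIONS = ("control", "treatment")


def primer_efficiency(slope: float) -> tuple[float, bool]:
    """Amplification efficiency in percent from a standard-curve slope.

    A perfect doubling per cycle corresponds to slope -3.3219 and
    E = 100%. Returns (E, within the 90-105% acceptance window).
    """
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    e = (10 ** (-1.0 / slope) - 1.0) * 100.0
    lo, hi = EFFICIENCY_WINDOW
    return e, lo <= e <= hi


@dataclass
class CtTable:
    """Replicate Ct values per (gene, condition), with a reference gene.

    `ct` columns: gene_id, condition in {control, treatment}, ct (one row
    per replicate). The reference gene must be measured in both
    conditions; every (gene, condition) cell needs >= 2 replicates.
    """

    ct: pd.DataFrame
    reference_gene_id: str

    def __post_init__(self) -> None:
        if (self.ct["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        bad = set(self.ct["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        for cond in CONDITIONS:
            ref = self.ct[
                (self.ct["gene_id"] == self.reference_gene_id)
                & (self.ct["condition"] == cond)
            ]
            if ref.empty:
                raise ValueError(
                    f"reference gene missing in condition '{cond}'"
                )
        counts = self.ct.groupby(["gene_id", "condition"])["ct"].size()
        if (counts < 2).any():
            raise ValueError("every gene x condition needs >= 2 replicate Ct values")


def ddct_fold_change(table: CtTable) -> pd.DataFrame:
    """2^-ddCt fold change (treatment vs control) per target gene.

    Replicates are averaged before the delta steps; the replicate SDs of
    the two dCt values are propagated in quadrature and reported as a
    log2-scale fold-change SD.
    """
    ref = table.reference_gene_id
    means = table.ct.groupby(["gene_id", "condition"])["ct"].mean()
    sds = table.ct.groupby(["gene_id", "condition"])["ct"].std(ddof=1)
    rows = []
    for gene in sorted(set(table.ct["gene_id"]) - {ref}):
        try:
            dct = {
                cond: means[(gene, cond)] - means[(ref, cond)]
                for cond in CONDITIONS
            }
        except KeyError as exc:
            raise ValueError(f"{gene}: missing condition {exc}") from exc
        ddct = dct["treatment"] - dct["control"]
        sd_log2 = float(
            np.sqrt(
                sum(
                    sds[(g, c)] ** 2
                    for g in (gene, ref)
                    for c in CONDITIONS
                )
            )
        )
        rows.append(
            {
                "gene_id": gene,
                "dct_control": dct["control"],
                "dct_treatment": dct["treatment"],
                "ddct": ddct,
                "fold_change": 2.0 ** (-ddct),
                "log2_fc_sd": sd_log2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "dct_control", "dct_treatment", "ddct",
                 "fold_change", "log2_fc_sd"],
    )
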