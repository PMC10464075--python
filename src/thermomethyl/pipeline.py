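"""End-to-end orchestration: growth -> annotation -> methylome ->
transcriptome -> conjoint -> enrichment.

A :class:`PipelineConfig` (constructible from a YAML file) names the
inputs, thresholds and output directory; :func:`run_pipeline` executes the
stages in order, writes per-stage TSVs plus a summary JSON, and logs the
growth-model discrepancy between computed stationary optima and the
originally printed ones. Every stage is a pure function of (inputs,
config), so reruns reproduce outputs exactly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation, conjoint, enrichment, growth, methylome, transcriptome

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    growth_tsv: str
    gff3: str
    chrom_sizes_tsv: str
    sites_tsv: str
    expression_tsv: str
    design_tsv: str
    terms_tsv: str
    outdir: str
    site_p: float = 0.05
    gene_p: float = 0.05
    deg_fdr: float = 0.05
    lfc_threshold: float = 1.0
    enrichment_min_genes: int = 2
    conjoint_scope: str = "promoter"
    flank: int = 2000

    def __post_init__(self) -> None:
        for name in ("site_p", "gene_p", "deg_fdr", "lfc_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def check_inputs(self) -> None:
        for name in ("growth_tsv", "gff3", "chrom_sizes_tsv", "sites_tsv",
                     "expression_tsv", "design_tsv", "terms_tsv"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file: {p}")


def _read_design(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"].astype(str), df["group"]))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the summary dict (also written as JSON).

    A stage failure raises :class:`PipelineError` naming the stage; stage
    outputs written before the failure are renamed with a ``.partial``
    suffix.
    """
    cfg.check_inputs()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {}

    def emit(df: pd.DataFrame, name: str, **kw) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", **kw)
        written.append(path)

    stage = "growth"
    try:
        records = pd.read_csv(cfg.growth_tsv, sep="\t")
        records["wgr"] = [
            growth.compute_wgr(w0, wt)
            for w0, wt in zip(records["w0_g"], records["wt_g"])
        ]
        fit = growth.fit_quadratic_surface(
            records.rename(columns={"diameter_cm": "diameter",
                                    "temperature_c": "temperature"})
        )
        optima = []
        for D in sorted(records["diameter_cm"].unique()):
            opt = growth.optimal_temperature(fit, D)
            optima.append({
                "diameter": D,
                "t_opt": round(opt.t_opt, 1),
                "wgr_max": round(opt.wgr_max, 2),
                "t_limit": round(growth.limit_temperature(fit, D), 1),
            })
        emit(pd.DataFrame(optima), "growth_optima.tsv", index=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            disc = growth.printed_optimum_discrepancy()
        emit(disc, "growth_printed_discrepancy.tsv", index=False)
        log.info(
            "growth model: stationary optima vs printed values\n%s",
            disc.to_string(index=False),
        )
        (outdir / "growth_model.json").write_text(json.dumps({
            "beta": list(fit.beta), "r_squared": fit.r_squared,
            "f_statistic": fit.f_statistic, "model_p": fit.model_p,
            "n_obs": fit.n_obs,
        }, indent=1))
        summary["growth"] = {
            "r_squared": round(fit.r_squared, 4),
            "optima": optima,
            "printed_optimum_discrepant": bool(disc["discrepant"].any()),
        }

        stage = "annotation"
        genes = annotation.parse_gene_models(cfg.gff3, "GFF3")
        sizes_df = pd.read_csv(cfg.chrom_sizes_tsv, sep="\t")
        chrom_sizes = dict(zip(sizes_df["chrom"], sizes_df["size"]))
        regions = annotation.derive_regions(genes, chrom_sizes, flank=cfg.flank)

        stage = "methylome"
        design = _read_design(cfg.design_tsv)
        sites = methylome.read_site_matrix(cfg.sites_tsv, design)
        assignments = annotation.assign_sites(sites.sites, regions)
        emit(annotation.assignments_frame(assignments), "site_assignments.tsv",
             index=False)
        element_counts = (
            annotation.assignments_frame(assignments)["element"]
            .value_counts().to_dict()
        )
        dms = methylome.site_differential_analysis(
            sites, alpha=cfg.site_p, lfc_threshold=cfg.lfc_threshold
        )
        summary["dms"] = {}
        promoter_dmgs: dict[str, pd.DataFrame] = {}
        gene_meth: dict[str, pd.DataFrame] = {}
        summary["dmg"] = {}
        for ctx, table in dms.items():
            emit(table, f"dms_{ctx}.tsv")
            sig = table[table["significant"]]
            summary["dms"][ctx] = {
                "total": int(len(sig)),
                "up": int((sig["direction"] == "up").sum()),
                "down": int((sig["direction"] == "down").sum()),
            }
            gm = methylome.aggregate_gene_methylation(
                sites, assignments, scope=cfg.conjoint_scope, context=ctx
            )
            gene_meth[ctx] = gm
            if len(gm) >= 2:
                dmg = methylome.gene_differential_analysis(
                    gm, design, alpha=cfg.gene_p,
                    lfc_threshold=cfg.lfc_threshold,
                )
            else:
                dmg = pd.DataFrame(
                    columns=["log2fc", "p_value", "q_value", "significant",
                             "direction"]
                )
            promoter_dmgs[ctx] = dmg
            emit(dmg, f"dmg_{ctx}.tsv")
            sig = dmg[dmg["significant"]] if len(dmg) else dmg
            summary["dmg"][ctx] = {
                "total": int(len(sig)),
                "up": int((sig["direction"] == "up").sum()) if len(sig) else 0,
                "down": int((sig["direction"] == "down").sum()) if len(sig) else 0,
            }
        summary["site_elements"] = element_counts

        stage = "transcriptome"
        em = transcriptome.read_expression_matrix(cfg.expression_tsv, design)
        fpkm = transcriptome.compute_fpkm(em)
        emit(fpkm, "fpkm.tsv")
        degs = transcriptome.expression_differential_analysis(
            em, alpha=cfg.deg_fdr, lfc_threshold=cfg.lfc_threshold
        )
        emit(degs, "deg.tsv")
        sig = degs[degs["significant"]]
        summary["deg"] = {
            "total": int(len(sig)),
            "up": int((sig["direction"] == "up").sum()),
            "down": int((sig["direction"] == "down").sum()),
        }

        stage = "conjoint"
        records_cj = conjoint.quadrant_join(promoter_dmgs, degs)
        records_cj = conjoint.methylation_expression_correlation(
            records_cj, gene_meth, fpkm
        )
        cj = conjoint.conjoint_frame(records_cj)
        emit(cj, "conjoint.tsv", index=False)
        summary["conjoint"] = {
            "total": int(len(cj)),
            "quadrants": {
                q: int((cj["quadrant"] == q).sum())
                for q in ("hyper_up", "hyper_down", "hypo_up", "hypo_down")
            },
            "positive": int((cj["association"] == "positive").sum()),
            "negative": int((cj["association"] == "negative").sum()),
        }

        stage = "enrichment"
        terms = enrichment.read_term_annotation(cfg.terms_tsv)
        universe = set(em.counts.index.astype(str))
        selected = set(sig.index.astype(str))
        enr = enrichment.enrich_terms(
            selected, universe, terms, min_genes=cfg.enrichment_min_genes
        )
        emit(enr, "enrichment.tsv", index=False)
        summary["enrichment_top_terms"] = enr.head(10)[
            ["term_id", "term_name", "p_value", "q_value"]
        ].to_dict("records")
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        for path in written:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        raise PipelineError(stage, exc) from exc

    # internal consistency: up + down = total everywhere
    for block in (*summary["dms"].values(), *summary["dmg"].values(),
                  summary["deg"]):
        assert block["up"] + block["down"] == block["total"]
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
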