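"""Seeded generators for synthetic heat-stress study data.

The generators emulate the study design the analysis assumes: two groups
(control 15 deg C vs high temperature 24 deg C) of three pooled samples
each; MethylRAD site depths that are negative-binomially distributed
around a mean of ~10 reads with CG sites outnumbering CWG sites about
11:1; RNA-seq counts over the same gene models; planted log2 effects on
promoter methylation and expression, including genes whose expression
shift is positively or negatively coupled to their promoter-methylation
shift; and a growth experiment whose true response surface is the
published WGR equation. Every generator takes an explicit seed and writes
a ground-truth manifest alongside its data.

Scaled-down defaults (2,000 genes, 20,000 CG / 1,800 CWG sites) preserve
the design's structure -- depth, dispersion, replication, CG:CWG ratio --
at a size that runs in seconds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, derive_regions
from .growth import PUBLISHED_COEFFICIENTS, QuadraticSurfaceModel, evaluate_surface
from .methylome import SiteCountMatrix
from .transcriptome import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    seed: int
    # genome / annotation
    n_chroms: int = 10
    chrom_size: int = 4_000_000
    n_genes: int = 2000
    # methylome
    n_cg_sites: int = 20_000
    n_cwg_sites: int = 1800
    n_samples_per_group: int = 3
    depth_mean: float = 10.0
    nb_dispersion: float = 0.2
    dm_fraction: float = 0.1
    dm_log2fc: float = 2.0
    # transcriptome
    expr_mean: float = 100.0
    expr_log_sd: float = 0.8
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    n_coupled_pos: int = 8
    n_coupled_neg: int = 7
    # growth experiment
    diameters: tuple[float, ...] = (2.0, 4.0, 6.0)
    temperatures: tuple[float, ...] = (10.0, 14.0, 18.0, 22.0, 24.0, 26.0)
    growth_replicates: int = 3
    growth_noise_sd: float = 0.3
    true_beta: tuple[float, ...] = PUBLISHED_COEFFICIENTS

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_chroms", "chrom_size", "n_genes", "n_cg_sites",
                     "n_cwg_sites", "n_samples_per_group"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("dm_fraction", "de_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    def sample_names(self) -> tuple[list[str], dict[str, str]]:
        ctrl = [f"C{i+1}" for i in range(self.n_samples_per_group)]
        trt = [f"T{i+1}" for i in range(self.n_samples_per_group)]
        design = {s: "control" for s in ctrl} | {s: "treatment" for s in trt}
        return ctrl + trt, design


@dataclass
class TruthManifest:
    """Planted ground truth, serializable next to the simulated data."""

    site_log2fc: dict[str, float] = field(default_factory=dict)
    gene_promoter_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    gene_expression_log2fc: dict[str, float] = field(default_factory=dict)
    coupled_genes: dict[str, str] = field(default_factory=dict)  # gene -> pos/neg
    growth_beta: tuple[float, ...] = ()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        d = json.loads(Path(path).read_text())
        d["growth_beta"] = tuple(d.get("growth_beta", ()))
        return cls(**d)


# typical initial wet weights (g) by shell-diameter class
_W0_BY_DIAMETER = {2.0: 4.0, 4.0: 25.0, 6.0: 70.0}


def simulate_growth_dataset(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, TruthManifest]:
    """Per-tank growth records from the true quadratic surface plus noise.

    Each (diameter, temperature, replicate) cell gets
    WGR = surface(beta, D, T) + N(0, noise_sd), back-converted to an
    (initial, final) weight pair. Final weights that would come out
    negative are resampled (logged); with the default surface they do not
    occur.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    model = QuadraticSurfaceModel(beta=tuple(cfg.true_beta))
    rows = []
    for D in cfg.diameters:
        for T in cfg.temperatures:
            for rep in range(cfg.growth_replicates):
                wgr = evaluate_surface(model, D, T) + rng.normal(0, cfg.growth_noise_sd)
                w0 = _W0_BY_DIAMETER.get(D, 10.0) * rng.uniform(0.9, 1.1)
                wt = w0 * (1 + wgr / 100.0)
                while wt < 0:
                    log.warning("resampling negative final weight at D=%s T=%s", D, T)
                    wgr = evaluate_surface(model, D, T) + rng.normal(0, cfg.growth_noise_sd)
                    wt = w0 * (1 + wgr / 100.0)
                rows.append(
                    {
                        "id": f"tank_D{D:g}_T{T:g}_r{rep+1}",
                        "diameter_cm": D,
                        "temperature_c": T,
                        "w0_g": round(w0, 4),
                        "wt_g": round(wt, 4),
                    }
                )
    truth = TruthManifest(growth_beta=tuple(cfg.true_beta))
    return pd.DataFrame(rows), truth


def simulate_annotation(
    cfg: SimulationConfig,
) -> tuple[list[GeneModel], dict[str, int]]:
    """Non-overlapping gene models on synthetic chromosomes.

    Genes (1-8 exons, spans ~1-20 kb, both strands) are laid down
    sequentially with random inter-gene gaps, which guarantees
    non-overlap; raises if the genome cannot hold the requested genes.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    chrom_sizes = {
        f"chr{i+1}": cfg.chrom_size for i in range(cfg.n_chroms)
    }
    genes: list[GeneModel] = []
    if cfg.n_genes == 0:
        return genes, chrom_sizes
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    gid = 0
    for chrom in chrom_sizes:
        cursor = 0
        for _ in range(per_chrom):
            if gid >= cfg.n_genes:
                break
            span = int(rng.integers(1000, 20001))
            gap = int(rng.integers(2500, 8000))  # room for 2 kb flanks
            start = cursor + gap
            end = start + span
            if end + 2500 > cfg.chrom_size:
                break
            n_exons = int(rng.integers(1, 9))
            bounds = np.sort(
                rng.choice(np.arange(1, span), size=2 * n_exons - 2, replace=False)
            ) if n_exons > 1 else np.array([], dtype=int)
            edges = np.concatenate([[0], bounds, [span]])
            exons = [
                (start + int(edges[2 * i]), start + int(edges[2 * i + 1]))
                for i in range(n_exons)
            ]
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            genes.append(
                GeneModel(f"gene{gid:05d}", chrom, start, end, strand, exons)
            )
            cursor = end
    if len(genes) < cfg.n_genes:
        raise ValueError(
            f"could only place {len(genes)}/{cfg.n_genes} genes; "
            f"increase chrom_size (currently {cfg.chrom_size})"
        )
    return genes, chrom_sizes


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def _nb_draws(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_methylrad_counts(
    cfg: SimulationConfig,
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
) -> tuple[SiteCountMatrix, TruthManifest]:
    """MethylRAD site depth matrix with planted promoter effects.

    Sites are placed uniformly over the genome with the configured CG:CWG
    split; depths are NB(depth_mean x per-sample scale, dispersion). Per
    context, genes with promoter sites are sampled until ~dm_fraction of
    that context's promoter sites carry a 2^dm_log2fc multiplicative shift
    in the treatment group (shift sign random per gene). The manifest
    records each shifted site's log2 effect and each gene's promoter-level
    effect per context.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    samples, design = cfg.sample_names()
    n_sites = cfg.n_cg_sites + cfg.n_cwg_sites
    chroms = list(chrom_sizes)
    site_chrom = rng.choice(chroms, size=n_sites)
    site_pos = rng.integers(0, cfg.chrom_size, size=n_sites)
    context = np.array(
        ["CG"] * cfg.n_cg_sites + ["CWG"] * cfg.n_cwg_sites
    )
    order = rng.permutation(n_sites)
    context = context[order]
    sites = pd.DataFrame(
        {
            "site_id": [f"site{i+1:06d}" for i in range(n_sites)],
            "chrom": site_chrom,
            "position": site_pos,
            "context": context,
        }
    )

    # per-sample library-scale multipliers around 1
    scale = np.exp(rng.normal(0.0, 0.15, size=len(samples)))
    base = cfg.depth_mean * np.exp(rng.normal(0.0, 0.3, size=n_sites))

    # plant promoter shifts per context
    region_set = derive_regions(genes, chrom_sizes)
    promoter_sites: dict[str, dict[str, list[int]]] = {"CG": {}, "CWG": {}}
    trees = {}
    for gid, gr in region_set.regions.items():
        s, e = gr.promoter
        trees.setdefault(gr.gene.chrom, []).append((s, e, gid))
    for i, (chrom, pos, ctx) in enumerate(
        zip(sites["chrom"], sites["position"], sites["context"])
    ):
        for s, e, gid in trees.get(chrom, ()):
            if s <= pos < e:
                promoter_sites[ctx].setdefault(gid, []).append(i)

    truth = TruthManifest()
    effect = np.zeros(n_sites)
    for ctx in ("CG", "CWG"):
        gene_pool = sorted(promoter_sites[ctx])
        total_prom = sum(len(v) for v in promoter_sites[ctx].values())
        target = cfg.dm_fraction * total_prom
        rng.shuffle(gene_pool)
        planted_sites = 0
        truth.gene_promoter_log2fc.setdefault(ctx, {})
        for gid in gene_pool:
            if planted_sites >= target:
                break
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lfc = sign * cfg.dm_log2fc
            truth.gene_promoter_log2fc[ctx][gid] = lfc
            for i in promoter_sites[ctx][gid]:
                effect[i] = lfc
                truth.site_log2fc[sites["site_id"].iloc[i]] = lfc
                planted_sites += 1

    depths = np.empty((n_sites, len(samples)), dtype=int)
    for j, s in enumerate(samples):
        mean = base * scale[j] * (2.0 ** effect if design[s] == "treatment" else 1.0)
        depths[:, j] = _nb_draws(rng, mean, cfg.nb_dispersion)
    depth_df = pd.DataFrame(depths, columns=samples, index=sites["site_id"])
    matrix = SiteCountMatrix(sites=sites, depths=depth_df, group_of=design)
    return matrix, truth


def simulate_rnaseq_counts(
    cfg: SimulationConfig,
    genes: list[GeneModel],
    methyl_truth: TruthManifest,
) -> tuple[ExpressionMatrix, TruthManifest]:
    """RNA-seq counts with planted DE and methylation-coupled genes.

    Baseline gene means are log-normal around `expr_mean`. A de_fraction
    of uncoupled genes get a +/-de_log2fc treatment shift. Coupled genes
    are drawn from the genes with planted CG promoter-methylation effects:
    positively coupled genes shift expression with the same sign as their
    methylation effect, negatively coupled genes with the opposite sign.
    Coupling acts on the NB mean, keeping the count marginals valid.
    """
    rng = np.random.default_rng([cfg.seed, 4])
    samples, design = cfg.sample_names()
    gene_ids = [g.gene_id for g in genes]
    exonic = {
        g.gene_id: sum(e - s for s, e in g.exons) or (g.end - g.start)
        for g in genes
    }
    n = len(gene_ids)
    base = cfg.expr_mean * np.exp(rng.normal(0.0, cfg.expr_log_sd, size=n))

    cg_dm_genes = sorted(methyl_truth.gene_promoter_log2fc.get("CG", {}))
    n_coupled = cfg.n_coupled_pos + cfg.n_coupled_neg
    if n_coupled > len(cg_dm_genes):
        raise ValueError("more coupled genes requested than planted DM genes")
    coupled = list(rng.choice(cg_dm_genes, size=n_coupled, replace=False))
    truth = TruthManifest(
        gene_promoter_log2fc=methyl_truth.gene_promoter_log2fc,
        site_log2fc=methyl_truth.site_log2fc,
        growth_beta=methyl_truth.growth_beta,
    )
    lfc = np.zeros(n)
    index = {g: i for i, g in enumerate(gene_ids)}
    for rank, gid in enumerate(coupled):
        meth_sign = np.sign(methyl_truth.gene_promoter_log2fc["CG"][gid])
        mode = "positive" if rank < cfg.n_coupled_pos else "negative"
        sign = meth_sign if mode == "positive" else -meth_sign
        lfc[index[gid]] = sign * cfg.de_log2fc
        truth.coupled_genes[gid] = mode
        truth.gene_expression_log2fc[gid] = float(lfc[index[gid]])

    free = [g for g in gene_ids if g not in truth.coupled_genes]
    n_de = int(round(cfg.de_fraction * n))
    de_genes = list(rng.choice(free, size=min(n_de, len(free)), replace=False))
    for gid in de_genes:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        lfc[index[gid]] = sign * cfg.de_log2fc
        truth.gene_expression_log2fc[gid] = float(lfc[index[gid]])

    scale = np.exp(rng.normal(0.0, 0.15, size=len(samples)))
    counts = np.empty((n, len(samples)), dtype=int)
    for j, s in enumerate(samples):
        mean = base * scale[j] * (
            2.0 ** lfc if design[s] == "treatment" else 1.0
        )
        counts[:, j] = _nb_draws(rng, mean, cfg.nb_dispersion)
    cm = pd.DataFrame(counts, columns=samples, index=pd.Index(gene_ids, name="gene_id"))
    em = ExpressionMatrix(
        counts=cm,
        gene_lengths=pd.Series(exonic).reindex(gene_ids),
        group_of=design,
    )
    return em, truth


def simulate_ct_table(
    cfg: SimulationConfig,
    fold_changes: dict[str, float],
    reference: str = "ref18S",
    replicates: int = 3,
    noise_sd: float = 0.1,
) -> pd.DataFrame:
    """Triplicate Ct rows whose expected 2^-ddCt equals `fold_changes`."""
    rng = np.random.default_rng([cfg.seed, 5])
    rows = []
    for cond in ("control", "treatment"):
        for _ in range(replicates):
            rows.append({"gene_id": reference, "condition": cond,
                         "ct": 15.0 + rng.normal(0, noise_sd)})
    for gene, fc in sorted(fold_changes.items()):
        base_ct = 24.0 + rng.normal(0, 0.5)
        for cond in ("control", "treatment"):
            shift = -np.log2(fc) if cond == "treatment" else 0.0
            for _ in range(replicates):
                rows.append({
                    "gene_id": gene, "condition": cond,
                    "ct": base_ct + shift + rng.normal(0, noise_sd),
                })
    return pd.DataFrame(rows)


def simulate_all(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every generator and write the full input bundle to `outdir`.

    Writes growth.tsv, genes.gff3, chrom_sizes.tsv, sites.tsv,
    expression.tsv, design.tsv, terms.tsv, ct.tsv and truth.json; returns
    the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in {
        "growth": "growth.tsv", "gff3": "genes.gff3",
        "chrom_sizes": "chrom_sizes.tsv", "sites": "sites.tsv",
        "expression": "expression.tsv", "design": "design.tsv",
        "terms": "terms.tsv", "ct": "ct.tsv", "truth": "truth.json",
    }.items()}

    growth, truth = simulate_growth_dataset(cfg)
    growth.to_csv(paths["growth"], sep="\t", index=False)

    genes, chrom_sizes = simulate_annotation(cfg)
    write_gff3(genes, paths["gff3"])
    pd.Series(chrom_sizes, name="size").rename_axis("chrom").to_csv(
        paths["chrom_sizes"], sep="\t"
    )

    meth, truth = simulate_methylrad_counts(cfg, genes, chrom_sizes)
    site_tsv = pd.concat(
        [meth.sites.reset_index(drop=True),
         meth.depths.reset_index(drop=True)], axis=1
    )
    site_tsv.to_csv(paths["sites"], sep="\t", index=False)

    em, truth = simulate_rnaseq_counts(cfg, genes, truth)
    expr = em.counts.copy()
    expr.insert(0, "length", em.gene_lengths)
    expr.to_csv(paths["expression"], sep="\t")

    _, design = cfg.sample_names()
    pd.Series(design, name="group").rename_axis("sample").to_csv(
        paths["design"], sep="\t"
    )

    _simulate_terms(cfg, [g.gene_id for g in genes]).to_csv(
        paths["terms"], sep="\t", index=False
    )

    degs = {g: 2.0 ** l for g, l in sorted(truth.gene_expression_log2fc.items())[:10]}
    simulate_ct_table(cfg, degs).to_csv(paths["ct"], sep="\t", index=False)

    truth.growth_beta = tuple(cfg.true_beta)
    truth.to_json(paths["truth"])
    return paths


def _simulate_terms(cfg: SimulationConfig, gene_ids: list[str]) -> pd.DataFrame:
    """Toy GO/KEGG-style term map: 40 terms of 10-80 genes each."""
    rng = np.random.default_rng([cfg.seed, 6])
    rows = []
    categories = ["BP", "CC", "MF", "pathway"]
    for t in range(40):
        size = int(rng.integers(10, 81))
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        cat = categories[t % 4]
        for g in sorted(members):
            rows.append({
                "term_id": f"TERM{t+1:03d}",
                "term_name": f"synthetic term {t+1}",
                "category": cat,
                "gene_id": g,
            })
    return pd.DataFrame(rows)
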