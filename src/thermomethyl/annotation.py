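"""Gene models, functional-element regions, and metagene profiling.

Coordinates are 0-based half-open internally; GFF3 input (1-based closed)
is converted on parse. Each gene yields a promoter (2 kb upstream of the
TSS, strand-aware, clipped at chromosome edges), a gene body (the gene
span; exons and the remaining introns), and a downstream flank (2 kb past
the TTS). Methylation sites are assigned a single element label with
priority promoter > exon > intron > downstream > intergenic, while every
overlapping gene is recorded for gene-level aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

ELEMENT_PRIORITY = ("promoter", "exon", "intron", "downstream")
DEFAULT_FLANK = 2000
DEFAULT_BINS = (20, 60, 20)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start >= end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        self.exons = sorted(self.exons)
        prev_end = self.start
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon outside gene span")
            if s < prev_end and (s, e) != self.exons[0]:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def introns(self) -> list[tuple[int, int]]:
        if not self.exons:
            return [(self.start, self.end)]
        out = []
        cursor = self.start
        for s, e in self.exons:
            if s > cursor:
                out.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < self.end:
            out.append((cursor, self.end))
        return out


def parse_gene_models(path: str, fmt: str = "GFF3") -> list[GeneModel]:
    """Read gene models from GFF3 or BED12.

    GFF3 parsing goes through gffutils (in-memory db); gene features
    provide spans and child ``exon`` features the block structure. BED12
    reconstructs exons from blockStarts/blockSizes. Raises with the line
    number for malformed records; an empty file logs a warning and
    returns [].
    """
    fmt = fmt.upper()
    if fmt == "GFF3":
        return _parse_gff3(path)
    if fmt == "BED12":
        return _parse_bed12(path)
    raise ValueError(f"unknown format: {fmt}")


def _parse_gff3(path: str) -> list[GeneModel]:
    with open(path) as fh:
        has_records = any(
            line.strip() and not line.startswith("#") for line in fh
        )
    if not has_records:
        log.warning("no records in %s", path)
        return []
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = [
            (e.start - 1, e.end)
            for e in db.children(g, featuretype="exon", order_by="start")
        ]
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start - 1,  # GFF3 is 1-based closed
                end=g.end,
                strand=g.strand,
                exons=exons,
            )
        )
    return genes


def _parse_bed12(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED fields")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            exons = [(start + s, start + s + z) for s, z in zip(starts, sizes)]
            genes.append(
                GeneModel(name, chrom, start, end, strand, exons)
            )
    if not genes:
        log.warning("no records in %s", path)
    return genes


@dataclass
class GeneRegions:
    gene: GeneModel
    promoter: tuple[int, int]
    body: tuple[int, int]
    downstream: tuple[int, int]


@dataclass
class RegionSet:
    regions: dict[str, GeneRegions]
    chrom_sizes: dict[str, int]


def derive_regions(
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    flank: int = DEFAULT_FLANK,
) -> RegionSet:
    """Promoter / gene-body / downstream regions for each gene.

    Strand-aware: a minus-strand gene's promoter lies 3'-ward of its end
    coordinate. Flanks are clipped to [0, chrom_size); zero-length clipped
    flanks are kept as empty intervals.
    """
    regions = {}
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome: {g.chrom}")
        size = chrom_sizes[g.chrom]
        if g.strand == "+":
            promoter = (max(0, g.start - flank), g.start)
            downstream = (g.end, min(size, g.end + flank))
        else:
            promoter = (g.end, min(size, g.end + flank))
            downstream = (max(0, g.start - flank), g.start)
        regions[g.gene_id] = GeneRegions(
            gene=g, promoter=promoter, body=(g.start, g.end),
            downstream=downstream,
        )
    return RegionSet(regions=regions, chrom_sizes=dict(chrom_sizes))


@dataclass
class SiteAssignment:
    site_id: str
    element: str                      # promoter|exon|intron|downstream|intergenic
    gene_ids: list[str]               # all genes whose regions cover the site
    element_of_gene: dict[str, str]   # per-gene element for scope filtering


def _region_trees(region_set: RegionSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gid, gr in region_set.regions.items():
        tree = trees.setdefault(gr.gene.chrom, IntervalTree())
        if gr.promoter[0] < gr.promoter[1]:
            tree.addi(*gr.promoter, (gid, "promoter"))
        for s, e in (gr.gene.exons or []):
            tree.addi(s, e, (gid, "exon"))
        for s, e in gr.gene.introns():
            if s < e:
                tree.addi(s, e, (gid, "intron"))
        if gr.downstream[0] < gr.downstream[1]:
            tree.addi(*gr.downstream, (gid, "downstream"))
    return trees


def assign_sites(
    sites: pd.DataFrame, region_set: RegionSet
) -> list[SiteAssignment]:
    """Assign each site (columns site_id, chrom, position) to one element.

    The site's label is the highest-priority element over all genes whose
    regions cover it; all covering genes are recorded with their own
    element so gene-level aggregation can filter by scope.
    """
    trees = _region_trees(region_set)
    rank = {el: i for i, el in enumerate(ELEMENT_PRIORITY)}
    out = []
    for site_id, chrom, pos in zip(
        sites["site_id"], sites["chrom"], sites["position"]
    ):
        hits = trees[chrom][int(pos)] if chrom in trees else ()
        per_gene: dict[str, str] = {}
        for iv in hits:
            gid, el = iv.data
            if gid not in per_gene or rank[el] < rank[per_gene[gid]]:
                per_gene[gid] = el
        if per_gene:
            label = min(per_gene.values(), key=rank.__getitem__)
            gene_ids = sorted(per_gene)
        else:
            label, gene_ids = "intergenic", []
        out.append(SiteAssignment(str(site_id), label, gene_ids, per_gene))
    return out


def assignments_frame(assignments: list[SiteAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [a.site_id for a in assignments],
            "element": [a.element for a in assignments],
            "gene_ids": [",".join(a.gene_ids) for a in assignments],
        }
    )


@dataclass
class MetageneProfile:
    """Summed signal in 20 upstream / 60 scaled-body / 20 downstream bins."""

    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray
    n_genes_used: int
    n_genes_skipped: int

    @property
    def total_mass(self) -> float:
        return float(
            self.upstream.sum() + self.body.sum() + self.downstream.sum()
        )

    def concat(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])


def metagene_profile(
    sites: pd.DataFrame,
    genes: list[GeneModel],
    signal: np.ndarray | pd.Series | None = None,
    bins: tuple[int, int, int] = DEFAULT_BINS,
    flank: int = DEFAULT_FLANK,
) -> MetageneProfile:
    """Signal profile around genes: fixed-width flank bins, scaled body bins.

    Flank bins are ``flank / n_up`` bp wide; the gene body is divided into
    `n_body` proportional bins. Orientation is strand-aware (upstream is
    always the 5' side). Each site contributes its signal once per gene
    whose [-flank, TTS+flank] window covers it, so with non-overlapping
    windows the profile mass equals the total signal of covered sites.
    Genes shorter than `n_body` bp are skipped with a warning.
    """
    n_up, n_body, n_down = bins
    up = np.zeros(n_up)
    body = np.zeros(n_body)
    down = np.zeros(n_down)
    if signal is None:
        signal = np.ones(len(sites))
    signal = np.asarray(signal, dtype=float)
    bin_bp = flank / n_up

    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for (chrom, pos), w in zip(
        zip(sites["chrom"], sites["position"]), signal
    ):
        by_chrom.setdefault(chrom, []).append((int(pos), w))

    used = skipped = 0
    for g in genes:
        if g.end - g.start < n_body:
            log.warning("gene %s shorter than %d bp: skipped", g.gene_id, n_body)
            skipped += 1
            continue
        used += 1
        length = g.end - g.start
        for pos, w in by_chrom.get(g.chrom, ()):
            if g.strand == "+":
                rel = pos - g.start          # bp from TSS, signed
            else:
                rel = (g.end - 1) - pos
            if -flank <= rel < 0:
                up[int((rel + flank) // bin_bp)] += w
            elif 0 <= rel < length:
                body[int(rel * n_body // length)] += w
            elif length <= rel < length + flank:
                down[int((rel - length) // bin_bp)] += w
    return MetageneProfile(up, body, down, used, skipped)
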