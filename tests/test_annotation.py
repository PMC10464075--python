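"""Tests for gene models, region derivation, site assignment and metagene
profiles."""

import numpy as np
import pandas as pd
import pytest

from thermomethyl import annotation as ann

CHROM_SIZES = {"chr1": 100_000, "chr2": 50_000}


def gene(gid="g1", chrom="chr1", start=5000, end=8000, strand="+", exons=None):
    return ann.GeneModel(gid, chrom, start, end, strand, exons or [])


# -------------------------------------------------------------- parsing

def test_gff3_coordinates_convert_to_half_open(tmp_path):
    path = tmp_path / "g.gff3"
    path.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=geneA\n"
        "chr1\tsrc\texon\t1001\t1200\t.\t+\t.\tID=geneA.e1;Parent=geneA\n"
        "chr1\tsrc\texon\t1801\t2000\t.\t+\t.\tID=geneA.e2;Parent=geneA\n"
    )
    (g,) = ann.parse_gene_models(str(path), "GFF3")
    assert (g.start, g.end) == (1000, 2000)
    assert g.exons == [(1000, 1200), (1800, 2000)]
    assert g.introns() == [(1200, 1800)]


def test_bed12_blocks_reconstruct_exons(tmp_path):
    path = tmp_path / "g.bed"
    path.write_text(
        "chr1\t1000\t2000\tgeneB\t0\t-\t1000\t2000\t0\t2\t200,300\t0,700\n"
    )
    (g,) = ann.parse_gene_models(str(path), "BED12")
    assert (g.start, g.end, g.strand) == (1000, 2000, "-")
    assert g.exons == [(1000, 1200), (1700, 2000)]


def test_empty_file_returns_empty_list(tmp_path, caplog):
    path = tmp_path / "empty.gff3"
    path.write_text("##gff-version 3\n")
    with caplog.at_level("WARNING"):
        assert ann.parse_gene_models(str(path), "GFF3") == []
    assert "no records" in caplog.text


def test_malformed_bed_reports_line(tmp_path):
    path = tmp_path / "bad.bed"
    path.write_text("chr1\t100\t50\tg\t0\t+\t.\t.\t.\t1\t10\t0\n")
    with pytest.raises(ValueError, match="bad.bed:1"):
        ann.parse_gene_models(str(path), "BED12")


def test_gene_model_invariants():
    with pytest.raises(ValueError, match="start >= end"):
        ann.GeneModel("g", "chr1", 10, 10, "+")
    with pytest.raises(ValueError, match="exon outside"):
        ann.GeneModel("g", "chr1", 10, 20, "+", [(5, 15)])


# -------------------------------------------------------------- regions

def test_region_derivation_strand_aware():
    rs = ann.derive_regions(
        [gene(strand="+"), gene(gid="g2", strand="-")], CHROM_SIZES
    )
    plus, minus = rs.regions["g1"], rs.regions["g2"]
    assert plus.promoter == (3000, 5000)
    assert plus.downstream == (8000, 10000)
    assert minus.promoter == (8000, 10000)
    assert minus.downstream == (3000, 5000)


def test_region_clipped_at_chromosome_edge():
    rs = ann.derive_regions([gene(start=500, end=1500)], CHROM_SIZES)
    assert rs.regions["g1"].promoter == (0, 500)


def test_region_unknown_chromosome_errors():
    with pytest.raises(ValueError, match="unknown chromosome"):
        ann.derive_regions([gene(chrom="chrX")], CHROM_SIZES)


def test_region_derivation_order_independent():
    genes = [gene(), gene(gid="g2", start=20000, end=30000, strand="-")]
    a = ann.derive_regions(genes, CHROM_SIZES)
    b = ann.derive_regions(genes[::-1], CHROM_SIZES)
    assert {
        k: (v.promoter, v.body, v.downstream) for k, v in a.regions.items()
    } == {k: (v.promoter, v.body, v.downstream) for k, v in b.regions.items()}


# ------------------------------------------------------------ assignment

def sites_frame(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(len(positions))],
            "chrom": chrom,
            "position": positions,
        }
    )


def test_assignment_element_priority():
    g1 = gene(exons=[(5000, 6000), (7000, 8000)])
    # g2's intron spans g1's promoter region
    g2 = gene(gid="g2", start=2000, end=4500, strand="+", exons=[(2000, 2500)])
    rs = ann.derive_regions([g1, g2], CHROM_SIZES)
    out = ann.assign_sites(sites_frame([5500, 6500, 3500, 40000]), rs)
    assert [a.element for a in out] == ["exon", "intron", "promoter", "intergenic"]
    assert out[2].gene_ids == ["g1", "g2"]  # promoter of g1, intron of g2
    assert out[3].gene_ids == []


def test_assignment_partitions_sites():
    rng = np.random.default_rng(0)
    genes = [
        gene(gid=f"g{i}", start=s, end=s + 2000, strand="+" if i % 2 else "-")
        for i, s in enumerate(range(5000, 85000, 8000))
    ]
    rs = ann.derive_regions(genes, CHROM_SIZES)
    sf = sites_frame(rng.integers(0, 100_000, size=500))
    out = ann.assign_sites(sf, rs)
    labels = pd.Series([a.element for a in out]).value_counts()
    assert labels.sum() == 500
    assert set(labels.index) <= {
        "promoter", "exon", "intron", "downstream", "intergenic"
    }


# -------------------------------------------------------------- metagene

def test_metagene_single_upstream_site_bin():
    g = gene(start=5000, end=8000, strand="+")
    prof = ann.metagene_profile(sites_frame([5000 - 150]), [g])
    assert prof.upstream[18] == 1.0
    assert prof.total_mass == 1.0
    assert prof.body.sum() == 0 and prof.downstream.sum() == 0


def test_metagene_uniform_body_is_flat():
    g = gene(start=0, end=6000, strand="+")
    # one site per bp across the body
    sf = sites_frame(np.arange(0, 6000))
    prof = ann.metagene_profile(sf, [g], flank=2000)
    assert np.allclose(prof.body, 100.0)


def test_metagene_no_sites_zero_profile():
    prof = ann.metagene_profile(sites_frame([]), [gene()])
    assert prof.total_mass == 0.0


def test_metagene_mass_conservation():
    rng = np.random.default_rng(1)
    genes = [
        gene(gid=f"g{i}", start=s, end=s + 3000, strand="+" if i % 2 else "-")
        for i, s in enumerate(range(5000, 85000, 10000))
    ]
    positions = rng.integers(0, 100_000, size=800)
    signal = rng.exponential(2.0, size=800)
    prof = ann.metagene_profile(sites_frame(positions), genes, signal=signal)
    covered = 0.0
    for pos, w in zip(positions, signal):
        if any(g.start - 2000 <= pos < g.end + 2000 for g in genes):
            covered += w
    assert prof.total_mass == pytest.approx(covered)


def test_metagene_strand_mirror():
    """Flipping a gene's strand mirrors its profile bin-for-bin."""
    L = 6000
    g_plus = gene(start=10000, end=10000 + L, strand="+")
    g_minus = gene(start=10000, end=10000 + L, strand="-")
    # sites at bin centres: flanks every 100 bp + body every 100 bp offset 50
    pos = (
        list(range(10000 - 1950, 10000, 100))
        + list(range(10000 + 50, 10000 + L, 100))
        + list(range(10000 + L + 50, 10000 + L + 2000, 100))
    )
    fwd = ann.metagene_profile(sites_frame(pos), [g_plus]).concat()
    rev = ann.metagene_profile(sites_frame(pos), [g_minus]).concat()
    assert np.array_equal(rev, fwd[::-1])


def test_metagene_skips_tiny_genes(caplog):
    tiny = gene(start=100, end=140)
    with caplog.at_level("WARNING"):
        prof = ann.metagene_profile(sites_frame([120]), [tiny])
    assert prof.n_genes_skipped == 1
    assert prof.total_mass == 0.0
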