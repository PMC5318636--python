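"""Reference genome and gene-model loading: coordinates, UTR derivation."""

import numpy as np
import pytest

from snpscape.refmodels import (
    derive_utrs,
    load_gene_models,
    load_genome,
    revcomp,
)

from helpers import write_fasta


def test_load_genome_lengths_and_slicing(tmp_path):
    fasta = write_fasta(tmp_path / "g.fa", {"chr1": "acgt"})
    g = load_genome(fasta)
    assert g.chrom_lengths == {"chr1": 4}
    assert g.fetch("chr1", 1, 3) == "CG"  # uppercased
    with pytest.raises(ValueError):
        g.fetch("chr1", 2, 9)
    with pytest.raises(KeyError):
        g.fetch("chrX", 0, 1)


def test_load_genome_rejects_duplicates_and_empty(tmp_path):
    p = tmp_path / "dup.fa"
    p.write_text(">a\nACGT\n>a\nTTTT\n")
    with pytest.raises(Exception):
        load_genome(str(p))
    empty = tmp_path / "empty.fa"
    empty.write_text("")
    with pytest.raises(Exception):
        load_genome(str(empty))


def test_gene_span_coordinate_shift(toy_ref):
    genome = load_genome(toy_ref["fasta"])
    transcripts, spans = load_gene_models(toy_ref["gff3"], genome)
    span_a = next(g for g in spans if g.gene_id == "geneA")
    assert span_a.span == (90, 120)  # GFF3 91..120 -> 0-based half-open
    assert span_a.cds_union_length == 9


def test_utr_derivation_matches_base_enumeration():
    """UTRs = exonic-minus-CDS flanks; checked against brute-force base sets."""
    exons = [(0, 60), (80, 100)]
    cds = [(10, 60), (80, 90)]
    utr5, utr3 = derive_utrs(exons, cds, "+")
    exon_bases = {b for s, e in exons for b in range(s, e)}
    cds_bases = {b for s, e in cds for b in range(s, e)}
    utr_bases = exon_bases - cds_bases
    five = {b for b in utr_bases if b < min(s for s, _ in cds)}
    three = {b for b in utr_bases if b >= max(e for _, e in cds)}
    assert {b for s, e in utr5 for b in range(s, e)} == five == set(range(0, 10))
    assert {b for s, e in utr3 for b in range(s, e)} == three == set(range(90, 100))
    # on the minus strand the same flanks swap roles
    u5m, u3m = derive_utrs(exons, cds, "-")
    assert (u5m, u3m) == (utr3, utr5)


def test_round_trip_to_gff3_coordinates(toy_ref):
    """Internal 0-based intervals map back to the input GFF3 rows exactly."""
    genome = load_genome(toy_ref["fasta"])
    transcripts, _ = load_gene_models(toy_ref["gff3"], genome)
    expected = {}
    for line in open(toy_ref["gff3"]):
        if line.startswith("#"):
            continue
        f = line.split("\t")
        if f[2] in ("exon", "CDS"):
            expected.setdefault((f[0], f[2], f[6]), set()).add((int(f[3]), int(f[4])))
    observed = {}
    for t in transcripts:
        for s, e in t.exons:
            observed.setdefault((t.chromosome, "exon", t.strand), set()).add((s + 1, e))
        for s, e in t.cds_segments:
            observed.setdefault((t.chromosome, "CDS", t.strand), set()).add((s + 1, e))
    assert observed == expected


def test_minus_strand_coding_sequence_reconstruction(toy_ref):
    """Spliced CDS on - equals the designed sequence; length is the segment sum."""
    genome = load_genome(toy_ref["fasta"])
    transcripts, _ = load_gene_models(toy_ref["gff3"], genome)
    tx_b = next(t for t in transcripts if t.gene_id == "geneB")
    cds = tx_b.coding_sequence(genome)
    assert len(cds) == sum(e - s for s, e in tx_b.cds_segments) == 120
    assert cds == toy_ref["cds_b"]
    assert cds.startswith("ATG")
    assert tx_b.is_complete


def test_overlapping_genes_both_retained(tmp_path):
    fasta = write_fasta(tmp_path / "g.fa", {"c": "A" * 300})
    gff = tmp_path / "o.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "c\tt\tgene\t51\t150\t.\t+\t.\tID=g1\n"
        "c\tt\tmRNA\t51\t150\t.\t+\t.\tID=g1.1;Parent=g1\n"
        "c\tt\texon\t51\t150\t.\t+\t.\tID=e1;Parent=g1.1\n"
        "c\tt\tgene\t101\t200\t.\t+\t.\tID=g2\n"
        "c\tt\tmRNA\t101\t200\t.\t+\t.\tID=g2.1;Parent=g2\n"
        "c\tt\texon\t101\t200\t.\t+\t.\tID=e2;Parent=g2.1\n"
    )
    genome = load_genome(fasta)
    _, spans = load_gene_models(str(gff), genome)
    assert {g.gene_id: g.span for g in spans} == {"g1": (50, 150), "g2": (100, 200)}


def test_unknown_chromosome_transcript_skipped(tmp_path):
    fasta = write_fasta(tmp_path / "g.fa", {"c": "A" * 100})
    gff = tmp_path / "bad.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "nowhere\tt\tgene\t1\t50\t.\t+\t.\tID=gx\n"
        "nowhere\tt\tmRNA\t1\t50\t.\t+\t.\tID=gx.1;Parent=gx\n"
        "nowhere\tt\texon\t1\t50\t.\t+\t.\tID=ex;Parent=gx.1\n"
    )
    genome = load_genome(fasta)
    with pytest.warns(UserWarning):
        transcripts, spans = load_gene_models(str(gff), genome)
    assert transcripts == [] and spans == []


def test_revcomp():
    assert revcomp("ATGC") == "GCAT"
    assert revcomp(revcomp("ACGTN")) == "ACGTN"
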