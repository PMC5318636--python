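"""Variant-effect classification against gene models."""

import numpy as np
import pytest

from snpscape.effects import (
    EffectSummary,
    annotate_variant,
    build_gene_index,
    classify_cds_snp,
    summarize_effects,
)
from snpscape.refmodels import GeneSpan, Transcript
from snpscape.variants import VariantRecord

from helpers import FakeGenome, oracle_classify, random_toy_transcript


def snp(pos1, ref, alt, chrom="chr1"):
    return VariantRecord("s", chrom, pos1, ref, alt, "SNP")


@pytest.fixture
def plus_gene():
    """Single-exon + gene: UTR5 [90,100), CDS ATGGCTTAA [100,109), UTR3 [109,120)."""
    seq = ["T"] * 300
    seq[100:109] = list("ATGGCTTAA")
    genome = FakeGenome({"chr1": "".join(seq)})
    tx = Transcript(
        transcript_id="tA.1", gene_id="gA", chromosome="chr1", strand="+",
        exons=[(90, 120)], cds_segments=[(100, 109)], cds_phases=[0],
        utr5=[(90, 100)], utr3=[(109, 120)],
    )
    span = GeneSpan("gA", "chr1", "+", (90, 120), 9)
    return genome, tx, span


def test_codon_substitution_plus_strand(plus_gene):
    genome, tx, _ = plus_gene
    # codon 2 position 1: GCT -> ACT, Ala -> Thr
    assert classify_cds_snp(snp(104, "G", "A"), tx, genome) == "cds_nonsynonymous"
    # codon 2 position 3: GCT -> GCC, Ala -> Ala
    assert classify_cds_snp(snp(106, "T", "C"), tx, genome) == "cds_synonymous"
    # stop loss counts as nonsynonymous
    assert classify_cds_snp(snp(107, "T", "C"), tx, genome) == "cds_nonsynonymous"


def test_incomplete_transcript_unclassified(plus_gene):
    genome, tx, _ = plus_gene
    broken = Transcript(
        transcript_id="tA.2", gene_id="gA", chromosome="chr1", strand="+",
        exons=[(90, 120)], cds_segments=[(100, 108)], cds_phases=[0],
    )
    assert classify_cds_snp(snp(104, "G", "A"), broken, genome) == "cds_unclassified"


def test_agrees_with_full_translation_oracle_both_strands():
    """Random toy transcripts: codon-level call equals whole-protein re-translation."""
    rng = np.random.default_rng(21)
    strands = set()
    for _ in range(200):
        genome, tx = random_toy_transcript(rng)
        strands.add(tx.strand)
        seg = tx.cds_segments[rng.integers(len(tx.cds_segments))]
        pos0 = int(rng.integers(seg[0], seg[1]))
        ref = genome.sequences["chrT"][pos0]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        got = classify_cds_snp(snp(pos0 + 1, ref, alt, chrom="chrT"), tx, genome)
        assert got == oracle_classify(genome, tx, pos0, alt)
    assert strands == {"+", "-"}


def test_annotation_categories_and_flanks(plus_gene):
    genome, tx, span = plus_gene
    index = build_gene_index([tx], [span], flank_bp=50)
    cases = {
        95: "utr5",
        112: "utr3",
        60: "regulatory_up",  # within 50 bp upstream of a + gene
        130: "regulatory_down",
        10: "intergenic",
    }
    for pos0, expected in cases.items():
        ref = genome.sequences["chr1"][pos0]
        recs = annotate_variant(snp(pos0 + 1, ref, "A" if ref != "A" else "C"), index, genome)
        assert [r.category for r in recs] == [expected], pos0
        assert recs[0].gene_id == ("" if expected == "intergenic" else "gA")


def test_cds_indel_category(plus_gene):
    genome, tx, span = plus_gene
    index = build_gene_index([tx], [span], flank_bp=50)
    v = VariantRecord("s", "chr1", 104, "GC", "G", "DEL")
    recs = annotate_variant(v, index, genome)
    assert [r.category for r in recs] == ["cds_indel"]


def test_one_record_per_overlapping_gene():
    """A SNP in gene A's intron that is also upstream of gene B yields two records."""
    genome = FakeGenome({"chr1": "T" * 1000})
    tx_a = Transcript(
        "tA.1", "gA", "chr1", "+", exons=[(100, 150), (250, 300)],
        cds_segments=[(100, 150), (250, 300)], cds_phases=[0, 1],
    )
    span_a = GeneSpan("gA", "chr1", "+", (100, 300), 100)
    tx_b = Transcript(
        "tB.1", "gB", "chr1", "+", exons=[(500, 600)], cds_segments=[], cds_phases=[]
    )
    span_b = GeneSpan("gB", "chr1", "+", (500, 600), 0)
    index = build_gene_index([tx_a, tx_b], [span_a, span_b], flank_bp=5000)
    recs = annotate_variant(snp(201, "T", "A"), index, genome)
    cats = {r.gene_id: r.category for r in recs}
    assert cats == {"gA": "intron", "gB": "regulatory_up"}


def test_severity_nonsynonymous_beats_synonymous(plus_gene):
    """Two transcripts of one gene disagree; the gene record takes the severer call."""
    genome, tx, span = plus_gene
    # second transcript shifted by one base so the same SNP hits another codon slot
    tx2 = Transcript(
        "tA.2", "gA", "chr1", "+", exons=[(90, 120)],
        cds_segments=[(99, 108)], cds_phases=[0],
    )
    seq = list(genome.sequences["chr1"])
    seq[99:108] = list("ATGGCTTAA")
    genome2 = FakeGenome({"chr1": "".join(seq)})
    index = build_gene_index([tx, tx2], [span], flank_bp=50)
    pos0 = 105
    ref = genome2.sequences["chr1"][pos0]
    recs = annotate_variant(snp(pos0 + 1, ref, "C"), index, genome2)
    assert len(recs) == 1
    per_tx = {
        t.transcript_id: classify_cds_snp(snp(pos0 + 1, ref, "C"), t, genome2)
        for t in (tx, tx2)
    }
    assert set(per_tx.values()) == {"cds_synonymous", "cds_nonsynonymous"}
    assert recs[0].category == "cds_nonsynonymous"


def test_ref_mismatch_is_tallied_not_fatal(plus_gene):
    from collections import Counter

    genome, tx, span = plus_gene
    index = build_gene_index([tx], [span], flank_bp=50)
    tally = Counter()
    recs = annotate_variant(snp(105, "A", "C"), index, genome, mismatch_tally=tally)
    assert tally["ref_mismatch"] == 1 and len(recs) == 1


def test_summary_percentages_single_intergenic(plus_gene):
    genome, tx, span = plus_gene
    index = build_gene_index([tx], [span], flank_bp=50)
    recs = annotate_variant(snp(11, "T", "A"), index, genome)
    summary = summarize_effects(recs)
    assert summary.percentages["intergenic"] == 100.0
    assert summary.counts["genic"] == 0


def test_summary_empty_input_all_zero():
    summary = summarize_effects([])
    assert all(v == 0 for v in summary.counts.values())
    assert all(v == 0.0 for v in summary.percentages.values())
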