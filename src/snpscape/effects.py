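"""Variant-effect annotation against gene models.

Each variant is classified, per overlapping gene, into one of:
intergenic, regulatory_up / regulatory_down (within a configurable flank,
default 5 kb, oriented by strand), intron, utr5 / utr3, or a CDS category.
CDS SNPs are sub-classified synonymous / nonsynonymous by rebuilding the
affected codon from the spliced coding sequence (reverse-complemented on
the minus strand) and translating with the standard genetic code; CDS
InDels are reported as cds_indel. One record is emitted per (variant, gene)
at the most severe category across that gene's transcripts, so overlapping
genes yield more effect records than variants — as annotation tables
conventionally do.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .refmodels import GenomeRef, GeneSpan, Transcript, revcomp
from .spectrum import round_half_up
from .variants import VariantRecord

DEFAULT_FLANK = 5000

CATEGORIES = (
    "intergenic",
    "regulatory_up",
    "regulatory_down",
    "intron",
    "utr5",
    "utr3",
    "cds_synonymous",
    "cds_nonsynonymous",
    "cds_unclassified",
    "cds_indel",
)

# lower = more severe; nonsynonymous outranks synonymous within CDS
_SEVERITY = {
    "cds_nonsynonymous": 0,
    "cds_indel": 0,
    "cds_synonymous": 1,
    "cds_unclassified": 2,
    "utr5": 3,
    "utr3": 3,
    "intron": 4,
    "regulatory_up": 5,
    "regulatory_down": 5,
}


@dataclass(frozen=True)
class EffectRecord:
    sample_id: str
    chromosome: str
    pos1: int
    ref: str
    alt: str
    gene_id: str  # empty for intergenic
    category: str
    transcript_id: str = ""  # transcript that determined the category


class GeneIndex:
    """Interval index answering which genes (incl. flanks) overlap a locus."""

    def __init__(
        self,
        transcripts: list[Transcript],
        gene_spans: list[GeneSpan],
        flank_bp: int = DEFAULT_FLANK,
    ):
        self.flank_bp = flank_bp
        self.genes: dict[str, GeneSpan] = {g.gene_id: g for g in gene_spans}
        self.transcripts_of: dict[str, list[Transcript]] = {}
        for t in transcripts:
            self.transcripts_of.setdefault(t.gene_id, []).append(t)
        self._trees: dict[str, IntervalTree] = {}
        for g in gene_spans:
            tree = self._trees.setdefault(g.chromosome, IntervalTree())
            s = max(0, g.span[0] - flank_bp)
            e = g.span[1] + flank_bp
            tree[s:e] = g.gene_id

    def overlapping_genes(self, chrom: str, start0: int, end0: int) -> list[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start0, end0)})


def build_gene_index(
    transcripts: list[Transcript],
    gene_spans: list[GeneSpan],
    flank_bp: int = DEFAULT_FLANK,
) -> GeneIndex:
    return GeneIndex(transcripts, gene_spans, flank_bp)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def classify_cds_snp(v: VariantRecord, transcript: Transcript, genome: GenomeRef) -> str:
    """Synonymous / nonsynonymous call for a SNP inside a CDS segment.

    The spliced coding sequence is assembled in transcription order, the
    variant's offset located, the alternate base substituted (complemented
    on −), and the affected codon translated. Incomplete transcripts,
    codons containing N, and truncated terminal codons are unclassifiable.
    """
    if not transcript.is_complete:
        return "cds_unclassified"
    pos0 = v.pos0
    segs = transcript.cds_segments
    offset = None
    if transcript.strand == "+":
        acc = 0
        for s, e in segs:
            if s <= pos0 < e:
                offset = acc + (pos0 - s)
                break
            acc += e - s
        alt = v.alt.upper()
    else:
        acc = 0
        for s, e in reversed(segs):
            if s <= pos0 < e:
                offset = acc + (e - 1 - pos0)
                break
            acc += e - s
        alt = revcomp(v.alt.upper())
    if offset is None:
        raise ValueError("variant does not overlap a CDS segment of the transcript")
    cds = transcript.coding_sequence(genome)
    eff = offset - transcript.first_phase
    if eff < 0:
        return "cds_unclassified"
    codon_start = transcript.first_phase + 3 * (eff // 3)
    codon = cds[codon_start : codon_start + 3]
    if len(codon) < 3 or "N" in codon or alt not in "ACGT":
        return "cds_unclassified"
    within = offset - codon_start
    mutant = codon[:within] + alt + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutant).translate())
    return "cds_synonymous" if aa_ref == aa_alt else "cds_nonsynonymous"


def _transcript_category(v: VariantRecord, t: Transcript, genome: GenomeRef) -> str | None:
    iv = (v.pos0, v.pos0 + (len(v.ref) if v.vtype == "DEL" else 1))
    if any(_overlaps(iv, seg) for seg in t.cds_segments):
        if v.vtype == "SNP":
            return classify_cds_snp(v, t, genome)
        return "cds_indel"
    if any(_overlaps(iv, u) for u in t.utr5):
        return "utr5"
    if any(_overlaps(iv, u) for u in t.utr3):
        return "utr3"
    if t.exons and _overlaps(iv, (t.exons[0][0], t.exons[-1][1])):
        return "intron"
    return None


def annotate_variant(
    v: VariantRecord,
    index: GeneIndex,
    genome: GenomeRef,
    mismatch_tally: Counter | None = None,
) -> list[EffectRecord]:
    """Classify one variant against every overlapping gene (or as intergenic)."""
    if v.chromosome in genome and v.pos0 < genome.chrom_lengths[v.chromosome]:
        end = min(v.pos0 + len(v.ref), genome.chrom_lengths[v.chromosome])
        observed = genome.fetch(v.chromosome, v.pos0, end)
        if observed != v.ref[: end - v.pos0]:
            if mismatch_tally is not None:
                mismatch_tally["ref_mismatch"] += 1
            else:
                warnings.warn(
                    f"REF mismatch at {v.chromosome}:{v.pos1} "
                    f"(VCF {v.ref}, genome {observed})"
                )
    var_end = v.pos0 + (len(v.ref) if v.vtype == "DEL" else 1)
    gene_ids = index.overlapping_genes(v.chromosome, v.pos0, var_end)
    records: list[EffectRecord] = []
    for gene_id in gene_ids:
        g = index.genes[gene_id]
        best: tuple[int, str, str] | None = None  # (severity, category, transcript)
        for t in sorted(index.transcripts_of.get(gene_id, []), key=lambda t: t.transcript_id):
            cat = _transcript_category(v, t, genome)
            if cat is not None:
                cand = (_SEVERITY[cat], cat, t.transcript_id)
                if best is None or cand < best:
                    best = cand
        if best is None:
            iv = (v.pos0, var_end)
            if _overlaps(iv, g.span):
                # inside the gene span but outside every transcript's exons
                best = (_SEVERITY["intron"], "intron", "")
            else:
                upstream = (
                    (max(0, g.span[0] - index.flank_bp), g.span[0])
                    if g.strand == "+"
                    else (g.span[1], g.span[1] + index.flank_bp)
                )
                cat = "regulatory_up" if _overlaps(iv, upstream) else "regulatory_down"
                best = (_SEVERITY[cat], cat, "")
        records.append(
            EffectRecord(
                sample_id=v.sample_id,
                chromosome=v.chromosome,
                pos1=v.pos1,
                ref=v.ref,
                alt=v.alt,
                gene_id=gene_id,
                category=best[1],
                transcript_id=best[2],
            )
        )
    if not records:
        records.append(
            EffectRecord(
                sample_id=v.sample_id,
                chromosome=v.chromosome,
                pos1=v.pos1,
                ref=v.ref,
                alt=v.alt,
                gene_id="",
                category="intergenic",
            )
        )
    return records


def annotate_all(
    variants: Iterable[VariantRecord], index: GeneIndex, genome: GenomeRef
) -> tuple[list[EffectRecord], Counter]:
    tally: Counter = Counter()
    out: list[EffectRecord] = []
    for v in variants:
        out.extend(annotate_variant(v, index, genome, mismatch_tally=tally))
    return out, tally


@dataclass
class EffectSummary:
    """Category counts with the percentages annotation tables conventionally print.

    Percentages: intergenic/genic over all effect records; intron-and-
    regulatory, UTRs and CDS over genic records; nonsynonymous/synonymous
    over classified CDS SNP records. Half-up rounding to 2 decimals.
    """

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_counts(
        cls,
        sample_id: str = "",
        intergenic: int = 0,
        genic: int = 0,
        intron_and_regulatory: int = 0,
        utrs: int = 0,
        cds: int = 0,
        nonsynonymous: int = 0,
        synonymous: int = 0,
        unclassified: int = 0,
    ) -> "EffectSummary":
        return cls(
            sample_id=sample_id,
            counts={
                "intergenic": intergenic,
                "genic": genic,
                "intron_and_regulatory": intron_and_regulatory,
                "utrs": utrs,
                "cds": cds,
                "nonsynonymous": nonsynonymous,
                "synonymous": synonymous,
                "unclassified": unclassified,
            },
        )

    def _pct(self, num: int, denom: int) -> float:
        return 0.0 if denom == 0 else round_half_up(100.0 * num / denom, 2)

    @property
    def percentages(self) -> dict[str, float]:
        c = self.counts
        all_records = c["intergenic"] + c["genic"]
        classified_cds = c["nonsynonymous"] + c["synonymous"]
        return {
            "intergenic": self._pct(c["intergenic"], all_records),
            "genic": self._pct(c["genic"], all_records),
            "intron_and_regulatory": self._pct(c["intron_and_regulatory"], c["genic"]),
            "utrs": self._pct(c["utrs"], c["genic"]),
            "cds": self._pct(c["cds"], c["genic"]),
            "nonsynonymous": self._pct(c["nonsynonymous"], classified_cds),
            "synonymous": self._pct(c["synonymous"], classified_cds),
        }


def summarize_effects(
    effects: Iterable[EffectRecord], sample_id: str | None = None
) -> EffectSummary:
    """Aggregate effect records from one sample and one variant class."""
    tally: Counter = Counter(e.category for e in effects)
    sid = sample_id
    if sid is None:
        sid = next((e.sample_id for e in effects), "")
    intergenic = tally["intergenic"]
    genic = sum(tally[c] for c in CATEGORIES if c != "intergenic")
    return EffectSummary.from_counts(
        sample_id=sid or "",
        intergenic=intergenic,
        genic=genic,
        intron_and_regulatory=tally["intron"]
        + tally["regulatory_up"]
        + tally["regulatory_down"],
        utrs=tally["utr5"] + tally["utr3"],
        cds=tally["cds_synonymous"]
        + tally["cds_nonsynonymous"]
        + tally["cds_unclassified"]
        + tally["cds_indel"],
        nonsynonymous=tally["cds_nonsynonymous"],
        synonymous=tally["cds_synonymous"],
        unclassified=tally["cds_unclassified"],
    )


def write_effects_tsv(effects: Iterable[EffectRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tpos1\tref\talt\tgene_id\tcategory\ttranscript_id\n")
        for e in effects:
            fh.write(
                f"{e.sample_id}\t{e.chromosome}\t{e.pos1}\t{e.ref}\t{e.alt}\t"
                f"{e.gene_id}\t{e.category}\t{e.transcript_id}\n"
            )


def write_summary_tsv(summaries: list[EffectSummary], path: str) -> None:
    keys = [
        "intergenic",
        "genic",
        "intron_and_regulatory",
        "utrs",
        "cds",
        "nonsynonymous",
        "synonymous",
    ]
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(f"{k}\t{k}_pct" for k in keys) + "\n")
        for s in summaries:
            pct = s.percentages
            fh.write(
                s.sample_id
                + "\t"
                + "\t".join(f"{s.counts[k]}\t{pct[k]:.2f}" for k in keys)
                + "\n"
            )
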