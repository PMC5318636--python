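"""Reference genome and gene-model access.

All coordinates inside the package are 0-based half-open; FASTA/GFF3/VCF
conventions are converted at the I/O boundary so downstream modules never
see a 1-based number.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gffutils
from pyfaidx import Fasta

log = logging.getLogger(__name__)

Interval = tuple[int, int]  # 0-based half-open


class GenomeRef:
    """Indexed reference genome with bounds-checked, uppercase access."""

    def __init__(self, fasta: Fasta):
        self._fasta = fasta
        self.chrom_names: list[str] = list(fasta.keys())
        self.chrom_lengths: dict[str, int] = {name: len(fasta[name]) for name in self.chrom_names}

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        """Return the sequence of ``chrom[start0:end0)`` as an uppercase string."""
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        length = self.chrom_lengths[chrom]
        if not (0 <= start0 <= end0 <= length):
            raise ValueError(
                f"interval [{start0},{end0}) out of range for {chrom} (length {length})"
            )
        return str(self._fasta[chrom][start0:end0]).upper()

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths


def load_genome(fasta_path: str) -> GenomeRef:
    """Load a FASTA reference.

    Fails on duplicate record identifiers or an empty file.
    """
    fasta = Fasta(str(fasta_path), sequence_always_upper=True)
    if len(list(fasta.keys())) == 0:
        raise ValueError(f"{fasta_path}: no FASTA records")
    return GenomeRef(fasta)


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str  # "+" or "-"
    exons: list[Interval]  # sorted, non-overlapping, genomic order
    cds_segments: list[Interval]  # genomic order
    cds_phases: list[int]  # phase of each cds segment, genomic order
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def is_complete(self) -> bool:
        """A transcript is translation-complete when its CDS is a positive multiple of 3."""
        n = self.cds_length
        return n > 0 and n % 3 == 0

    @property
    def first_phase(self) -> int:
        """Phase of the first CDS segment in transcription order (GFF3 default 0)."""
        if not self.cds_segments:
            return 0
        idx = 0 if self.strand == "+" else len(self.cds_segments) - 1
        return self.cds_phases[idx]

    def introns(self) -> list[Interval]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    def coding_sequence(self, genome: GenomeRef) -> str:
        """Concatenated CDS in transcription order (reverse-complemented on −)."""
        parts = [genome.fetch(self.chromosome, s, e) for s, e in self.cds_segments]
        seq = "".join(parts)
        if self.strand == "-":
            seq = revcomp(seq)
        return seq


@dataclass
class GeneSpan:
    gene_id: str
    chromosome: str
    strand: str
    span: Interval  # covers all transcripts
    cds_union_length: int  # bp in the union of all CDS intervals of the gene


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _to0(start1: int, end1: int) -> Interval:
    # GFF3 1-based inclusive -> 0-based half-open
    return (start1 - 1, end1)


def _union_length(intervals: list[Interval]) -> int:
    if not intervals:
        return 0
    total = 0
    cur_s, cur_e = sorted(intervals)[0]
    for s, e in sorted(intervals)[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def _subtract(intervals: list[Interval], minus: list[Interval]) -> list[Interval]:
    """Set difference of interval lists, result sorted and disjoint."""
    out = []
    for s, e in sorted(intervals):
        cuts = sorted(i for i in minus if i[0] < e and i[1] > s)
        pos = s
        for ms, me in cuts:
            if ms > pos:
                out.append((pos, ms))
            pos = max(pos, me)
        if pos < e:
            out.append((pos, e))
    return out


def derive_utrs(
    exons: list[Interval], cds: list[Interval], strand: str
) -> tuple[list[Interval], list[Interval]]:
    """Exonic-minus-CDS flanks split into 5' and 3' UTR by transcription order."""
    if not cds:
        return [], []
    non_cds = _subtract(exons, cds)
    cds_start = min(s for s, _ in cds)
    cds_end = max(e for _, e in cds)
    left = [(s, e) for s, e in non_cds if e <= cds_start]
    right = [(s, e) for s, e in non_cds if s >= cds_end]
    if strand == "+":
        return left, right
    return right, left


def load_gene_models(
    gff3_path: str, genome: GenomeRef
) -> tuple[list[Transcript], list[GeneSpan]]:
    """Parse gene/mRNA/exon/CDS(/UTR) features into internal 0-based models.

    UTRs come from explicit five_prime_UTR / three_prime_UTR features when
    present, otherwise are derived as the exonic-minus-CDS flanks. CDS
    features poking outside every exon are clipped with a warning; transcripts
    on unknown chromosomes or without a Parent are skipped with a warning.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts: list[Transcript] = []
    genes: dict[str, list[Transcript]] = {}
    gene_meta: dict[str, tuple[str, str]] = {}

    for gene in db.features_of_type("gene"):
        gene_meta[gene.id] = (gene.seqid, gene.strand)

    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent")
        if not parents:
            warnings.warn(f"mRNA {mrna.id} has no Parent; skipped")
            continue
        gene_id = parents[0]
        if mrna.seqid not in genome:
            warnings.warn(f"transcript {mrna.id} on unknown chromosome {mrna.seqid}; skipped")
            continue
        exons = sorted(_to0(f.start, f.end) for f in db.children(mrna, featuretype="exon"))
        cds_feats = sorted(
            db.children(mrna, featuretype="CDS"), key=lambda f: (f.start, f.end)
        )
        cds, phases = [], []
        for f in cds_feats:
            s, e = _to0(f.start, f.end)
            host = next((x for x in exons if x[0] <= s and e <= x[1]), None)
            if host is None:
                clip = next((x for x in exons if x[0] < e and x[1] > s), None)
                if clip is None:
                    warnings.warn(
                        f"CDS {s}-{e} of {mrna.id} outside every exon; dropped"
                    )
                    continue
                warnings.warn(f"CDS {s}-{e} of {mrna.id} clipped to exon {clip}")
                s, e = max(s, clip[0]), min(e, clip[1])
            phases.append(int(f.frame) if f.frame not in (None, ".") else 0)
            cds.append((s, e))
        utr5 = sorted(
            _to0(f.start, f.end) for f in db.children(mrna, featuretype="five_prime_UTR")
        )
        utr3 = sorted(
            _to0(f.start, f.end) for f in db.children(mrna, featuretype="three_prime_UTR")
        )
        if not utr5 and not utr3:
            utr5, utr3 = derive_utrs(exons, cds, mrna.strand)
        tx = Transcript(
            transcript_id=mrna.id,
            gene_id=gene_id,
            chromosome=mrna.seqid,
            strand=mrna.strand,
            exons=exons,
            cds_segments=cds,
            cds_phases=phases,
            utr5=utr5,
            utr3=utr3,
        )
        transcripts.append(tx)
        genes.setdefault(gene_id, []).append(tx)

    gene_spans: list[GeneSpan] = []
    for gene_id, txs in genes.items():
        chrom = txs[0].chromosome
        strand = gene_meta.get(gene_id, (chrom, txs[0].strand))[1]
        exon_bounds = [iv for t in txs for iv in t.exons] or [
            iv for t in txs for iv in t.cds_segments
        ]
        span = (min(s for s, _ in exon_bounds), max(e for _, e in exon_bounds))
        # widen to the gene feature if the GFF declares one
        try:
            g = db[gene_id]
            gs, ge = _to0(g.start, g.end)
            span = (min(span[0], gs), max(span[1], ge))
        except gffutils.FeatureNotFoundError:
            pass
        cds_union = _union_length([iv for t in txs for iv in t.cds_segments])
        gene_spans.append(
            GeneSpan(
                gene_id=gene_id,
                chromosome=chrom,
                strand=strand,
                span=span,
                cds_union_length=cds_union,
            )
        )
    gene_spans.sort(key=lambda g: (g.chromosome, g.span))
    transcripts.sort(key=lambda t: (t.chromosome, t.exons[0] if t.exons else (0, 0)))
    return transcripts, gene_spans
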