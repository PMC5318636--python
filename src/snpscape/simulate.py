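"""Synthetic reference, gene models and multi-sample variant calls.

The generator emulates the statistical structure a two-subspecies rice
resequencing panel shows against a common reference: two sample groups
whose SNP densities differ about 2.5-fold (defaults 7.7 vs 3.0 SNPs/kb),
strong within-group sharing of variants, embedded low-density intervals
(SNP deserts), a transition bias (p_transition = 0.70 giving an expected
Ts/Tv of 7/3 ~ 2.33), geometric InDel lengths with a mononucleotide
majority, and protein-coding gene models with UTR/CDS/intron structure on
alternating strands. Every planted variant carries a ground-truth category
label so downstream stages can be scored for recovery.

Variant positions follow a Poisson process whose rate is piecewise
constant: the group rate, thinned by a multiplier inside desert intervals
and amplified inside designated "hot" genes' CDS. Base composition is
i.i.d. uniform and no linkage structure is simulated; none of the
downstream statistics consume either.
"""

from __future__ import annotations

import bisect
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .refmodels import revcomp
from .variants import VariantRecord, write_vcf

BASES = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}
NON_STOP_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - STOPS
)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS_OF = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

#: flanks must not overlap a neighbouring gene so every locus has exactly
#: one gene context and truth labels are unambiguous
MIN_GENE_SPACING = 10_500


def _default_groups() -> dict[str, list[str]]:
    return {
        "indica": ["indica_1", "indica_2", "indica_3"],
        "japonica": ["japonica_1", "japonica_2"],
    }


@dataclass
class SimConfig:
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 20  # per chromosome
    exons_per_gene: int = 3
    exon_cds_bp: int = 300  # CDS bp per exon, multiple of 3
    intron_bp: int = 200
    utr5_bp: int = 90
    utr3_bp: int = 120
    groups: dict[str, list[str]] = field(default_factory=_default_groups)
    snp_rate_per_kb: dict[str, float] = field(
        default_factory=lambda: {"indica": 7.7, "japonica": 3.0}
    )
    indel_rate_per_kb: dict[str, float] = field(
        default_factory=lambda: {"indica": 1.1, "japonica": 0.45}
    )
    shared_fraction: float = 0.8
    p_transition: float = 0.70
    p_deletion: float = 0.55
    indel_geom_p: float = 0.55
    # (chromosome, start0, end0, rate multiplier)
    deserts: list[tuple[str, int, int, float]] = field(
        default_factory=lambda: [("chr1", 300_000, 500_000, 0.02)]
    )
    n_hot_genes: int = 4
    hot_multiplier: float = 8.0
    fail_fraction: float = 0.05
    flank_bp: int = 5000
    seed: int = 0

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def samples(self) -> list[str]:
        return [s for ss in self.groups.values() for s in ss]

    def group_of(self, sample: str) -> str:
        for g, ss in self.groups.items():
            if sample in ss:
                return g
        raise KeyError(sample)

    def validate(self) -> None:
        if self.exon_cds_bp % 3:
            raise ValueError("exon_cds_bp must be a multiple of 3")
        if not (0 <= self.shared_fraction <= 1):
            raise ValueError("shared_fraction must be in [0,1]")
        for chrom, s, e, _ in self.deserts:
            if chrom in self.chrom_names and not (0 <= s < e <= self.chrom_length):
                raise ValueError(f"desert {chrom}:{s}-{e} outside chromosome")


@dataclass
class SimGene:
    gene_id: str
    chromosome: str
    strand: str
    span: tuple[int, int]
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]]
    utr3: list[tuple[int, int]]


@dataclass
class TruthVariant:
    chromosome: str
    pos1: int
    ref: str
    alt: str
    vtype: str
    category: str
    gene_id: str


@dataclass
class GroundTruth:
    groups: dict[str, str] = field(default_factory=dict)  # sample -> group
    deserts: list[tuple[str, int, int]] = field(default_factory=list)
    hot_genes: list[str] = field(default_factory=list)
    variants: dict[str, list[TruthVariant]] = field(default_factory=dict)


@dataclass
class SimulatedReference:
    sequences: dict[str, str]
    genes: list[SimGene]
    truth: GroundTruth

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    def write_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                gid, tid = g.gene_id, g.gene_id + ".1"
                rows = [
                    (g.span, "gene", f"ID={gid}", "."),
                    (g.span, "mRNA", f"ID={tid};Parent={gid}", "."),
                ]
                for iv in g.exons:
                    rows.append((iv, "exon", f"ID={tid}.exon;Parent={tid}", "."))
                cds_tx = g.cds if g.strand == "+" else list(reversed(g.cds))
                acc = 0
                phased = {}
                for iv in cds_tx:
                    phased[iv] = (3 - acc % 3) % 3
                    acc += iv[1] - iv[0]
                for iv in g.cds:
                    rows.append((iv, "CDS", f"ID={tid}.cds;Parent={tid}", str(phased[iv])))
                for iv in g.utr5:
                    rows.append((iv, "five_prime_UTR", f"ID={tid}.u5;Parent={tid}", "."))
                for iv in g.utr3:
                    rows.append((iv, "three_prime_UTR", f"ID={tid}.u3;Parent={tid}", "."))
                for (s, e), ftype, attrs, phase in rows:
                    fh.write(
                        f"{g.chromosome}\tsnpscape_sim\t{ftype}\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t{phase}\t{attrs}\n"
                    )


def _rng(seed: int, *names: str) -> np.random.Generator:
    parts = [seed] + [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(parts)


def _make_cds_seq(n_bp: int, rng: np.random.Generator) -> str:
    """ATG + random non-stop codons + one stop; translates cleanly."""
    n_codons = n_bp // 3
    if n_codons < 3:
        raise ValueError("CDS too short")
    internal = rng.choice(NON_STOP_CODONS, size=n_codons - 2)
    return "ATG" + "".join(internal) + str(rng.choice(sorted(STOPS)))


def generate_reference(cfg: SimConfig) -> SimulatedReference:
    """Random genome with designed, non-overlapping gene models.

    Deterministic given cfg.seed; fails with the required chromosome length
    when the requested genes cannot fit with non-overlapping flanks.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "reference")
    n_ex = cfg.exons_per_gene
    gene_len = (
        cfg.utr5_bp + n_ex * cfg.exon_cds_bp + (n_ex - 1) * cfg.intron_bp + cfg.utr3_bp
    )
    sequences: dict[str, str] = {}
    genes: list[SimGene] = []
    for chrom in cfg.chrom_names:
        seq = rng.choice(BASES, size=cfg.chrom_length)
        if cfg.n_genes > 0:
            spacing = (cfg.chrom_length - cfg.n_genes * gene_len) / (cfg.n_genes + 1)
            if spacing < MIN_GENE_SPACING:
                need = cfg.n_genes * gene_len + (cfg.n_genes + 1) * MIN_GENE_SPACING
                raise ValueError(
                    f"{cfg.n_genes} genes of {gene_len} bp need a chromosome of "
                    f">= {need} bp (got {cfg.chrom_length})"
                )
            for i in range(cfg.n_genes):
                start = int(round(spacing * (i + 1) + gene_len * i))
                strand = "+" if i % 2 == 0 else "-"
                gene = _build_gene(cfg, chrom, f"{chrom}g{i + 1:04d}", start, strand, rng)
                _imprint_gene(seq, gene, cfg, rng)
                genes.append(gene)
        sequences[chrom] = "".join(seq)
    truth = GroundTruth()
    for group, samples in cfg.groups.items():
        for s in samples:
            truth.groups[s] = group
    truth.deserts = [(c, s, e) for c, s, e, _ in cfg.deserts if c in cfg.chrom_names]
    coding = [g.gene_id for g in genes]
    hot_rng = _rng(cfg.seed, "hot_genes")
    n_hot = min(cfg.n_hot_genes, len(coding))
    truth.hot_genes = (
        sorted(str(g) for g in hot_rng.choice(coding, size=n_hot, replace=False))
        if n_hot
        else []
    )
    return SimulatedReference(sequences=sequences, genes=genes, truth=truth)


def _build_gene(
    cfg: SimConfig, chrom: str, gene_id: str, start: int, strand: str, rng
) -> SimGene:
    """Lay out exon/CDS/UTR intervals in genomic coordinates.

    Transcription order equals genomic order on +; on - the 5'UTR sits at
    the genomic right end.
    """
    n_ex = cfg.exons_per_gene
    utr_left = cfg.utr5_bp if strand == "+" else cfg.utr3_bp
    utr_right = cfg.utr3_bp if strand == "+" else cfg.utr5_bp
    exons, cds = [], []
    pos = start
    for i in range(n_ex):
        ex_start = pos
        if i == 0:
            pos += utr_left
        cds_iv = (pos, pos + cfg.exon_cds_bp)
        pos += cfg.exon_cds_bp
        if i == n_ex - 1:
            pos += utr_right
        exons.append((ex_start, pos))
        cds.append(cds_iv)
        if i < n_ex - 1:
            pos += cfg.intron_bp
    span = (start, pos)
    left = [(span[0], span[0] + utr_left)]
    right = [(span[1] - utr_right, span[1])]
    utr5, utr3 = (left, right) if strand == "+" else (right, left)
    return SimGene(
        gene_id=gene_id,
        chromosome=chrom,
        strand=strand,
        span=span,
        exons=exons,
        cds=cds,
        utr5=utr5,
        utr3=utr3,
    )


def _imprint_gene(seq: np.ndarray, gene: SimGene, cfg: SimConfig, rng) -> None:
    """Overwrite the chromosome slice with a CDS that translates cleanly."""
    total_cds = sum(e - s for s, e in gene.cds)
    cds_seq = _make_cds_seq(total_cds, rng)
    genomic = cds_seq if gene.strand == "+" else revcomp(cds_seq)
    acc = 0
    for s, e in gene.cds:
        seq[s:e] = list(genomic[acc : acc + (e - s)])
        acc += e - s


# ---------------------------------------------------------------------------
# variant simulation


def _rate_segments(
    cfg: SimConfig, reference: SimulatedReference, chrom: str, base_per_bp: float,
    amplify_hot: bool,
) -> list[tuple[int, int, float]]:
    """Piecewise-constant rate: thinned in deserts, amplified in hot CDS."""
    modifiers: list[tuple[int, int, float]] = []
    for c, s, e, mult in cfg.deserts:
        if c == chrom:
            modifiers.append((s, e, mult))
    if amplify_hot:
        hot = set(reference.truth.hot_genes)
        for g in reference.genes:
            if g.chromosome == chrom and g.gene_id in hot:
                for s, e in g.cds:
                    modifiers.append((s, e, cfg.hot_multiplier))
    cuts = sorted({0, cfg.chrom_length} | {x for s, e, _ in modifiers for x in (s, e)})
    segs = []
    for s, e in zip(cuts, cuts[1:]):
        rate = base_per_bp
        for ms, me, mult in modifiers:
            if ms <= s and e <= me:
                rate *= mult
        segs.append((s, e, rate))
    return segs


def _draw_positions(segs, rng) -> np.ndarray:
    pos = []
    for s, e, rate in segs:
        n = rng.poisson(rate * (e - s))
        if n:
            pos.append(rng.integers(s, e, size=n))
    if not pos:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(pos))


def _draw_snvs(cfg, reference, chrom, rate_per_kb, rng, amplify_hot=True):
    segs = _rate_segments(cfg, reference, chrom, rate_per_kb / 1000.0, amplify_hot)
    seq = reference.sequences[chrom]
    out = []
    for p0 in _draw_positions(segs, rng):
        ref = seq[p0]
        if ref not in "ACGT":
            continue
        if rng.random() < cfg.p_transition:
            alt = TRANSITION[ref]
        else:
            alt = TRANSVERSIONS_OF[ref][rng.integers(0, 2)]
        out.append((chrom, int(p0) + 1, ref, alt, "SNP"))
    return out


def _draw_indels(cfg, reference, chrom, rate_per_kb, rng):
    segs = _rate_segments(cfg, reference, chrom, rate_per_kb / 1000.0, amplify_hot=False)
    seq = reference.sequences[chrom]
    out = []
    for p0 in _draw_positions(segs, rng):
        p0 = int(p0)
        length = int(rng.geometric(cfg.indel_geom_p))
        anchor = seq[p0]
        if anchor not in "ACGT":
            continue
        if rng.random() < cfg.p_deletion:
            if p0 + 1 + length > len(seq):
                continue
            ref = seq[p0 : p0 + 1 + length]
            if "N" in ref:
                continue
            out.append((chrom, p0 + 1, ref, anchor, "DEL"))
        else:
            ins = "".join(rng.choice(BASES, size=length))
            out.append((chrom, p0 + 1, anchor, anchor + ins, "INS"))
    return out


def _truth_category(
    reference: SimulatedReference, cfg: SimConfig, chrom: str, pos1: int, ref: str,
    alt: str, vtype: str,
) -> tuple[str, str]:
    """(category, gene_id) under the same coordinate rules the annotator uses."""
    pos0 = pos1 - 1
    iv = (pos0, pos0 + (len(ref) if vtype == "DEL" else 1))
    cache = getattr(reference, "_gene_lookup", None)
    if cache is None:
        cache = {}
        for g in sorted(reference.genes, key=lambda g: (g.chromosome, g.span)):
            cache.setdefault(g.chromosome, ([], []))
            cache[g.chromosome][0].append(max(0, g.span[0] - cfg.flank_bp))
            cache[g.chromosome][1].append(g)
        reference._gene_lookup = cache
    starts, genes = cache.get(chrom, ([], []))
    # flanked spans are disjoint by construction: at most two candidates
    idx = bisect.bisect_right(starts, iv[1] - 1) - 1
    for g in genes[max(0, idx) : idx + 2] if genes else []:
        lo = max(0, g.span[0] - cfg.flank_bp)
        hi = g.span[1] + cfg.flank_bp
        if not (iv[0] < hi and lo < iv[1]):
            continue
        if any(iv[0] < e and s < iv[1] for s, e in g.cds):
            if vtype != "SNP":
                return "cds_indel", g.gene_id
            return _truth_syn_nonsyn(reference, g, pos0, alt), g.gene_id
        if any(iv[0] < e and s < iv[1] for s, e in g.utr5):
            return "utr5", g.gene_id
        if any(iv[0] < e and s < iv[1] for s, e in g.utr3):
            return "utr3", g.gene_id
        if iv[0] < g.span[1] and g.span[0] < iv[1]:
            return "intron", g.gene_id
        upstream = (
            (lo, g.span[0]) if g.strand == "+" else (g.span[1], hi)
        )
        if iv[0] < upstream[1] and upstream[0] < iv[1]:
            return "regulatory_up", g.gene_id
        return "regulatory_down", g.gene_id
    return "intergenic", ""


def _truth_syn_nonsyn(reference: SimulatedReference, g: SimGene, pos0: int, alt: str) -> str:
    seq = reference.sequences[g.chromosome]
    cds = "".join(seq[s:e] for s, e in g.cds)
    if g.strand == "+":
        acc = 0
        offset = None
        for s, e in g.cds:
            if s <= pos0 < e:
                offset = acc + pos0 - s
                break
            acc += e - s
        sub = alt
    else:
        cds = revcomp(cds)
        acc = 0
        offset = None
        for s, e in reversed(g.cds):
            if s <= pos0 < e:
                offset = acc + (e - 1 - pos0)
                break
            acc += e - s
        sub = revcomp(alt)
    codon_i = offset // 3
    codon = cds[3 * codon_i : 3 * codon_i + 3]
    mutant = codon[: offset % 3] + sub + codon[offset % 3 + 1 :]
    same = str(Seq(codon).translate()) == str(Seq(mutant).translate())
    return "cds_synonymous" if same else "cds_nonsynonymous"


def _quality_fields(rng, vtype: str, fail: bool) -> dict:
    vaf = float(rng.uniform(0.35, 0.99))
    q = {"mapq": 50.0, "depth": 40.0, "base_qual": 35.0, "vaf": round(vaf, 4)}
    if fail:
        which = rng.integers(0, 4)
        if which == 0:
            q["mapq"] = 10.0
        elif which == 1:
            q["depth"] = 5.0
        elif which == 2:
            q["base_qual"] = 20.0
        else:
            q["vaf"] = 0.05
    return q


def simulate_sample_variants(
    cfg: SimConfig, reference: SimulatedReference, sample: str
) -> list[VariantRecord]:
    """Draw one sample's variants: the group's shared pool plus private draws.

    The shared pool is generated from a substream keyed by (seed, group) so
    every sample of a group sees identical shared variants; private draws
    use a (seed, sample) substream. Quality fields pass the default
    thresholds except for a configurable fraction of deliberate failures.
    Ground-truth entries are appended to reference.truth.
    """
    group = cfg.group_of(sample)
    snp_rate = cfg.snp_rate_per_kb[group]
    indel_rate = cfg.indel_rate_per_kb.get(group, 0.0)
    raw: list[tuple[str, int, str, str, str]] = []
    for chrom in cfg.chrom_names:
        shared_rng = _rng(cfg.seed, "shared", group, chrom)
        private_rng = _rng(cfg.seed, "private", sample, chrom)
        raw += _draw_snvs(cfg, reference, chrom, snp_rate * cfg.shared_fraction, shared_rng)
        raw += _draw_snvs(
            cfg, reference, chrom, snp_rate * (1 - cfg.shared_fraction), private_rng
        )
        if indel_rate > 0:
            raw += _draw_indels(
                cfg, reference, chrom, indel_rate * cfg.shared_fraction, shared_rng
            )
            raw += _draw_indels(
                cfg, reference, chrom, indel_rate * (1 - cfg.shared_fraction), private_rng
            )
    # one record per site: first wins after sort (shared pools sort stably)
    seen: set[tuple[str, int]] = set()
    uniq = []
    for rec in sorted(raw, key=lambda r: (r[0], r[1], r[4])):
        if (rec[0], rec[1]) in seen:
            continue
        seen.add((rec[0], rec[1]))
        uniq.append(rec)
    qual_rng = _rng(cfg.seed, "quality", sample)
    records: list[VariantRecord] = []
    truth_list: list[TruthVariant] = []
    for chrom, pos1, ref, alt, vtype in uniq:
        fail = bool(qual_rng.random() < cfg.fail_fraction)
        q = _quality_fields(qual_rng, vtype, fail)
        records.append(
            VariantRecord(
                sample_id=sample,
                chromosome=chrom,
                pos1=pos1,
                ref=ref,
                alt=alt,
                vtype=vtype,
                **q,
            )
        )
        category, gene_id = _truth_category(reference, cfg, chrom, pos1, ref, alt, vtype)
        truth_list.append(
            TruthVariant(
                chromosome=chrom,
                pos1=pos1,
                ref=ref,
                alt=alt,
                vtype=vtype,
                category=category,
                gene_id=gene_id,
            )
        )
    reference.truth.variants[sample] = truth_list
    return records


def simulate_study(
    cfg: SimConfig,
) -> tuple[SimulatedReference, dict[str, list[VariantRecord]]]:
    """Reference plus every configured sample's variant calls."""
    reference = generate_reference(cfg)
    calls = {s: simulate_sample_variants(cfg, reference, s) for s in cfg.samples}
    return reference, calls


def write_study(
    cfg: SimConfig, reference: SimulatedReference, calls: dict[str, list[VariantRecord]],
    outdir: str,
) -> dict[str, str]:
    """Emit FASTA, GFF3 and per-sample VCFs; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"fasta": str(out / "reference.fa"), "gff3": str(out / "genes.gff3")}
    reference.write_fasta(paths["fasta"])
    reference.write_gff3(paths["gff3"])
    contigs = {c: cfg.chrom_length for c in cfg.chrom_names}
    for sample, records in calls.items():
        p = str(out / f"{sample}.vcf")
        write_vcf(records, p, contigs=contigs)
        paths[sample] = p
    return paths


def truth_report(truth: GroundTruth, outdir: str) -> dict[str, str]:
    """Machine-readable ground truth: deserts BED, categories TSV, groups TSV."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "deserts": str(out / "truth_deserts.bed"),
        "categories": str(out / "truth_categories.tsv"),
        "groups": str(out / "truth_groups.tsv"),
        "hot_genes": str(out / "truth_hot_genes.tsv"),
    }
    with open(paths["deserts"], "w") as fh:
        for chrom, s, e in truth.deserts:
            fh.write(f"{chrom}\t{s}\t{e}\tplanted_desert\n")
    with open(paths["categories"], "w") as fh:
        fh.write("sample\tchrom\tpos1\tref\talt\tvtype\tcategory\tgene_id\n")
        for sample, tvs in truth.variants.items():
            for t in tvs:
                fh.write(
                    f"{sample}\t{t.chromosome}\t{t.pos1}\t{t.ref}\t{t.alt}\t"
                    f"{t.vtype}\t{t.category}\t{t.gene_id}\n"
                )
    with open(paths["groups"], "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in truth.groups.items():
            fh.write(f"{sample}\t{group}\n")
    with open(paths["hot_genes"], "w") as fh:
        fh.write("gene_id\n")
        for g in truth.hot_genes:
            fh.write(g + "\n")
    return paths
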