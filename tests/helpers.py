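"""Shared builders and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

from snpscape.refmodels import Transcript, revcomp


def write_fasta(path, sequences: dict[str, str]) -> str:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return str(path)


class FakeGenome:
    """In-memory genome with the same access contract as GenomeRef."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {k: v.upper() for k, v in sequences.items()}
        self.chrom_names = list(self.sequences)
        self.chrom_lengths = {k: len(v) for k, v in self.sequences.items()}

    def fetch(self, chrom, start0, end0):
        if not (0 <= start0 <= end0 <= self.chrom_lengths[chrom]):
            raise ValueError("out of range")
        return self.sequences[chrom][start0:end0]

    def __contains__(self, chrom):
        return chrom in self.sequences


def imprint(seq: list[str], segments, content: str) -> None:
    """Write `content` across genomic segments in genomic order."""
    acc = 0
    for s, e in segments:
        seq[s:e] = list(content[acc : acc + (e - s)])
        acc += e - s


STOPS = {"TAA", "TAG", "TGA"}
NON_STOP = sorted({a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - STOPS)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    internal = rng.choice(NON_STOP, size=n_codons - 2)
    return "ATG" + "".join(internal) + ["TAA", "TAG", "TGA"][rng.integers(0, 3)]


def random_toy_transcript(rng: np.random.Generator):
    """Random 1-3 exon coding transcript on a random sequence, either strand.

    Returns (FakeGenome, Transcript). Exons equal CDS segments (no UTRs) --
    enough for codon-classification checks.
    """
    n_ex = int(rng.integers(1, 4))
    seg_codons = [int(rng.integers(2, 8)) for _ in range(n_ex)]
    # ensure total CDS has room for start+stop
    while sum(seg_codons) < 3:
        seg_codons[0] += 1
    cds_seq = random_cds(sum(seg_codons), rng)
    strand = "+" if rng.random() < 0.5 else "-"
    pos = int(rng.integers(5, 20))
    segments = []
    lengths = [3 * c for c in seg_codons]
    for L in lengths:
        segments.append((pos, pos + L))
        pos += L + int(rng.integers(5, 15))
    total_len = pos + 10
    seq = list(rng.choice(list("ACGT"), size=total_len))
    genomic = cds_seq if strand == "+" else revcomp(cds_seq)
    imprint(seq, segments, genomic)
    genome = FakeGenome({"chrT": "".join(seq)})
    tx = Transcript(
        transcript_id="t1",
        gene_id="g1",
        chromosome="chrT",
        strand=strand,
        exons=segments,
        cds_segments=segments,
        cds_phases=[0] * n_ex,
    )
    return genome, tx


def oracle_classify(genome: FakeGenome, tx: Transcript, pos0: int, alt: str) -> str:
    """Full-protein translation oracle: rebuild and translate the whole mutant CDS.

    Independent of classify_cds_snp: the substitution is applied in genomic
    coordinates before splicing.
    """
    seq = list(genome.sequences[tx.chromosome])
    ref_cds = "".join("".join(seq[s:e]) for s, e in tx.cds_segments)
    seq[pos0] = alt
    alt_cds = "".join("".join(seq[s:e]) for s, e in tx.cds_segments)
    if tx.strand == "-":
        ref_cds, alt_cds = revcomp(ref_cds), revcomp(alt_cds)
    ref_protein = str(Seq(ref_cds).translate())
    alt_protein = str(Seq(alt_cds).translate())
    return "cds_synonymous" if ref_protein == alt_protein else "cds_nonsynonymous"


def brute_force_deserts(counts, window_size, chrom_length, threshold_per_kb=1.0):
    """Exhaustive maximal-run scan: every qualifying window, merged greedily."""
    qualifying = []
    for i, c in enumerate(counts):
        wlen = min(window_size, chrom_length - i * window_size)
        qualifying.append(c < threshold_per_kb * wlen / 1000.0)
    runs = []
    i = 0
    n = len(counts)
    while i < n:
        if qualifying[i]:
            j = i
            while j + 1 < n and qualifying[j + 1]:
                j += 1
            runs.append(
                (i * window_size, min((j + 1) * window_size, chrom_length))
            )
            i = j + 1
        else:
            i += 1
    return runs


def tukey_five_numbers(values):
    """Second, independent implementation of Tukey hinges via statistics.median."""
    import statistics

    vals = sorted(values)
    n = len(vals)
    med = statistics.median(vals)
    if n % 2:
        lower = vals[: n // 2 + 1]
        upper = vals[n // 2 :]
    else:
        lower = vals[: n // 2]
        upper = vals[n // 2 :]
    return (
        vals[0],
        statistics.median(lower),
        med,
        statistics.median(upper),
        vals[-1],
    )


def brute_force_pearson(x, y):
    """Textbook Pearson r computed with explicit loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)
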