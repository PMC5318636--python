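import numpy as np
import pytest

from snpscape.simulate import SimConfig, simulate_study

from helpers import FakeGenome, imprint, write_fasta


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at default two-group settings."""
    cfg = SimConfig(seed=11)
    reference, calls = simulate_study(cfg)
    return cfg, reference, calls


@pytest.fixture(scope="session")
def toy_ref(tmp_path_factory):
    """Tiny two-chromosome reference with hand-placed gene models.

    chr1: + strand single-exon-structure gene A with CDS ATGGCTTAA at
    [100,109), UTRs [90,100) and [109,120).
    chr2: - strand two-exon gene B, CDS segments [60,130) and [180,230)
    (120 bp of coding sequence read right-to-left).
    """
    rng = np.random.default_rng(42)
    chr1 = list(rng.choice(list("ACGT"), size=300))
    imprint(chr1, [(100, 109)], "ATGGCTTAA")
    chr2 = list(rng.choice(list("ACGT"), size=400))
    from helpers import random_cds
    from snpscape.refmodels import revcomp

    cds_b = random_cds(40, rng)  # 120 bp
    imprint(chr2, [(60, 130), (180, 230)], revcomp(cds_b))
    sequences = {"chr1": "".join(chr1), "chr2": "".join(chr2)}

    d = tmp_path_factory.mktemp("toyref")
    fasta = write_fasta(d / "ref.fa", sequences)
    gff = d / "genes.gff3"
    rows = [
        # gene A, + strand, chr1
        ("chr1", "gene", 91, 120, "+", ".", "ID=geneA"),
        ("chr1", "mRNA", 91, 120, "+", ".", "ID=geneA.1;Parent=geneA"),
        ("chr1", "exon", 91, 120, "+", ".", "ID=geneA.1.e1;Parent=geneA.1"),
        ("chr1", "CDS", 101, 109, "+", "0", "ID=geneA.1.c1;Parent=geneA.1"),
        # gene B, - strand, chr2, two exons; transcription starts at the right
        ("chr2", "gene", 51, 260, "-", ".", "ID=geneB"),
        ("chr2", "mRNA", 51, 260, "-", ".", "ID=geneB.1;Parent=geneB"),
        ("chr2", "exon", 51, 130, "-", ".", "ID=geneB.1.e1;Parent=geneB.1"),
        ("chr2", "exon", 181, 260, "-", ".", "ID=geneB.1.e2;Parent=geneB.1"),
        ("chr2", "CDS", 61, 130, "-", "1", "ID=geneB.1.c1;Parent=geneB.1"),
        ("chr2", "CDS", 181, 230, "-", "0", "ID=geneB.1.c2;Parent=geneB.1"),
    ]
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, ftype, start, end, strand, phase, attrs in rows:
            fh.write(
                f"{chrom}\ttest\t{ftype}\t{start}\t{end}\t.\t{strand}\t{phase}\t{attrs}\n"
            )
    return {"fasta": fasta, "gff3": str(gff), "sequences": sequences, "cds_b": cds_b}


@pytest.fixture()
def fake_genome(toy_ref):
    return FakeGenome(toy_ref["sequences"])
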