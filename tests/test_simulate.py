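"""Synthetic-study generator: determinism, rates, structure, ground truth."""

import io
from collections import Counter

import numpy as np
import pytest
from Bio.Seq import Seq

from snpscape.refmodels import load_gene_models, load_genome
from snpscape.simulate import (
    SimConfig,
    generate_reference,
    simulate_sample_variants,
    simulate_study,
    truth_report,
    write_study,
)

SMALL = dict(n_chromosomes=1, chrom_length=400_000, n_genes=5, deserts=[])


def test_same_seed_is_byte_identical(tmp_path):
    outs = []
    for d in ("a", "b"):
        cfg = SimConfig(seed=5, **SMALL)
        ref, calls = simulate_study(cfg)
        paths = write_study(cfg, ref, calls, str(tmp_path / d))
        outs.append(paths)
    for key in outs[0]:
        assert (
            open(outs[0][key], "rb").read() == open(outs[1][key], "rb").read()
        ), key


def test_gene_free_genome():
    cfg = SimConfig(seed=1, n_chromosomes=1, chrom_length=100_000, n_genes=0, deserts=[])
    ref = generate_reference(cfg)
    assert ref.genes == []
    assert len(ref.sequences["chr1"]) == 100_000


def test_genes_that_cannot_fit_are_fatal():
    cfg = SimConfig(seed=1, n_chromosomes=1, chrom_length=20_000, n_genes=10, deserts=[])
    with pytest.raises(ValueError, match="chromosome of"):
        generate_reference(cfg)


def test_every_cds_translates_without_internal_stop():
    cfg = SimConfig(seed=2, **SMALL)
    ref = generate_reference(cfg)
    assert ref.genes
    for g in ref.genes:
        cds = "".join(ref.sequences[g.chromosome][s:e] for s, e in g.cds)
        if g.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        protein = str(Seq(cds).translate())
        assert protein.startswith("M")
        assert protein.endswith("*")
        assert "*" not in protein[:-1]


def test_emitted_gff3_round_trips_through_loader(tmp_path):
    cfg = SimConfig(seed=3, **SMALL)
    ref, calls = simulate_study(cfg)
    paths = write_study(cfg, ref, calls, str(tmp_path))
    genome = load_genome(paths["fasta"])
    transcripts, spans = load_gene_models(paths["gff3"], genome)
    assert len(spans) == len(ref.genes)
    for tx in transcripts:
        assert tx.is_complete
        assert tx.coding_sequence(genome).startswith("ATG")


def test_snp_count_within_three_se_of_rate():
    cfg = SimConfig(
        seed=4, n_chromosomes=1, chrom_length=2_000_000, n_genes=0, deserts=[],
        groups={"indica": ["x"]}, snp_rate_per_kb={"indica": 7.7},
        indel_rate_per_kb={"indica": 0.0}, fail_fraction=0.0,
    )
    ref = generate_reference(cfg)
    records = simulate_sample_variants(cfg, ref, "x")
    expected = 7.7 * 2000
    n_snp = sum(r.vtype == "SNP" for r in records)
    assert abs(n_snp - expected) < 3 * expected**0.5 + 3  # +3 for position dedup


def test_transition_fraction_within_three_se():
    cfg = SimConfig(
        seed=6, n_chromosomes=1, chrom_length=2_000_000, n_genes=0, deserts=[],
        groups={"indica": ["x"]}, snp_rate_per_kb={"indica": 7.7},
        indel_rate_per_kb={"indica": 0.0},
    )
    ref = generate_reference(cfg)
    records = [r for r in simulate_sample_variants(cfg, ref, "x") if r.vtype == "SNP"]
    ts = sum(
        tuple(sorted((r.ref, r.alt))) in (("A", "G"), ("C", "T")) for r in records
    )
    p_hat = ts / len(records)
    se = (0.7 * 0.3 / len(records)) ** 0.5
    assert abs(p_hat - 0.7) < 3 * se


def test_zero_multiplier_desert_has_no_planted_variants():
    cfg = SimConfig(
        seed=7, n_chromosomes=1, chrom_length=500_000, n_genes=0,
        deserts=[("chr1", 100_000, 200_000, 0.0)],
        groups={"indica": ["x"]}, snp_rate_per_kb={"indica": 7.7},
        indel_rate_per_kb={"indica": 1.0},
    )
    ref = generate_reference(cfg)
    records = simulate_sample_variants(cfg, ref, "x")
    assert not [r for r in records if 100_000 < r.pos1 <= 200_000]


def test_within_group_sharing(default_study):
    cfg, ref, calls = default_study
    sites = {s: {(r.chromosome, r.pos1, r.alt) for r in rs} for s, rs in calls.items()}
    i1, i2 = sites["indica_1"], sites["indica_2"]
    j1 = sites["japonica_1"]
    within = len(i1 & i2) / len(i1)
    across = len(i1 & j1) / len(i1)
    assert within > 0.6  # shared pool dominates
    assert across < 0.1


def test_group_density_ratio_emulates_study_design(default_study):
    cfg, ref, calls = default_study
    n_indica = np.mean([
        sum(r.vtype == "SNP" for r in calls[s]) for s in cfg.groups["indica"]
    ])
    n_japonica = np.mean([
        sum(r.vtype == "SNP" for r in calls[s]) for s in cfg.groups["japonica"]
    ])
    assert n_indica / n_japonica == pytest.approx(7.7 / 3.0, rel=0.15)


def test_truth_counts_match_emitted_records(default_study):
    cfg, ref, calls = default_study
    for sample, records in calls.items():
        truth = ref.truth.variants[sample]
        assert len(truth) == len(records)
        assert {(t.chromosome, t.pos1, t.ref, t.alt) for t in truth} == {
            (r.chromosome, r.pos1, r.ref, r.alt) for r in records
        }


def test_truth_report_files(tmp_path, default_study):
    cfg, ref, calls = default_study
    paths = truth_report(ref.truth, str(tmp_path))
    groups = dict(
        line.split("\t")
        for line in open(paths["groups"]).read().strip().splitlines()[1:]
    )
    assert groups == ref.truth.groups
    n_rows = len(open(paths["categories"]).readlines()) - 1
    assert n_rows == sum(len(v) for v in ref.truth.variants.values())
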