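"""End-to-end orchestration: filter -> densities -> deserts -> spectrum ->
effects -> outliers -> clustering, with every artifact written to disk and a
manifest reconciling record counts across stages."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .cluster import (
    cluster_samples,
    density_matrix,
    pearson_matrix,
    to_newick,
    write_correlation_tsv,
)
from .density import (
    DEFAULT_WINDOW,
    bin_counts,
    density_summary,
    write_track_bedgraph,
    write_track_tsv,
)
from .deserts import (
    DESERT_THRESHOLD_PER_KB,
    annotate_desert_genes,
    find_deserts,
    shared_deserts,
    write_deserts_bed,
    write_deserts_tsv,
)
from .effects import (
    DEFAULT_FLANK,
    annotate_all,
    build_gene_index,
    summarize_effects,
    write_effects_tsv,
    write_summary_tsv,
)
from .outliers import (
    find_outlier_genes,
    five_number_summary,
    gene_ns_density,
    write_outliers_tsv,
)
from .refmodels import load_gene_models, load_genome
from .spectrum import indel_lengths, spectrum, write_indel_hist_tsv, write_spectrum_tsv
from .variants import FilterThresholds, filter_variants, read_vcf, write_vcf

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    fasta: str
    gff3: str
    vcfs: dict[str, str]  # sample -> path
    outdir: str
    window_size: int = DEFAULT_WINDOW
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    flank_bp: int = DEFAULT_FLANK
    desert_threshold_per_kb: float = DESERT_THRESHOLD_PER_KB
    linkage_method: str = "average"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.window_size < 1000:
            raise ValueError("window_size must be >= 1000")
        missing = [
            p
            for p in [self.fasta, self.gff3, *self.vcfs.values()]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every sample; returns the manifest dict.

    Outputs land under config.outdir: per-sample filter reports, density
    tracks, desert BEDs, spectrum and effect-summary tables, outlier-gene
    tables; across samples a shared-desert BED, the correlation matrix and
    a Newick dendrogram.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "snpscape_version": __version__,
        "config_hash": _config_hash(config),
        "samples": {},
        "status": "running",
    }
    t0 = time.time()
    genome = load_genome(config.fasta)
    transcripts, gene_spans = load_gene_models(config.gff3, genome)
    index = build_gene_index(transcripts, gene_spans, flank_bp=config.flank_bp)
    log.info(
        "loaded %d chromosomes, %d transcripts, %d genes (%.1fs)",
        len(genome.chrom_names), len(transcripts), len(gene_spans), time.time() - t0,
    )

    snp_tracks = {}
    spectra, hists, summaries = [], [], []
    try:
        for sample, vcf_path in config.vcfs.items():
            t1 = time.time()
            sdir = out / sample
            sdir.mkdir(exist_ok=True)
            records = read_vcf(vcf_path, sample)
            kept, report = filter_variants(records, config.thresholds)
            (sdir / "filter_report.json").write_text(json.dumps(report.as_dict(), indent=1))
            write_vcf(
                kept, str(sdir / "filtered.vcf"), contigs=genome.chrom_lengths,
                provenance=f"snpscape {__version__} thresholds={config.thresholds}",
            )

            tracks = {}
            for vclass in ("SNP", "INS", "DEL"):
                tr = bin_counts(
                    kept, genome, config.window_size, vclass, sample_id=sample
                )
                tracks[vclass] = tr
                write_track_tsv(tr, str(sdir / f"density_{vclass}.tsv"))
                write_track_bedgraph(tr, str(sdir / f"density_{vclass}.bedgraph"))
            snp_tracks[sample] = tracks["SNP"]
            (sdir / "density_summary.json").write_text(
                json.dumps(density_summary(tracks["SNP"]), indent=1)
            )

            ds = find_deserts(tracks["SNP"], config.desert_threshold_per_kb)
            annotate_desert_genes(ds, gene_spans)
            write_deserts_bed(ds, str(sdir / "deserts.bed"))
            write_deserts_tsv(ds, str(sdir / "deserts.tsv"))

            spectra.append(spectrum(kept, sample_id=sample))
            hists.append(indel_lengths(kept, sample_id=sample))

            snp_effects, mismatches = annotate_all(
                (r for r in kept if r.vtype == "SNP"), index, genome
            )
            write_effects_tsv(snp_effects, str(sdir / "snp_effects.tsv"))
            summaries.append(summarize_effects(snp_effects, sample_id=sample))

            densities = gene_ns_density(snp_effects, gene_spans)
            outliers = []
            fence = None
            if len(densities) >= 4:
                fns = five_number_summary([g.density for g in densities])
                fence = fns.upper_fence
                outliers = find_outlier_genes(densities, fns)
            write_outliers_tsv(outliers, str(sdir / "outlier_genes.tsv"))

            manifest["samples"][sample] = {
                "n_input": report.n_input,
                "n_kept": report.n_kept,
                "n_rejected": report.n_rejected,
                "n_snp_effects": len(snp_effects),
                "n_ref_mismatches": int(sum(mismatches.values())),
                "n_deserts": len(ds),
                "n_outlier_genes": len(outliers),
                "outlier_fence": fence,
                "seconds": round(time.time() - t1, 3),
            }
            log.info("sample %s done in %.1fs", sample, time.time() - t1)

        write_spectrum_tsv(spectra, str(out / "spectrum.tsv"))
        write_indel_hist_tsv(hists, str(out / "indel_lengths.tsv"))
        write_summary_tsv(summaries, str(out / "effect_summary.tsv"))

        per_sample_deserts = {
            s: find_deserts(t, config.desert_threshold_per_kb)
            for s, t in snp_tracks.items()
        }
        if len(per_sample_deserts) >= 2:
            shared = shared_deserts(per_sample_deserts, window_size=config.window_size)
            annotate_desert_genes(shared, gene_spans)
            write_deserts_bed(shared, str(out / "shared_deserts.bed"))
            manifest["n_shared_deserts"] = len(shared)

        if len(snp_tracks) >= 2:
            try:
                dm = density_matrix(snp_tracks)
                corr = pearson_matrix(dm)
                cluster_samples(corr, method=config.linkage_method)
                write_correlation_tsv(corr, str(out / "correlation.tsv"))
                (out / "dendrogram.nwk").write_text(to_newick(corr) + "\n")
            except ValueError as exc:
                # e.g. a variant-free sample has zero variance across windows
                manifest["correlation"] = f"skipped: {exc}"
                log.warning("correlation stage skipped: %s", exc)

        manifest["status"] = "ok"
    except Exception as exc:  # partial outputs retained, failure recorded
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    manifest["seconds_total"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
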