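"""VCF reading, biallelic normalization and quality filtering.

The filter reproduces a VarScan-style qualification: minimum mean mapping
quality 20, read depth 10, average base quality 30, and variant allele
frequency 0.1 for SNPs / 0.3 for InDels, all as inclusive (>=) thresholds.
Criteria whose annotation is absent from a record are skipped, not failed,
and the skip is tallied so heterogeneous caller dialects stay visible.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from cyvcf2 import VCF

VALID_BASES = set("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """One normalized biallelic variant (positions are 1-based as in VCF)."""

    sample_id: str
    chromosome: str
    pos1: int
    ref: str
    alt: str
    vtype: str  # SNP | INS | DEL | OTHER
    mapq: Optional[float] = None
    depth: Optional[float] = None
    base_qual: Optional[float] = None
    vaf: Optional[float] = None

    @property
    def pos0(self) -> int:
        return self.pos1 - 1

    @property
    def indel_length(self) -> int:
        """Signed length change: positive insertion, negative deletion."""
        return len(self.alt) - len(self.ref)


def classify_alleles(ref: str, alt: str) -> str:
    """SNP/INS/DEL by the prefix rule; anything else (MNPs, symbolic) is OTHER."""
    if alt.startswith("<") or "[" in alt or "]" in alt or "." in alt:
        return "OTHER"
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    if len(alt) > len(ref) and alt.startswith(ref):
        return "INS"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "DEL"
    return "OTHER"


@dataclass(frozen=True)
class FilterThresholds:
    min_mapq: float = 20.0
    min_depth: float = 10.0
    min_base_qual: float = 30.0
    min_vaf_snp: float = 0.1
    min_vaf_indel: float = 0.3


#: INFO/FORMAT tag names probed for each quality annotation, in order.
DEFAULT_TAGS = {
    "depth": ("DP", "ADP"),
    "mapq": ("MQ", "MAPQ"),
    "base_qual": ("ABQ", "BQ"),
    "vaf": ("FREQ", "AF", "VAF"),
}


def _parse_freq(value) -> Optional[float]:
    """VarScan formats FREQ as a percent string ('12.5%'); others use fractions."""
    if value is None:
        return None
    if isinstance(value, bytes):
        value = value.decode()
    if isinstance(value, str):
        value = value.strip()
        is_pct = value.endswith("%")
        try:
            v = float(value.rstrip("%"))
        except ValueError:
            return None
        return v / 100.0 if is_pct or v > 1.0 else v
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    return v / 100.0 if v > 1.0 else v


def _scalar(value, alt_index: int):
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        if len(value) == 0:
            return None
        return value[alt_index] if alt_index < len(value) else value[0]
    return value


def _lookup(variant, tags: tuple[str, ...], alt_index: int):
    for tag in tags:
        if tag in dict(variant.INFO):
            return _scalar(variant.INFO.get(tag), alt_index)
        try:
            arr = variant.format(tag)
        except KeyError:
            arr = None
        if arr is not None and len(arr) > 0:
            v = arr[0]
            if hasattr(v, "__len__") and not isinstance(v, (str, bytes)):
                v = v[0] if len(v) > 0 else None
            return v
    return None


def read_vcf(path: str, sample_id: str, tags: dict | None = None) -> list[VariantRecord]:
    """Read a VCF, decomposing multi-allelic rows into one record per ALT.

    Records come back sorted by (chromosome, pos1); unsorted input is sorted
    with a warning. Malformed rows (empty/identical alleles, non-positive
    position) are skipped with a warning and counted.
    """
    tags = {**DEFAULT_TAGS, **(tags or {})}
    records: list[VariantRecord] = []
    skipped = 0
    vcf = VCF(str(path))
    try:
        for v in vcf:
            ref = (v.REF or "").upper()
            if not ref or v.POS < 1:
                skipped += 1
                continue
            for i, alt in enumerate(v.ALT):
                alt = (alt or "").upper()
                if not alt or alt == ref:
                    skipped += 1
                    continue
                vtype = classify_alleles(ref, alt)
                mapq = _lookup(v, tags["mapq"], i)
                depth = _lookup(v, tags["depth"], i)
                bq = _lookup(v, tags["base_qual"], i)
                vaf = _parse_freq(_lookup(v, tags["vaf"], i))
                records.append(
                    VariantRecord(
                        sample_id=sample_id,
                        chromosome=v.CHROM,
                        pos1=v.POS,
                        ref=ref,
                        alt=alt,
                        vtype=vtype,
                        mapq=float(mapq) if mapq is not None else None,
                        depth=float(depth) if depth is not None else None,
                        base_qual=float(bq) if bq is not None else None,
                        vaf=vaf,
                    )
                )
    finally:
        vcf.close()
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} malformed record(s)")
    key = lambda r: (r.chromosome, r.pos1)
    if any(key(a) > key(b) for a, b in zip(records, records[1:])):
        warnings.warn(f"{path}: records out of order; sorting")
    records.sort(key=key)
    return records


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    n_rejected: int = 0
    reasons: Counter = field(default_factory=Counter)
    skipped_criteria: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_rejected": self.n_rejected,
            "reasons": dict(self.reasons),
            "skipped_criteria": dict(self.skipped_criteria),
        }


def filter_variants(
    records: Iterable[VariantRecord], thresholds: FilterThresholds = FilterThresholds()
) -> tuple[list[VariantRecord], FilterReport]:
    """Keep records passing every available criterion (inclusive >= comparisons).

    OTHER-type records are always rejected ('unsupported_type'). Every failing
    criterion of a rejected record is tallied; the kept/rejected partition is
    exact and the filter is idempotent.
    """
    report = FilterReport()
    kept: list[VariantRecord] = []
    th = thresholds
    for r in records:
        report.n_input += 1
        if r.vtype == "OTHER":
            report.n_rejected += 1
            report.reasons["unsupported_type"] += 1
            continue
        failures = []
        min_vaf = th.min_vaf_snp if r.vtype == "SNP" else th.min_vaf_indel
        for name, value, cutoff in (
            ("mapq", r.mapq, th.min_mapq),
            ("depth", r.depth, th.min_depth),
            ("base_qual", r.base_qual, th.min_base_qual),
            ("vaf", r.vaf, min_vaf),
        ):
            if value is None:
                report.skipped_criteria[name] += 1
            elif value < cutoff:
                failures.append(name)
        if failures:
            report.n_rejected += 1
            for name in failures:
                report.reasons[name] += 1
        else:
            report.n_kept += 1
            kept.append(r)
    return kept, report


VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mean mapping quality">
##INFO=<ID=ABQ,Number=1,Type=Float,Description="Average base quality">
##INFO=<ID=FREQ,Number=1,Type=String,Description="Variant allele frequency">
"""


def write_vcf(
    records: Iterable[VariantRecord],
    path: str,
    contigs: dict[str, int] | None = None,
    provenance: str | None = None,
) -> None:
    """Write records back out as a minimal single-column VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        if provenance:
            fh.write(f"##snpscape_filter={provenance}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            info = []
            if r.depth is not None:
                info.append(f"DP={int(r.depth)}")
            if r.mapq is not None:
                info.append(f"MQ={r.mapq:g}")
            if r.base_qual is not None:
                info.append(f"ABQ={r.base_qual:g}")
            if r.vaf is not None:
                info.append(f"FREQ={100 * r.vaf:.2f}%")
            fh.write(
                f"{r.chromosome}\t{r.pos1}\t.\t{r.ref}\t{r.alt}\t.\t.\t"
                f"{';'.join(info) or '.'}\n"
            )
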