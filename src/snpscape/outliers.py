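"""Outlier genes by the box-and-whisker upper fence.

Per-gene nonsynonymous SNP density (nsSNPs per kb of CDS union) is
summarized by Tukey's five-number summary; genes strictly above the upper
fence Q3 + 1.5*IQR are flagged. Hinges are medians of the lower/upper half,
the halves including the overall median when n is odd.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .effects import EffectRecord
from .refmodels import GeneSpan


@dataclass
class GeneNsDensity:
    gene_id: str
    nssnp_count: int
    cds_union_length: int  # bp
    density: float  # nsSNPs per kb of CDS union


def gene_ns_density(
    effects: Iterable[EffectRecord],
    gene_spans: Sequence[GeneSpan],
    length_from: str = "cds_union",
) -> list[GeneNsDensity]:
    """Per-gene nonsynonymous density for every gene with coding sequence.

    Genes with zero nsSNPs are retained at density 0; genes without CDS are
    excluded. ``length_from='span'`` uses the full gene span as denominator
    instead of the CDS union.
    """
    ns_counts: Counter = Counter(
        e.gene_id for e in effects if e.category == "cds_nonsynonymous"
    )
    out = []
    for g in gene_spans:
        length = (
            g.cds_union_length if length_from == "cds_union" else g.span[1] - g.span[0]
        )
        if length <= 0:
            continue
        n = ns_counts.get(g.gene_id, 0)
        out.append(
            GeneNsDensity(
                gene_id=g.gene_id,
                nssnp_count=n,
                cds_union_length=g.cds_union_length,
                density=n / (length / 1000.0),
            )
        )
    return out


@dataclass
class FiveNumberSummary:
    min: float
    q1: float
    median: float
    q3: float
    max: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def upper_fence(self) -> float:
        return self.q3 + 1.5 * self.iqr


def _median(sorted_vals: Sequence[float]) -> float:
    n = len(sorted_vals)
    mid = n // 2
    if n % 2:
        return float(sorted_vals[mid])
    return (sorted_vals[mid - 1] + sorted_vals[mid]) / 2.0


def five_number_summary(values: Sequence[float]) -> FiveNumberSummary:
    """Tukey hinges: halves include the median when n is odd."""
    if len(values) < 4:
        raise ValueError("need at least 4 values for a five-number summary")
    vals = sorted(float(v) for v in values)
    n = len(vals)
    half = (n + 1) // 2  # lower half includes the median for odd n
    return FiveNumberSummary(
        min=vals[0],
        q1=_median(vals[:half]),
        median=_median(vals),
        q3=_median(vals[n - half :]),
        max=vals[-1],
    )


def find_outlier_genes(
    densities: Sequence[GeneNsDensity], summary: FiveNumberSummary
) -> list[GeneNsDensity]:
    """Genes strictly above the upper fence, sorted descending by density.

    One-sided: the fence value itself is the whisker end, not an outlier,
    and low-density genes are never flagged.
    """
    out = [g for g in densities if g.density > summary.upper_fence]
    out.sort(key=lambda g: (-g.density, g.gene_id))
    return out


def write_outliers_tsv(outliers: Sequence[GeneNsDensity], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tnssnp_count\tcds_kb\tdensity_per_kb\n")
        for g in outliers:
            fh.write(
                f"{g.gene_id}\t{g.nssnp_count}\t{g.cds_union_length / 1000:.3f}\t"
                f"{g.density:.4f}\n"
            )
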