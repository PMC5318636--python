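"""SNP-desert detection: maximal runs of windows under 1 SNP/kb.

A window qualifies when its count is strictly below threshold_per_kb times
its true length in kb (the last, possibly partial, window uses its real
length). Maximal runs of qualifying windows become desert intervals; shared
deserts across samples are the base-pair intersection of everyone's deserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .density import DensityTrack
from .refmodels import GeneSpan

DESERT_THRESHOLD_PER_KB = 1.0


@dataclass
class DesertInterval:
    sample_id: str  # or "shared"
    chromosome: str
    start0: int
    end0: int
    n_windows: int = 0
    genes_within: int | None = None
    sub_window: bool = False

    @property
    def size_bp(self) -> int:
        return self.end0 - self.start0


def find_deserts(
    track: DensityTrack, threshold_per_kb: float = DESERT_THRESHOLD_PER_KB
) -> list[DesertInterval]:
    """Maximal runs of low-SNP windows on each chromosome.

    Only defined on SNP tracks; the qualifying test is strict (<).
    """
    if track.variant_class != "SNP":
        raise ValueError("deserts are defined on SNP tracks only")
    deserts: list[DesertInterval] = []
    for chrom, counts in track.counts.items():
        run_start = None
        n = len(counts)
        for i in range(n + 1):
            qualifies = False
            if i < n:
                wlen = track.window_length(chrom, i)
                qualifies = counts[i] < threshold_per_kb * (wlen / 1000.0)
            if qualifies and run_start is None:
                run_start = i
            elif not qualifies and run_start is not None:
                s = run_start * track.window_size
                e = min(i * track.window_size, track.chrom_lengths[chrom])
                deserts.append(
                    DesertInterval(
                        sample_id=track.sample_id,
                        chromosome=chrom,
                        start0=s,
                        end0=e,
                        n_windows=i - run_start,
                    )
                )
                run_start = None
    return deserts


def _intersect(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out, i, j = [], 0, 0
    a, b = sorted(a), sorted(b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def shared_deserts(
    per_sample: dict[str, list[DesertInterval]], window_size: int | None = None
) -> list[DesertInterval]:
    """Base-pair intersection of all samples' deserts, as maximal intervals.

    Symmetric in sample order; intervals narrower than one window are kept
    but flagged sub_window.
    """
    if not per_sample:
        raise ValueError("no samples given")
    chroms = {d.chromosome for ds in per_sample.values() for d in ds}
    out: list[DesertInterval] = []
    for chrom in sorted(chroms):
        current: list[tuple[int, int]] | None = None
        for sample in per_sample:
            ivs = [
                (d.start0, d.end0) for d in per_sample[sample] if d.chromosome == chrom
            ]
            current = ivs if current is None else _intersect(current, ivs)
            if not current:
                break
        for s, e in current or []:
            out.append(
                DesertInterval(
                    sample_id="shared",
                    chromosome=chrom,
                    start0=s,
                    end0=e,
                    sub_window=bool(window_size and (e - s) < window_size),
                )
            )
    return out


def annotate_desert_genes(
    deserts: list[DesertInterval], gene_spans: list[GeneSpan]
) -> list[DesertInterval]:
    """Fill genes_within: gene spans fully contained in each desert interval."""
    by_chrom: dict[str, list[GeneSpan]] = {}
    for g in gene_spans:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for d in deserts:
        d.genes_within = sum(
            1
            for g in by_chrom.get(d.chromosome, [])
            if d.start0 <= g.span[0] and g.span[1] <= d.end0
        )
    return deserts


def write_deserts_bed(deserts: list[DesertInterval], path: str) -> None:
    with open(path, "w") as fh:
        for d in sorted(deserts, key=lambda d: (d.chromosome, d.start0)):
            fh.write(f"{d.chromosome}\t{d.start0}\t{d.end0}\t{d.sample_id}\n")


def write_deserts_tsv(deserts: list[DesertInterval], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart0\tend0\tsize_bp\tn_windows\tgenes_within\n")
        for d in sorted(deserts, key=lambda d: (d.chromosome, d.start0)):
            gw = "" if d.genes_within is None else d.genes_within
            fh.write(
                f"{d.sample_id}\t{d.chromosome}\t{d.start0}\t{d.end0}\t"
                f"{d.size_bp}\t{d.n_windows}\t{gw}\n"
            )
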