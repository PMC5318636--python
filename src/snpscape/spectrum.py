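"""Base-change spectrum, Ts/Tv ratio and InDel length summaries.

Base changes are counted as the six unordered pairs: the two transitions
{A,G} and {C,T} (purine-purine / pyrimidine-pyrimidine) and the four
transversions {A,C}, {A,T}, {C,G}, {G,T}. The Ts/Tv ratio is the transition
count over the transversion count; values above 0.5 indicate transition
bias relative to the random expectation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

from .variants import VariantRecord

TRANSITIONS = (("A", "G"), ("C", "T"))
TRANSVERSIONS = (("A", "C"), ("A", "T"), ("C", "G"), ("G", "T"))
PAIRS = TRANSITIONS + TRANSVERSIONS


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (2.3645 -> 2.365 at 3 digits), as tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def classify_base_change(ref_base: str, alt_base: str) -> tuple[str, tuple[str, str]]:
    """Return ("transition"|"transversion", unordered pair) for a substitution.

    Raises ValueError on N or IUPAC ambiguity codes so callers can tally
    unclassifiable sites.
    """
    pair = tuple(sorted((ref_base.upper(), alt_base.upper())))
    if pair in TRANSITIONS:
        return "transition", pair
    if pair in TRANSVERSIONS:
        return "transversion", pair
    raise ValueError(f"unclassifiable base change {ref_base}->{alt_base}")


@dataclass
class SpectrumTable:
    sample_id: str
    counts: dict[tuple[str, str], int] = field(
        default_factory=lambda: {p: 0 for p in PAIRS}
    )
    n_unclassified: int = 0

    @property
    def ts_total(self) -> int:
        return sum(self.counts[p] for p in TRANSITIONS)

    @property
    def tv_total(self) -> int:
        return sum(self.counts[p] for p in TRANSVERSIONS)

    @property
    def ts_tv_ratio(self) -> Optional[float]:
        """None when no transversions were observed (undefined, not infinity)."""
        if self.tv_total == 0:
            return None
        return self.ts_total / self.tv_total

    @property
    def ts_tv_3dp(self) -> Optional[float]:
        r = self.ts_tv_ratio
        return None if r is None else round_half_up(r, 3)

    @classmethod
    def from_counts(
        cls, sample_id: str, counts: dict[tuple[str, str], int]
    ) -> "SpectrumTable":
        """Build a table directly from the six unordered-pair counts."""
        table = cls(sample_id=sample_id)
        for pair, n in counts.items():
            key = tuple(sorted(pair))
            if key not in table.counts:
                raise ValueError(f"not a base-change pair: {pair}")
            table.counts[key] += int(n)
        return table


def spectrum(records: Iterable[VariantRecord], sample_id: str | None = None) -> SpectrumTable:
    """Tally the base-change spectrum of filtered SNP records."""
    table = SpectrumTable(sample_id=sample_id or "")
    for r in records:
        if r.vtype != "SNP":
            continue
        if not table.sample_id:
            table.sample_id = r.sample_id
        try:
            _, pair = classify_base_change(r.ref, r.alt)
        except ValueError:
            table.n_unclassified += 1
            continue
        table.counts[pair] += 1
    return table


@dataclass
class IndelLengthHistogram:
    sample_id: str
    counts: Counter = field(default_factory=Counter)  # signed length -> count

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def max_insertion(self) -> int:
        ins = [k for k in self.counts if k > 0]
        return max(ins) if ins else 0

    @property
    def max_deletion(self) -> int:
        dels = [-k for k in self.counts if k < 0]
        return max(dels) if dels else 0

    def fraction_of_length(self, abs_len: int) -> float:
        if self.total == 0:
            return 0.0
        return (self.counts.get(abs_len, 0) + self.counts.get(-abs_len, 0)) / self.total

    @property
    def fraction_mono(self) -> float:
        return self.fraction_of_length(1)

    @property
    def fraction_di(self) -> float:
        return self.fraction_of_length(2)


def indel_lengths(
    records: Iterable[VariantRecord], sample_id: str | None = None
) -> IndelLengthHistogram:
    """Signed length histogram of filtered insertions (+) and deletions (−)."""
    hist = IndelLengthHistogram(sample_id=sample_id or "")
    for r in records:
        if r.vtype not in ("INS", "DEL"):
            continue
        if not hist.sample_id:
            hist.sample_id = r.sample_id
        hist.counts[r.indel_length] += 1
    return hist


def write_spectrum_tsv(tables: list[SpectrumTable], path: str) -> None:
    cols = ["/".join(p) for p in PAIRS]
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(cols) + "\tts_total\ttv_total\tts_tv\n")
        for t in tables:
            ratio = "NA" if t.ts_tv_3dp is None else f"{t.ts_tv_3dp:.3f}"
            fh.write(
                t.sample_id
                + "\t"
                + "\t".join(str(t.counts[p]) for p in PAIRS)
                + f"\t{t.ts_total}\t{t.tv_total}\t{ratio}\n"
            )


def write_indel_hist_tsv(hists: list[IndelLengthHistogram], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tlength\tcount\n")
        for h in hists:
            for length in sorted(h.counts):
                fh.write(f"{h.sample_id}\t{length}\t{h.counts[length]}\n")
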