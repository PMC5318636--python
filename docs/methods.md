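# Methods

## Coordinates and I/O

All internal coordinates are 0-based half-open. VCF (1-based) and GFF3
(1-based inclusive) are converted at the I/O boundary; density tracks,
desert intervals and BED exports are 0-based half-open throughout.
Multi-allelic VCF rows are decomposed into one biallelic record per ALT;
variant type follows the prefix rule (SNP for 1/1, INS when REF is a
prefix of a longer ALT, DEL for the converse, everything else OTHER —
MNPs, symbolic alleles and breakends are not analysed). VarScan-style
percent frequency strings ("12.50%") are parsed to fractions.

## Qualification filter

A record is kept iff every *available* criterion passes with an inclusive
comparison: mapping quality ≥ 20, depth ≥ 10, mean base quality ≥ 30, and
allele frequency ≥ 0.1 (SNPs) or ≥ 0.3 (InDels). "Quality of 20" is read
as the minimum acceptable value, matching the `--min-*` semantics of the
callers these thresholds come from; treating the thresholds as strict
would shift boundary counts by the mass at exactly the cutoff. Records
lacking an annotation skip that criterion rather than fail it — VCFs from
different callers carry different tags — and skips are tallied in the
filter report so silent leniency is visible. The filter partitions its
input exactly and is idempotent and order-independent.

## Density tracks and deserts

Variants are counted in non-overlapping windows (default 100 kb; the
window size is a parameter with a 1-kb floor). A variant at 1-based
position p belongs to window ⌊(p−1)/w⌋; InDels are anchored at the first
REF base. The final partial window is kept and weighted by its true
length in per-kb summaries — dropping it would delete telomeric variants.

A window is desert-qualifying when its SNP count is strictly below
1 SNP/kb × its true length (strict "<", so a window at exactly the
threshold does not qualify). Maximal runs of qualifying windows are
reported per sample; runs never cross chromosomes, and no merging across
single high windows is performed. Shared deserts are the exact base-pair
intersection of all samples' desert sets, reported as maximal intervals;
on a common window grid these stay window-aligned, and a `sub_window`
flag covers future variable grids. Gene content of a desert counts gene
spans *fully contained* in the interval.

## Base-change spectrum

Substitutions are tallied as six unordered pairs — transitions {A,G} and
{C,T}, transversions {A,C}, {A,T}, {C,G}, {G,T} — so G→A and A→G fall in
one class; strand-collapsing to 12 classes is deliberately not done, as
the six-class table is what resequencing studies print. Ts/Tv is
undefined (reported NA, not infinity) when no transversions exist. Table
exports round half-up to 3 decimals (ratios) and 2 decimals
(percentages), matching how such tables are conventionally printed; the
underlying floats are never rounded internally.

## Effect annotation

A gene index (interval tree per chromosome) stores each gene's span
extended by a regulatory flank, default 5,000 bp per side, oriented by
strand into upstream/downstream. The default follows the most widespread
annotation convention; the flank is a parameter because "regulatory
sequence" has no single accepted width.

Each variant yields one effect record per overlapping gene — so
overlapping gene models produce more effect records than variants, the
over-counting that genic/intergenic summary tables conventionally show —
or a single intergenic record when nothing overlaps. Within a gene the
category is the most severe across its transcripts, with severity
cds (nonsynonymous = indel > synonymous > unclassified) > UTR > intron >
regulatory; ties between transcripts break lexicographically by
transcript id for determinism. Splice sites are not a separate category;
stop gain/loss counts as nonsynonymous (the summary is binary).

CDS SNPs are classified by assembling the spliced coding sequence in
transcription order (reverse-complemented on −), locating the variant's
offset, substituting the (complemented) alternate base and translating
the affected codon with the standard genetic code. Transcripts whose CDS
length is not a positive multiple of 3 are retained but flagged
incomplete, and their CDS variants are emitted as `cds_unclassified`
rather than silently dropped — real GFF dialects contain partial models,
and dropping them would bias category counts. GFF3 phase is trusted for
the first CDS segment (default 0 per the standard); positions inside a
leading partial codon, codons containing N, and truncated terminal codons
are unclassifiable. A REF allele disagreeing with the reference sequence
is tallied but still classified positionally.

## Outlier genes

Per-gene nonsynonymous density is nsSNP count per kb of the gene's CDS
*union* (shared exonic bases across transcripts counted once); the full
gene span is available as an alternative denominator. The five-number
summary uses Tukey hinges — medians of the lower/upper halves, halves
including the overall median when n is odd — because the procedure is
defined by the box-and-whisker plot; interpolated quantiles are a
configurable alternative that differs at small n. Outliers are strictly
above the upper fence Q3 + 1.5·IQR (the fence is the whisker end, not an
outlier), one-sided by construction. At least 4 genes are required.

## Correlation and clustering

The windows × samples count matrix concatenates all chromosomes on a
common grid (genome scope; per-chromosome matrices are also available,
since density correlations are sometimes inspected chromosome by
chromosome). All-zero windows are retained — shared deserts are signal.
Pearson r is computed on raw counts (log1p is a config option); a sample
with zero variance across windows is an error naming the sample.
Clustering is agglomerative on d = 1 − r with average linkage (UPGMA);
single/complete linkage are options. Samples are processed in
lexicographic name order so ties break deterministically, and permuting
the input order yields an identical Newick string. Branch lengths derive
from merge heights.

## Synthetic studies

The generator emulates the statistical structure of a two-subspecies
resequencing panel, with defaults chosen as that design's conditions:

| parameter | default | meaning |
|---|---|---|
| group SNP rates | 7.7 / 3.0 per kb | ≈2.5× density ratio between groups |
| group InDel rates | 1.1 / 0.45 per kb | ≈1/7 of the SNP rate, same ratio |
| shared fraction | 0.8 | of a group's rate drawn from a common pool |
| p_transition | 0.70 | expected Ts/Tv = 7/3 ≈ 2.33 |
| p_deletion | 0.55 | deletions slightly outnumber insertions |
| InDel lengths | geometric, p = 0.55 | mononucleotide majority |
| desert | chr1:300–500 kb, ×0.02 | planted low-rate interval |
| hot genes | 4 (of 40), ×8 in CDS | nsSNP-dense outlier genes |
| failing records | 5% | exercise the filter report |

Positions follow a Poisson process with a piecewise-constant rate:
thinned by the desert multiplier, amplified inside hot genes' CDS.
Alternate alleles are a transition with probability 0.70, else one of the
two transversions uniformly. Gene models are placed non-overlapping on
alternating strands with ≥10.5 kb spacing so regulatory flanks never
overlap a neighbour and every locus has exactly one gene context; each
CDS starts ATG, ends with a stop, and translates without internal stops.
Every planted variant carries a truth category computed under the same
coordinate rules the annotator uses. Determinism is per-substream: the
shared pool is keyed by (seed, group), private draws by (seed, sample),
so adding a sample never perturbs the others.

Not emulated: linkage disequilibrium, non-uniform base composition,
mutation-rate heterogeneity beyond the planted intervals, sequencing
error, genotype likelihoods, multi-allelic sites, and overlapping gene
models. Tests passing on these simulations therefore demonstrate the
correctness of the coordinate and counting machinery and the
recoverability of planted structure — not robustness to every property
of real resequencing data (real VCFs bring overlapping gene models and
ambiguous bases, which the annotator handles but the simulator does not
generate).

## Problem sizes and tolerances

The default synthetic study is 2 × 1 Mb chromosomes with 40 genes and
five samples (~26 k kept variants) — large enough that every recovery
statistic has tight sampling error, small enough for interactive runs.
Rate and proportion recoveries are asserted within 3 standard errors
(delta method for the Ts/Tv ratio); planted-desert recovery at Jaccard
≥ 0.8; group bipartition over 50 seeds at ≥ 49 correct; hot-gene recall
at ≥ 80% on one 6.1-Mb/500-gene sample. The oracle checks (codon
classifier vs whole-protein re-translation; desert scan vs exhaustive
run enumeration) assert exact agreement. Pearson r agrees with the
textbook formula to 1e-12; numerical correlation output is clipped to
[−1, 1] before clustering.
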