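"""Sample correlation and clustering on windowed SNP densities.

The sample x sample Pearson correlation of per-window SNP counts separates
diverged groups (within-group r near one, between-group r near zero);
agglomerative clustering on distance d = 1 - r with average linkage (UPGMA)
turns that into a dendrogram whose first split is the group bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .density import DensityTrack


@dataclass
class DensityMatrix:
    samples: list[str]
    windows: list[tuple[str, int]]  # (chromosome, window index)
    matrix: np.ndarray  # windows x samples, counts


@dataclass
class CorrelationResult:
    samples: list[str]
    matrix: np.ndarray  # samples x samples Pearson r
    linkage: np.ndarray | None = None  # scipy linkage over lexicographic order
    leaf_order: list[str] | None = None


def density_matrix(tracks: dict[str, DensityTrack]) -> DensityMatrix:
    """Stack per-sample window counts into one windows x samples matrix.

    All tracks must share the genome grid (same chromosomes, lengths and
    window size); a mismatch is fatal.
    """
    if not tracks:
        raise ValueError("no tracks given")
    samples = list(tracks)
    first = tracks[samples[0]]
    for s in samples[1:]:
        t = tracks[s]
        if (
            t.window_size != first.window_size
            or t.chrom_lengths != first.chrom_lengths
            or list(t.counts) != list(first.counts)
        ):
            raise ValueError(f"track {s} is on a different window grid")
    windows = [
        (chrom, i) for chrom in first.counts for i in range(len(first.counts[chrom]))
    ]
    matrix = np.column_stack(
        [
            np.concatenate([tracks[s].counts[chrom] for chrom in first.counts])
            for s in samples
        ]
    ).astype(float)
    return DensityMatrix(samples=samples, windows=windows, matrix=matrix)


def pearson_matrix(
    m: DensityMatrix, scope: str = "genome"
) -> CorrelationResult | dict[str, CorrelationResult]:
    """Pearson r between samples over window counts.

    scope='genome' correlates concatenated windows; scope='per_chromosome'
    returns one CorrelationResult per chromosome. A sample with zero
    variance across windows is an error naming the sample.
    """
    if scope == "per_chromosome":
        out = {}
        for chrom in {c for c, _ in m.windows}:
            rows = [i for i, (c, _) in enumerate(m.windows) if c == chrom]
            sub = DensityMatrix(
                samples=m.samples,
                windows=[m.windows[i] for i in rows],
                matrix=m.matrix[rows, :],
            )
            out[chrom] = pearson_matrix(sub, scope="genome")
        return out
    if m.matrix.shape[0] < 2:
        raise ValueError("need at least 2 windows")
    sd = m.matrix.std(axis=0)
    for name, s in zip(m.samples, sd):
        if s == 0:
            raise ValueError(f"sample {name} has zero variance across windows")
    corr = np.corrcoef(m.matrix, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationResult(samples=list(m.samples), matrix=corr)


def cluster_samples(result: CorrelationResult, method: str = "average") -> CorrelationResult:
    """Agglomerative clustering on d = 1 - r; fills linkage and leaf order.

    Samples are processed in lexicographic name order so ties break
    deterministically regardless of input order.
    """
    corr = result.matrix
    if not np.allclose(corr, corr.T):
        raise ValueError("correlation matrix is not symmetric")
    order = sorted(range(len(result.samples)), key=lambda i: result.samples[i])
    names = [result.samples[i] for i in order]
    d = 1.0 - corr[np.ix_(order, order)]
    np.fill_diagonal(d, 0.0)
    condensed = d[np.triu_indices(len(names), k=1)]
    Z = hierarchy.linkage(condensed, method=method)
    leaves = hierarchy.leaves_list(Z)
    result.linkage = Z
    result.leaf_order = [names[i] for i in leaves]
    result._linkage_names = names  # type: ignore[attr-defined]
    return result


def to_newick(result: CorrelationResult) -> str:
    """Dendrogram as a Newick string with branch lengths from merge heights."""
    if result.linkage is None:
        raise ValueError("call cluster_samples first")
    names = getattr(result, "_linkage_names", sorted(result.samples))
    tree = hierarchy.to_tree(result.linkage)

    def walk(node, parent_height: float) -> str:
        blen = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{blen:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{blen:.6g}"

    return walk(tree, tree.dist) + ";"


def top_bipartition(result: CorrelationResult) -> tuple[set[str], set[str]]:
    """The two sample sets separated by the root of the dendrogram."""
    if result.linkage is None:
        raise ValueError("call cluster_samples first")
    names = getattr(result, "_linkage_names", sorted(result.samples))
    tree = hierarchy.to_tree(result.linkage)

    def leaves(node) -> set[str]:
        if node.is_leaf():
            return {names[node.id]}
        return leaves(node.left) | leaves(node.right)

    return leaves(tree.left), leaves(tree.right)


def write_correlation_tsv(result: CorrelationResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(result.samples) + "\n")
        for i, s in enumerate(result.samples):
            fh.write(s + "\t" + "\t".join(f"{v:.6f}" for v in result.matrix[i]) + "\n")
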