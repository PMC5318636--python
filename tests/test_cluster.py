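"""Density correlation matrix and sample clustering."""

import numpy as np
import pytest

from snpscape.cluster import (
    cluster_samples,
    density_matrix,
    pearson_matrix,
    to_newick,
    top_bipartition,
)
from snpscape.density import DensityTrack

from helpers import brute_force_pearson


def make_track(counts_by_chrom, sample="s", window=100_000):
    lengths = {c: window * len(v) for c, v in counts_by_chrom.items()}
    return DensityTrack(
        sample_id=sample,
        variant_class="SNP",
        window_size=window,
        chrom_lengths=lengths,
        counts={c: np.asarray(v, dtype=np.int64) for c, v in counts_by_chrom.items()},
    )


def test_matrix_shape_and_column_sums():
    tracks = {
        "a": make_track({"chr1": [1, 2, 3]}),
        "b": make_track({"chr1": [4, 5, 6]}, sample="b"),
    }
    m = density_matrix(tracks)
    assert m.matrix.shape == (3, 2)
    assert m.samples == ["a", "b"]
    assert m.matrix.sum(axis=0).tolist() == [6.0, 15.0]


def test_mismatched_grids_fatal():
    tracks = {
        "a": make_track({"chr1": [1, 2, 3]}),
        "b": make_track({"chr1": [1, 2]}, sample="b"),
    }
    with pytest.raises(ValueError):
        density_matrix(tracks)


def test_identical_and_opposed_tracks():
    x = [1, 5, 2, 8, 4]  # integer mean so the mirrored track stays integral
    neg = (2 * np.mean(x) - np.asarray(x)).tolist()
    m = density_matrix(
        {
            "a": make_track({"chr1": x}),
            "b": make_track({"chr1": x}, sample="b"),
            "c": make_track({"chr1": neg}, sample="c"),
        }
    )
    corr = pearson_matrix(m).matrix
    assert corr[0, 1] == pytest.approx(1.0)
    assert corr[0, 2] == pytest.approx(-1.0)


def test_zero_variance_sample_named_in_error():
    m = density_matrix(
        {
            "flatline": make_track({"chr1": [2, 2, 2]}),
            "b": make_track({"chr1": [1, 2, 3]}, sample="b"),
        }
    )
    with pytest.raises(ValueError, match="flatline"):
        pearson_matrix(m)


def test_matches_textbook_formula():
    rng = np.random.default_rng(13)
    a, b = rng.poisson(50, 40).astype(float), rng.poisson(50, 40).astype(float)
    m = density_matrix(
        {"a": make_track({"chr1": a}), "b": make_track({"chr1": b}, sample="b")}
    )
    corr = pearson_matrix(m).matrix
    assert corr[0, 1] == pytest.approx(brute_force_pearson(a, b), abs=1e-12)


def test_per_chromosome_scope():
    tracks = {
        "a": make_track({"chr1": [1, 2, 3], "chr2": [3, 1, 2]}),
        "b": make_track({"chr1": [1, 2, 3], "chr2": [1, 2, 3]}, sample="b"),
    }
    per_chrom = pearson_matrix(density_matrix(tracks), scope="per_chromosome")
    assert per_chrom["chr1"].matrix[0, 1] == pytest.approx(1.0)
    assert per_chrom["chr2"].matrix[0, 1] < 1.0


def test_two_samples_join_at_one_minus_r():
    rng = np.random.default_rng(14)
    a = rng.poisson(50, 30).astype(float)
    b = a + rng.normal(0, 5, 30)
    m = density_matrix(
        {"a": make_track({"chr1": a}), "b": make_track({"chr1": b}, sample="b")}
    )
    result = cluster_samples(pearson_matrix(m))
    assert result.linkage.shape == (1, 4)
    assert result.linkage[0, 2] == pytest.approx(1 - result.matrix[0, 1])
    nwk = to_newick(result)
    assert nwk.count(",") == 1 and nwk.endswith(";")


def test_block_structure_splits_groups_first():
    rng = np.random.default_rng(15)
    shared_g1 = rng.poisson(100, 50).astype(float)
    shared_g2 = rng.poisson(100, 50).astype(float)
    tracks = {}
    for name, base in [("a1", shared_g1), ("a2", shared_g1), ("b1", shared_g2), ("b2", shared_g2)]:
        noisy = base + rng.normal(0, 2, 50)
        tracks[name] = make_track({"chr1": noisy}, sample=name)
    result = cluster_samples(pearson_matrix(density_matrix(tracks)))
    left, right = top_bipartition(result)
    assert {frozenset(left), frozenset(right)} == {
        frozenset({"a1", "a2"}),
        frozenset({"b1", "b2"}),
    }


def test_sample_permutation_gives_isomorphic_tree():
    rng = np.random.default_rng(16)
    data = {n: rng.poisson(60, 40).astype(float) for n in "abcd"}
    tracks1 = {n: make_track({"chr1": data[n]}, sample=n) for n in "abcd"}
    tracks2 = {n: make_track({"chr1": data[n]}, sample=n) for n in "dcba"}
    r1 = cluster_samples(pearson_matrix(density_matrix(tracks1)))
    r2 = cluster_samples(pearson_matrix(density_matrix(tracks2)))
    assert to_newick(r1) == to_newick(r2)  # lexicographic processing order
    # correlation matrices are consistent under the permutation
    idx = [r2.samples.index(s) for s in r1.samples]
    assert np.allclose(r1.matrix, r2.matrix[np.ix_(idx, idx)])


def test_asymmetric_matrix_fatal():
    from snpscape.cluster import CorrelationResult

    bad = CorrelationResult(samples=["a", "b"], matrix=np.array([[1.0, 0.5], [0.2, 1.0]]))
    with pytest.raises(ValueError):
        cluster_samples(bad)
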