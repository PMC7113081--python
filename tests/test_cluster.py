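"""Fiber resampling, distances, spectral clustering, atlas assignment."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from dmrikit.cluster import (
    ClusterAtlas,
    assign_to_atlas,
    build_atlas_from_labels,
    cluster_fibers,
    fiber_distance,
    pairwise_distance_matrix,
    resample_streamline,
    spectral_embed,
)
from dmrikit.core import Tractogram
from dmrikit.phantom import synthetic_bundle_tractogram


def purity(labels, truth):
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    k = max(labels.max(), truth.max()) + 1
    C = np.zeros((k, k))
    for a, b in zip(labels, truth):
        C[a, b] += 1
    r, c = linear_sum_assignment(-C)
    return C[r, c].sum() / len(labels)


# ---------------------------------------------------------------------------
# resampling


def test_resample_straight_segment_equal_fractions():
    s = np.array([[0, 0, 0], [0, 0, 10.0]])
    out = resample_streamline(s, 5)
    assert np.allclose(out[:, 2], [0, 2.5, 5, 7.5, 10])


def test_resample_preserves_endpoints_and_uniform_identity(rng):
    s = np.cumsum(rng.uniform(-3, 3, size=(9, 3)), axis=0)
    out = resample_streamline(s, 30)
    assert np.allclose(out[0], s[0])
    assert np.allclose(out[-1], s[-1])
    # uniform arc-length spacing
    gaps = np.linalg.norm(np.diff(out, axis=0), axis=1)
    assert gaps.std() / gaps.mean() < 0.35  # chord spacing on a jagged line
    # an already-uniform polyline resampled at its own count is unchanged
    line = np.linspace([0, 0, 0], [12.0, 0, 0], 7)
    assert np.allclose(resample_streamline(line, 7), line, atol=1e-12)


def test_resample_degenerate():
    with pytest.raises(ValueError, match="degenerate streamline"):
        resample_streamline(np.zeros((3, 3)), 5)


# ---------------------------------------------------------------------------
# distances


def test_identical_fibers_zero_distance(rng):
    f = np.cumsum(rng.uniform(-2, 2, (15, 3)), axis=0)
    for metric in ("mdf", "mean_closest_point_sym"):
        assert fiber_distance(f, f, metric) == 0.0


def test_parallel_offset_fibers_distance():
    a = np.linspace([0, 0, 0], [30.0, 0, 0], 15)
    b = a + np.array([0, 3.0, 0])
    assert fiber_distance(a, b, "mdf") == pytest.approx(3.0)
    assert fiber_distance(a, b, "mean_closest_point_sym") == pytest.approx(3.0)


def test_mdf_flip_invariance(rng):
    f = np.cumsum(rng.uniform(-2, 2, (15, 3)), axis=0)
    assert fiber_distance(f, f[::-1], "mdf") == 0.0


def test_distance_size_mismatch():
    with pytest.raises(ValueError, match="feature size mismatch"):
        fiber_distance(np.zeros((5, 3)), np.zeros((7, 3)))


def test_pairwise_matrix_properties(rng):
    feats = [np.cumsum(rng.uniform(-2, 2, (10, 3)), axis=0) for _ in range(6)]
    M = pairwise_distance_matrix(feats, "mdf")
    assert M.shape == (6, 6)
    assert np.allclose(M, M.T)
    assert np.allclose(np.diag(M), 0.0)
    assert np.all(M >= 0)
    for i in range(6):
        for j in range(6):
            assert M[i, j] == pytest.approx(fiber_distance(feats[i], feats[j], "mdf"))


def test_pairwise_matrix_permutation_consistency(rng):
    feats = [np.cumsum(rng.uniform(-2, 2, (10, 3)), axis=0) for _ in range(5)]
    M = pairwise_distance_matrix(feats, "mdf")
    perm = [3, 1, 4, 0, 2]
    Mp = pairwise_distance_matrix([feats[i] for i in perm], "mdf")
    assert np.allclose(Mp, M[np.ix_(perm, perm)])


# ---------------------------------------------------------------------------
# embedding and clustering


def _bundled_features(rng_seed=0, n_bundles=2, fibers=20, sep=40.0):
    t, labels = synthetic_bundle_tractogram(
        n_bundles=n_bundles, fibers_per_bundle=fibers,
        separation_mm=sep, rng_seed=rng_seed,
    )
    feats = [resample_streamline(s, 15) for s in t.streamlines]
    return feats, labels


def test_embedding_separates_far_groups():
    feats, labels = _bundled_features()
    M = pairwise_distance_matrix(feats, "mdf")
    emb = spectral_embed(M, sigma_mm=30.0, dims=2)
    within = []
    between = []
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            d = np.linalg.norm(emb[i] - emb[j])
            (within if labels[i] == labels[j] else between).append(d)
    assert max(within) < min(between)


def test_embedding_duplicate_fiber_identical_rows():
    feats, _ = _bundled_features(fibers=5)
    feats.append(feats[0].copy())
    M = pairwise_distance_matrix(feats, "mdf")
    emb = spectral_embed(M, sigma_mm=30.0, dims=4)
    assert np.allclose(emb[0], emb[-1], atol=1e-8)


def test_embedding_deterministic():
    feats, _ = _bundled_features(fibers=8)
    M = pairwise_distance_matrix(feats, "mdf")
    e1 = spectral_embed(M, 30.0, 5)
    e2 = spectral_embed(M, 30.0, 5)
    assert np.array_equal(e1, e2)


def test_embedding_bad_bandwidth():
    with pytest.raises(ValueError, match="bad bandwidth"):
        spectral_embed(np.zeros((3, 3)), sigma_mm=0.0)


def test_two_bundle_clustering_pure():
    feats, labels = _bundled_features(fibers=50)
    M = pairwise_distance_matrix(feats, "mdf")
    emb = spectral_embed(M, 30.0, 10)
    pred = cluster_fibers(emb, 2, rng_seed=0)
    assert purity(pred, labels) == 1.0


def test_cluster_each_fiber_own_cluster():
    feats, _ = _bundled_features(fibers=3)
    M = pairwise_distance_matrix(feats, "mdf")
    emb = spectral_embed(M, 30.0, 6)
    pred = cluster_fibers(emb, len(feats), rng_seed=1)
    assert len(set(pred)) == len(feats)


def test_cluster_seed_reproducible_and_bad_k():
    feats, _ = _bundled_features(fibers=10)
    emb = spectral_embed(pairwise_distance_matrix(feats, "mdf"), 30.0, 5)
    a = cluster_fibers(emb, 2, rng_seed=5)
    b = cluster_fibers(emb, 2, rng_seed=5)
    assert np.array_equal(a, b)
    with pytest.raises(ValueError, match="bad k"):
        cluster_fibers(emb, 0)


def test_four_bundle_recovery_across_seeds():
    """End-to-end: 4 well-separated bundles recovered with purity >= 0.98
    for every clustering seed."""
    t, labels = synthetic_bundle_tractogram(
        n_bundles=4, fibers_per_bundle=50, separation_mm=30.0, rng_seed=11
    )
    feats = [resample_streamline(s, 15) for s in t.streamlines]
    M = pairwise_distance_matrix(feats, "mdf")
    emb = spectral_embed(M, 30.0, 10)
    for seed in range(10):
        pred = cluster_fibers(emb, 4, rng_seed=seed)
        assert purity(pred, labels) >= 0.98


# ---------------------------------------------------------------------------
# atlas


def _atlas_and_fibers(rng):
    t, labels = synthetic_bundle_tractogram(
        n_bundles=3, fibers_per_bundle=20, separation_mm=40.0, rng_seed=2
    )
    atlas = build_atlas_from_labels(t, labels, k_resample=15)
    return atlas, t, labels


def test_jittered_centroid_copies_assigned(rng):
    atlas, t, labels = _atlas_and_fibers(rng)
    jittered = []
    expect = []
    for lab, cent in atlas.centroids:
        for _ in range(10):
            jittered.append(cent + rng.uniform(-0.5, 0.5, size=cent.shape))
            expect.append(lab)
    tt = Tractogram(streamlines=jittered)
    got, dists, subs = assign_to_atlas(tt, atlas, reject_distance_mm=5.0)
    assert got == expect
    assert sum(len(s) for s in subs.values()) == len(jittered)


def test_far_fiber_unassigned(rng):
    atlas, t, labels = _atlas_and_fibers(rng)
    far = np.linspace([0, 0, 500.0], [60.0, 0, 500.0], 15)
    got, dists, subs = assign_to_atlas(Tractogram(streamlines=[far]), atlas, 5.0)
    assert got == ["unassigned"]
    assert subs == {}


def test_assignment_flip_invariant(rng):
    atlas, t, labels = _atlas_and_fibers(rng)
    sl = t.streamlines[:10]
    a1, _, _ = assign_to_atlas(Tractogram(streamlines=sl), atlas, 10.0)
    a2, _, _ = assign_to_atlas(
        Tractogram(streamlines=[s[::-1] for s in sl]), atlas, 10.0
    )
    assert a1 == a2


def test_atlas_round_trip(tmp_path, rng):
    atlas, _, _ = _atlas_and_fibers(rng)
    path = tmp_path / "atlas.json"
    atlas.save(path)
    back = ClusterAtlas.load(path)
    assert [l for l, _ in back.centroids] == [l for l, _ in atlas.centroids]
    for (_, a), (_, b) in zip(back.centroids, atlas.centroids):
        assert np.allclose(a, b, atol=1e-4)


def test_empty_atlas_rejected():
    with pytest.raises(ValueError, match="empty atlas"):
        assign_to_atlas(
            Tractogram(streamlines=[np.zeros((2, 3)) + [[0, 0, 0], [1, 0, 0]]]),
            ClusterAtlas(centroids=[]),
            5.0,
        )
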