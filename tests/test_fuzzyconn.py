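"""Otsu initialization, fuzzy affinity, seed selection, and scene propagation.

The fuzzy-scene contract is checked against an exhaustive maximin-path
oracle (Floyd-Warshall widest-path closure) on small grids, and the Otsu
thresholds against a brute-force search over all bin pairs.
"""

import itertools
import math

import numpy as np
import pytest

import vesselfc as v
from vesselfc.errors import DegenerateInputError, GridError, ParameterError, SizeError
from vesselfc.fuzzyconn import _edge_affinities


# ---------------------------------------------------------------------------
# Otsu


def _otsu_oracle(values, n_bins=256):
    """Naive double loop over all cut pairs maximizing between-class variance."""
    hist, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    p = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    best, best_pair = -np.inf, None
    for i in range(n_bins - 1):
        for j in range(i + 1, n_bins - 1):
            bcv = 0.0
            for sl in (slice(0, i + 1), slice(i + 1, j + 1), slice(j + 1, n_bins)):
                w = p[sl].sum()
                if w > 0:
                    mu = (p[sl] * centers[sl]).sum() / w
                    bcv += w * mu * mu
            if bcv > best + 1e-15:
                best, best_pair = bcv, (i, j)
    return edges[best_pair[0] + 1], edges[best_pair[1] + 1]


def test_otsu_three_delta_classes():
    values = np.concatenate([np.full(100, 0.1), np.full(50, 0.5), np.full(20, 0.9)])
    t_low, t_high = v.otsu_two_threshold(values)
    assert 0.1 < t_low < 0.5 < t_high < 0.9
    assert (values > t_high).sum() == 20


@pytest.mark.parametrize("trial", range(10))
def test_otsu_matches_exhaustive_oracle(trial):
    rng = np.random.default_rng(100 + trial)
    n_modes = rng.integers(3, 6)
    values = np.concatenate(
        [
            np.clip(rng.normal(rng.uniform(0.05, 0.95), 0.03, rng.integers(30, 200)), 0, 1)
            for _ in range(n_modes)
        ]
    )
    got = v.otsu_two_threshold(values, n_bins=32)
    expected = _otsu_oracle(values, n_bins=32)
    assert got == pytest.approx(expected, abs=1e-12)


def test_otsu_constant_sample_degenerate():
    with pytest.raises(DegenerateInputError):
        v.otsu_two_threshold(np.full(100, 0.5))


# ---------------------------------------------------------------------------
# Affinity statistics and components


def test_affinity_stats_two_point():
    feat = v.VolumetricImage(np.array([[[0.8, 1.0, 0.3]]]), (1, 1, 1))
    fg = v.BinaryMask(np.array([[[1, 1, 0]]]), (1, 1, 1))
    p = v.affinity_stats(feat, fg)
    assert p.m == pytest.approx(0.9)
    assert p.s == pytest.approx(0.1)  # population SD


def test_affinity_stats_degenerate_cases(rng):
    feat = v.VolumetricImage(np.full((4, 4, 4), 0.5), (1, 1, 1))
    with pytest.raises(DegenerateInputError):
        v.affinity_stats(feat, v.BinaryMask(np.ones((4, 4, 4)), (1, 1, 1)))
    with pytest.raises(DegenerateInputError):
        v.affinity_stats(feat, v.BinaryMask(np.zeros((4, 4, 4)), (1, 1, 1)))


def test_affinity_stats_matches_two_pass_oracle(rng):
    vals = rng.random((6, 6, 6))
    fg = (rng.random((6, 6, 6)) > 0.4).astype(np.uint8)
    p = v.affinity_stats(
        v.VolumetricImage(vals, (1, 1, 1)), v.BinaryMask(fg, (1, 1, 1))
    )
    sel = vals[fg.astype(bool)]
    mean = sum(sel) / sel.size
    var = sum((x - mean) ** 2 for x in sel) / sel.size
    assert p.m == pytest.approx(mean, abs=1e-12)
    assert p.s == pytest.approx(math.sqrt(var), abs=1e-12)


def test_h_components_scalar_values():
    p = v.AffinityParams(m=0.5, s=0.1)
    h1, h2 = v.h_components(0.5, 0.5, p)
    assert h1 == pytest.approx(1.0)
    h1, h2 = v.h_components(0.75, 0.25, p)  # |fc-fd| = 0.5 = m
    assert h2 == pytest.approx(1.0)
    h1, h2 = v.h_components(0.6, 0.5, p)
    assert h1 == pytest.approx(math.exp(-0.125), abs=1e-12)
    assert h2 == pytest.approx(math.exp(-8.0), abs=1e-12)


def test_adaptive_weights():
    assert v.adaptive_weights(0.3, 0.3) == pytest.approx((0.5, 0.5))
    assert v.adaptive_weights(0.7, 0.0) == pytest.approx((1.0, 0.0))
    w1, w2 = v.adaptive_weights(math.exp(-0.125), math.exp(-8.0))
    assert w1 == pytest.approx(0.99962, abs=1e-4)
    assert w1 + w2 == pytest.approx(1.0)
    assert v.adaptive_weights(0.0, 0.0) == (0.5, 0.5)


def test_affinity_adjacency_and_symmetry(rng):
    feat = v.VolumetricImage(rng.random((5, 5, 5)), (1, 1, 1))
    p = v.AffinityParams(m=0.5, s=0.2)
    assert v.affinity((0, 0, 0), (1, 1, 0), feat, p) == 0.0
    assert v.affinity((0, 0, 0), (0, 0, 2), feat, p) == 0.0
    for _ in range(200):
        c = tuple(rng.integers(0, 5, 3))
        d = tuple(rng.integers(0, 5, 3))
        assert v.affinity(c, d, feat, p) == pytest.approx(
            v.affinity(d, c, feat, p), abs=1e-15
        )
        assert 0.0 <= v.affinity(c, d, feat, p) <= 1.0


def test_pair_affinity_composition():
    # adjacent pair with fc = fd = m: mu = w1*1 + w2*h2, h2 = exp(-m^2/2s^2)
    p = v.AffinityParams(m=0.5, s=0.1)
    feat = v.VolumetricImage(np.full((3, 3, 3), 0.5), (1, 1, 1))
    h2 = math.exp(-0.5 * (0.5 / 0.1) ** 2)
    w1 = 1.0 / (1.0 + h2)
    expected = w1 * 1.0 + (1 - w1) * h2
    assert v.affinity((1, 1, 1), (1, 1, 2), feat, p) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# Seed selection


def test_seed_single_bright_voxel():
    arr = np.zeros((10, 10, 6))
    arr[7, 3, 4] = 1.0
    seed = v.select_seed(v.VolumetricImage(arr, (1, 1, 1)))
    assert seed.index == (7, 3, 4)


def test_seed_constant_volume_tie_break():
    seed = v.select_seed(v.VolumetricImage(np.ones((10, 10, 6)), (1, 1, 1)))
    assert seed.index == (0, 0, 0)
    assert seed.vesselness_mean == pytest.approx(1.0)


def test_seed_prefers_wide_blob():
    arr = np.zeros((20, 10, 6))
    ii, jj, kk = np.meshgrid(np.arange(20), np.arange(10), np.arange(6), indexing="ij")
    narrow = np.exp(-(((ii - 4) ** 2 + (jj - 5) ** 2 + (kk - 3) ** 2) / 0.5))
    wide = np.exp(-(((ii - 14) ** 2 + (jj - 5) ** 2 + (kk - 3) ** 2) / 8.0))
    arr = np.maximum(narrow / narrow.max(), wide / wide.max())
    seed = v.select_seed(v.VolumetricImage(arr, (1, 1, 1)))
    # both blobs peak at 1.0, but the wide blob has the larger block mean
    assert seed.index[0] > 10
    # exhaustive check: no other potential seed block has a larger mean
    assert seed.vesselness_mean == pytest.approx(
        _best_block_mean(arr), abs=1e-12
    )


def _best_block_mean(arr):
    nx, ny, nz = arr.shape
    best = -1.0
    for i0 in range(0, nx, 5):
        for j0 in range(0, ny, 5):
            for k0 in range(0, nz, 3):
                block = arr[i0 : i0 + 5, j0 : j0 + 5, k0 : k0 + 3]
                loc = np.unravel_index(np.argmax(block), block.shape)
                i, j, k = i0 + loc[0], j0 + loc[1], k0 + loc[2]
                m = arr[
                    max(i - 2, 0) : i + 3, max(j - 2, 0) : j + 3, max(k - 1, 0) : k + 2
                ].mean()
                best = max(best, m)
    return best


def test_seed_requires_minimum_volume():
    with pytest.raises(SizeError):
        v.select_seed(v.VolumetricImage(np.zeros((4, 4, 2)), (1, 1, 1)))


# ---------------------------------------------------------------------------
# Fuzzy scene


def _scene_oracle(feature, seed_idx, params, region=None):
    """Floyd-Warshall widest-path (maximin) closure over the voxel graph."""
    shape = feature.voxels.shape
    nodes = list(np.ndindex(shape))
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    np.fill_diagonal(W, 1.0)
    for a in nodes:
        for axis in range(3):
            b = list(a)
            b[axis] += 1
            b = tuple(b)
            if b[axis] < shape[axis]:
                if region is not None and not (region[a] and region[b]):
                    continue
                mu = v.affinity(a, b, feature, params)
                W[index[a], index[b]] = mu
                W[index[b], index[a]] = mu
    for k in range(n):
        W = np.maximum(W, np.minimum(W[:, k : k + 1], W[k : k + 1, :]))
    conn = W[index[seed_idx]].reshape(shape).copy()
    conn[seed_idx] = 1.0
    return conn


def test_scene_chain_and_binarize():
    feat = v.VolumetricImage(np.array([[[0.9, 0.8, 0.1]]]).reshape(3, 1, 1), (1, 1, 1))
    params = v.AffinityParams(m=0.85, s=0.15)
    seed = v.SeedPoint(index=(0, 0, 0), vesselness_mean=0.9)
    scene = v.compute_fuzzy_scene(feat, seed, params)
    a12 = v.affinity((0, 0, 0), (1, 0, 0), feat, params)
    a23 = v.affinity((1, 0, 0), (2, 0, 0), feat, params)
    expected = np.array([1.0, a12, min(a12, a23)])
    np.testing.assert_allclose(scene.connectivity.ravel(), expected, atol=1e-15)
    mask = v.binarize_scene(scene, min(a12, a23) + 1e-6)
    assert mask.voxels.ravel().tolist() == [1, 1, 0]


def test_scene_single_voxel():
    feat = v.VolumetricImage(np.full((1, 1, 1), 0.7), (1, 1, 1))
    scene = v.compute_fuzzy_scene(
        feat, v.SeedPoint((0, 0, 0), 0.7), v.AffinityParams(0.5, 0.1)
    )
    assert scene.connectivity.ravel().tolist() == [1.0]


@pytest.mark.parametrize("trial", range(40))
def test_scene_matches_maximin_oracle_random(trial):
    rng = np.random.default_rng(500 + trial)
    feat = v.VolumetricImage(rng.random((3, 3, 3)), (1, 1, 1))
    params = v.AffinityParams(m=float(rng.uniform(0.2, 0.8)), s=float(rng.uniform(0.05, 0.4)))
    seed_idx = tuple(rng.integers(0, 3, 3))
    scene = v.compute_fuzzy_scene(feat, v.SeedPoint(seed_idx, 0.5), params)
    oracle = _scene_oracle(feat, seed_idx, params)
    assert np.abs(scene.connectivity - oracle).max() <= 1e-12


@pytest.mark.parametrize("shape", [(2, 2, 2), (4, 4, 3), (4, 2, 3), (1, 4, 3)])
def test_scene_matches_oracle_all_small_shapes(shape):
    rng = np.random.default_rng(97 * sum(shape) + shape[0])
    feat = v.VolumetricImage(rng.random(shape), (1, 1, 1))
    params = v.AffinityParams(m=0.5, s=0.2)
    seed_idx = (0, 0, 0)
    scene = v.compute_fuzzy_scene(feat, v.SeedPoint(seed_idx, 0.5), params)
    oracle = _scene_oracle(feat, seed_idx, params)
    assert np.abs(scene.connectivity - oracle).max() <= 1e-12


def test_scene_respects_region(rng):
    feat = v.VolumetricImage(rng.random((3, 3, 3)), (1, 1, 1))
    region = np.ones((3, 3, 3), dtype=np.uint8)
    region[2, :, :] = 0
    params = v.AffinityParams(m=0.5, s=0.2)
    scene = v.compute_fuzzy_scene(
        feat, v.SeedPoint((0, 0, 0), 0.5), params,
        region=v.BinaryMask(region, (1, 1, 1)),
    )
    assert (scene.connectivity[2, :, :] == 0).all()
    oracle = _scene_oracle(feat, (0, 0, 0), params, region=region.astype(bool))
    assert np.abs(scene.connectivity - oracle).max() <= 1e-12


def test_scene_seed_invariant_and_bounds(rng):
    feat = v.VolumetricImage(rng.random((4, 4, 3)), (1, 1, 1))
    scene = v.compute_fuzzy_scene(
        feat, v.SeedPoint((1, 2, 1), 0.5), v.AffinityParams(0.4, 0.15)
    )
    assert scene.connectivity[1, 2, 1] == 1.0
    assert scene.connectivity.min() >= 0.0
    assert scene.connectivity.max() <= 1.0


def test_binarize_threshold_validation_and_monotonicity(rng):
    feat = v.VolumetricImage(rng.random((4, 4, 3)), (1, 1, 1))
    scene = v.compute_fuzzy_scene(
        feat, v.SeedPoint((0, 0, 0), 0.5), v.AffinityParams(0.4, 0.3)
    )
    with pytest.raises(ParameterError):
        v.binarize_scene(scene, 1.0)
    with pytest.raises(ParameterError):
        v.binarize_scene(scene, 0.0)
    counts = [v.binarize_scene(scene, t).voxels.sum() for t in np.linspace(0.01, 0.9, 8)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    # T below the minimum positive connectivity keeps every reachable voxel
    reachable = scene.connectivity > 0
    t_tiny = scene.connectivity[reachable].min() / 2
    assert v.binarize_scene(scene, t_tiny).voxels.sum() == reachable.sum()


def test_vectorized_edge_affinity_matches_scalar(rng):
    feat = v.VolumetricImage(rng.random((4, 3, 3)), (1, 1, 1))
    params = v.AffinityParams(m=0.5, s=0.15)
    for axis in range(3):
        edges = _edge_affinities(feat.voxels, params, axis)
        for a in np.ndindex(edges.shape):
            b = list(a)
            b[axis] += 1
            assert edges[a] == pytest.approx(
                v.affinity(a, tuple(b), feat, params), abs=1e-14
            )
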