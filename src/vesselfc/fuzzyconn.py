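"""Single-seed fuzzy-connectedness segmentation on the vesselness image.

Fuzzy connectedness assigns every voxel the strength of its best path to a
seed, where a path's strength is the minimum pairwise affinity along it
(maximin path strength). The affinity of a 6-face-adjacent voxel pair (c, d)
combines an object-feature term and a homogeneity term,

    mu(c, d) = mu_alpha(c, d) * [w1 * h1 + w2 * h2],
    h1 = exp(-1/2 [((f(c)+f(d))/2 - m) / s]^2),
    h2 = exp(-1/2 [(|f(c)-f(d)| - m) / s]^2),
    w1 = h1 / (h1 + h2),   w2 = 1 - w1,

with f the feature image (vesselness here, intensity for the traditional
variant) and (m, s) the mean/SD of the feature over the foreground of a
two-threshold Otsu vessel mask. mu_alpha is hard 6-face adjacency. The seed
is picked automatically: the volume is tiled into 5x5x3 blocks, each block's
maximum-vesselness voxel is a potential seed, and the potential seed whose
own 5x5x3 neighbourhood has the largest mean wins. The fuzzy scene is
computed by best-first (max-heap) propagation and binarized at threshold T.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, GridError, ParameterError, SizeError
from .io_resample import BinaryMask, VolumetricImage

R_SUB = (5, 5, 3)  # seed-search block, in-plane 5x5 by 3 slices


@dataclass(frozen=True)
class AffinityParams:
    """Foreground feature statistics driving the affinity function."""

    m: float
    s: float
    adjacency: str = "face_6"

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise DegenerateInputError(f"affinity SD must be > 0, got {self.s}")
        if self.adjacency != "face_6":
            raise ParameterError(f"unsupported adjacency {self.adjacency!r}")


@dataclass(frozen=True)
class SeedPoint:
    index: tuple[int, int, int]
    vesselness_mean: float


@dataclass
class FuzzyScene:
    """Per-voxel connectivity strengths in [0, 1] relative to the seed."""

    connectivity: np.ndarray
    seed: SeedPoint
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Otsu initialization


def otsu_two_threshold(values: np.ndarray, n_bins: int = 256) -> tuple[float, float]:
    """Two cut points maximizing three-class between-class variance.

    The histogram uses ``n_bins`` uniform bins over [0, 1]. Returns
    (t_low, t_high) with t_low < t_high; foreground = values > t_high.
    Ties are broken toward the smallest (i, j) bin pair.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise DegenerateInputError("empty sample")
    hist, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    if np.count_nonzero(hist) < 3:
        raise DegenerateInputError(
            f"need >= 3 occupied histogram bins, found {np.count_nonzero(hist)}"
        )
    p = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_T = mu[-1]

    # cut after bin i and after bin j, 0 <= i < j <= n_bins - 2
    i_idx = np.arange(n_bins - 1)
    w1 = w[i_idx][:, None]
    s1 = mu[i_idx][:, None]
    w2 = w[i_idx][None, :] - w1
    s2 = mu[i_idx][None, :] - s1
    w3 = 1.0 - w[i_idx][None, :]
    s3 = mu_T - mu[i_idx][None, :]

    def term(s_, w_):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = s_ * s_ / w_
        return np.where(w_ > 0, t, 0.0)

    bcv = term(s1, w1) + term(s2, w2) + term(s3, w3) - mu_T * mu_T
    valid = i_idx[:, None] < i_idx[None, :]
    bcv = np.where(valid, bcv, -np.inf)
    flat = int(np.argmax(bcv))  # C-order argmax = smallest (i, j) on ties
    i, j = np.unravel_index(flat, bcv.shape)
    return float(edges[i + 1]), float(edges[j + 1])


def affinity_stats(vesselness: VolumetricImage, mask_fg: BinaryMask) -> AffinityParams:
    """Mean and population SD of the feature over the foreground mask."""
    if vesselness.shape != mask_fg.shape:
        raise GridError(f"shape mismatch {vesselness.shape} vs {mask_fg.shape}")
    fg = vesselness.voxels[mask_fg.astype_bool()]
    if fg.size == 0:
        raise DegenerateInputError("empty foreground: cannot estimate (m, s)")
    m = float(fg.mean())
    s = float(fg.std())
    if s == 0:
        raise DegenerateInputError("zero foreground SD: constant feature values")
    return AffinityParams(m=m, s=s)


# ---------------------------------------------------------------------------
# Affinity


def h_components(fc: float, fd: float, params: AffinityParams) -> tuple[float, float]:
    h1 = np.exp(-0.5 * (((fc + fd) / 2.0 - params.m) / params.s) ** 2)
    h2 = np.exp(-0.5 * ((abs(fc - fd) - params.m) / params.s) ** 2)
    return float(h1), float(h2)


def adaptive_weights(h1: float, h2: float) -> tuple[float, float]:
    """Pair-adaptive weights w1 = h1/(h1+h2); (0.5, 0.5) when both vanish."""
    total = h1 + h2
    if total <= 0:
        return 0.5, 0.5
    w1 = h1 / total
    return w1, 1.0 - w1


def _is_adjacent(c: tuple[int, int, int], d: tuple[int, int, int]) -> bool:
    diff = sum(abs(a - b) for a, b in zip(c, d))
    return diff <= 1


def affinity(
    c: tuple[int, int, int],
    d: tuple[int, int, int],
    feature: VolumetricImage,
    params: AffinityParams,
) -> float:
    """Fuzzy affinity of a voxel pair; 0 unless 6-face-adjacent or identical."""
    if not _is_adjacent(c, d):
        return 0.0
    fc = float(feature.voxels[c])
    fd = float(feature.voxels[d])
    h1, h2 = h_components(fc, fd, params)
    w1, w2 = adaptive_weights(h1, h2)
    return float(w1 * h1 + w2 * h2)


def _edge_affinities(f: np.ndarray, params: AffinityParams, axis: int) -> np.ndarray:
    """Affinity between every voxel and its +axis neighbour (shape reduced by 1)."""
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[axis] = slice(None, -1)
    hi[axis] = slice(1, None)
    fa = f[tuple(lo)]
    fb = f[tuple(hi)]
    h1 = np.exp(-0.5 * (((fa + fb) / 2.0 - params.m) / params.s) ** 2)
    h2 = np.exp(-0.5 * ((np.abs(fa - fb) - params.m) / params.s) ** 2)
    total = h1 + h2
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = (h1 * h1 + h2 * h2) / total
    return np.where(total > 0, mu, 0.0)  # both-zero convention gives mu = 0


# ---------------------------------------------------------------------------
# Seed selection


def select_seed(vesselness: VolumetricImage) -> SeedPoint:
    """Automatic single-seed selection on the vesselness image.

    The volume is partitioned into 5x5x3 blocks (truncated at borders); the
    maximum-vesselness voxel of each block is a potential seed. Around every
    potential seed a 5x5x3 block (clipped at borders) is averaged, and the
    potential seed with the largest mean wins. Ties break toward the larger
    seed-voxel vesselness, then the smallest x-fastest linear index.
    """
    arr = vesselness.voxels
    nx, ny, nz = arr.shape
    if nx < R_SUB[0] or ny < R_SUB[1] or nz < R_SUB[2]:
        raise SizeError(f"volume {arr.shape} smaller than seed block {R_SUB}")

    potentials: list[tuple[int, int, int]] = []
    for i0 in range(0, nx, R_SUB[0]):
        for j0 in range(0, ny, R_SUB[1]):
            for k0 in range(0, nz, R_SUB[2]):
                block = arr[i0 : i0 + R_SUB[0], j0 : j0 + R_SUB[1], k0 : k0 + R_SUB[2]]
                # first max in (z, y, x) C-order == smallest x-fastest index
                t = block.transpose(2, 1, 0)
                kz, jy, ix = np.unravel_index(int(np.argmax(t)), t.shape)
                potentials.append((i0 + int(ix), j0 + int(jy), k0 + int(kz)))

    best_key = None
    best_seed = None
    for (i, j, k) in potentials:
        sl = arr[
            max(i - 2, 0) : i + 3, max(j - 2, 0) : j + 3, max(k - 1, 0) : k + 2
        ]
        mean = float(sl.mean())
        lin = i + nx * (j + ny * k)
        key = (-mean, -float(arr[i, j, k]), lin)
        if best_key is None or key < best_key:
            best_key = key
            best_seed = SeedPoint(index=(i, j, k), vesselness_mean=mean)
    return best_seed


# ---------------------------------------------------------------------------
# Fuzzy-scene propagation


def compute_fuzzy_scene(
    feature: VolumetricImage,
    seed: SeedPoint,
    params: AffinityParams,
    region: BinaryMask | None = None,
) -> FuzzyScene:
    """Maximin path strength from the seed to every voxel.

    connectivity(v) = max over paths P from seed to v of min affinity along
    P, computed by best-first max-heap propagation (each voxel finalized at
    its true strength the first time it is popped). Voxels outside ``region``
    keep connectivity 0 and are never traversed.
    """
    arr = feature.voxels
    nx, ny, nz = arr.shape
    idx = seed.index
    if not all(0 <= idx[a] < arr.shape[a] for a in range(3)):
        raise ParameterError(f"seed {idx} outside volume {arr.shape}")
    region_arr = None if region is None else region.astype_bool()
    if region_arr is not None and region_arr.shape != arr.shape:
        raise GridError(f"region shape {region_arr.shape} != {arr.shape}")

    # Precompute the 6 neighbour affinities as full-size arrays (0 on the
    # border and across the region boundary), flattened in C order.
    n = arr.size
    offsets = (ny * nz, -(ny * nz), nz, -nz, 1, -1)
    aff_flat: list[np.ndarray] = []
    for axis in range(3):
        fwd = np.zeros(arr.shape)
        sl = [slice(None)] * 3
        sl[axis] = slice(None, -1)
        edge = _edge_affinities(arr, params, axis)
        if region_arr is not None:
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(None, -1)
            hi[axis] = slice(1, None)
            edge = edge * region_arr[tuple(lo)] * region_arr[tuple(hi)]
        fwd[tuple(sl)] = edge
        bwd = np.zeros(arr.shape)
        sl[axis] = slice(1, None)
        bwd[tuple(sl)] = edge
        aff_flat.append(fwd.ravel())
        aff_flat.append(bwd.ravel())
    edges = list(zip(offsets, [a.tolist() for a in aff_flat]))

    conn = [0.0] * n
    s_flat = (idx[0] * ny + idx[1]) * nz + idx[2]
    conn[s_flat] = 1.0
    heap = [(-1.0, s_flat)]
    pop = heapq.heappop
    push = heapq.heappush
    while heap:
        negc, u = pop(heap)
        c = -negc
        if c < conn[u]:
            continue  # stale entry
        for off, aff in edges:
            a = aff[u]
            if a <= 0.0:
                continue
            v = u + off
            cand = c if a > c else a
            if cand > conn[v]:
                conn[v] = cand
                push(heap, (-cand, v))

    connectivity = np.asarray(conn).reshape(arr.shape)
    if region_arr is not None:
        connectivity[~region_arr] = 0.0
        connectivity[idx] = 1.0
    return FuzzyScene(connectivity, seed, feature.spacing, feature.origin)


def binarize_scene(scene: FuzzyScene, T: float) -> BinaryMask:
    """Threshold the fuzzy scene: foreground = connectivity > T, 0 < T < 1."""
    if not 0 < T < 1:
        raise ParameterError(f"T must be in (0, 1), got {T}")
    return BinaryMask(
        (scene.connectivity > T).astype(np.uint8), scene.spacing, scene.origin
    )
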