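"""Adaptive sigmoid contrast enhancement initialized by K-means clustering.

The in-VOI intensity distribution of a contrast-enhanced liver CT is modelled
as five regions with increasing mean intensity: background, tumor, liver
parenchyma, low-intensity vessel mixed with parenchyma, and high-intensity
vessel. The means of the last two regions, m1 and m2, fix the sigmoid window

    I_sigmoid = 1 / (1 + exp(-(I - beta) / alpha)),
    alpha = (m2 - m1) / 2,   beta = (m2 + m1) / 2,

which maps vessels toward 1 and everything darker toward 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import DegenerateInputError, ParameterError
from .io_resample import UNIT_INTERVAL, BinaryMask, VolumetricImage


@dataclass(frozen=True)
class SigmoidParams:
    """Sigmoid window derived from the two brightest cluster means (HU)."""

    alpha: float  # intensity half-range, > 0
    beta: float  # intensity center
    m1: float
    m2: float

    def __post_init__(self) -> None:
        if not self.m2 > self.m1:
            raise DegenerateInputError(f"need m2 > m1, got m1={self.m1}, m2={self.m2}")
        if self.alpha <= 0:
            raise ParameterError(f"alpha must be > 0, got {self.alpha}")


def cluster_voi(
    voi: VolumetricImage,
    k: int = 5,
    seed: int = 0,
    mask: BinaryMask | None = None,
) -> np.ndarray:
    """Cluster in-mask intensities into ``k`` regions; return ascending means.

    Initialization is deterministic quantile seeding of the centers on the
    in-mask intensity distribution, so the result is reproducible regardless
    of ``seed`` (kept for interface stability).
    """
    values = voi.voxels if mask is None else voi.voxels[mask.astype_bool()]
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise DegenerateInputError("no in-mask voxels to cluster")
    if np.unique(values).size < k:
        raise DegenerateInputError(
            f"need at least {k} distinct intensities, found {np.unique(values).size}"
        )
    init = np.quantile(values, (np.arange(k) + 0.5) / k).reshape(-1, 1)
    # quantile ties (heavily repeated values) would collapse centers; nudge apart
    for i in range(1, k):
        if init[i, 0] <= init[i - 1, 0]:
            init[i, 0] = init[i - 1, 0] + 1e-6
    km = KMeans(
        n_clusters=k, init=init, n_init=1, max_iter=300, tol=1e-8, random_state=seed
    )
    km.fit(values.reshape(-1, 1))
    means = np.sort(km.cluster_centers_.ravel())
    if np.any(np.diff(means) == 0):
        raise DegenerateInputError("tied cluster means: degenerate intensity distribution")
    return means


def sigmoid_params_from_clusters(means: np.ndarray) -> SigmoidParams:
    """Build the sigmoid window from ascending cluster means (uses the last two)."""
    means = np.asarray(means, dtype=np.float64)
    if means.size < 2:
        raise DegenerateInputError("need at least 2 cluster means")
    m1, m2 = float(means[-2]), float(means[-1])
    if m2 <= m1:
        raise DegenerateInputError(f"need m2 > m1, got m1={m1}, m2={m2}")
    return SigmoidParams(alpha=(m2 - m1) / 2.0, beta=(m2 + m1) / 2.0, m1=m1, m2=m2)


def sigmoid_enhance(voi: VolumetricImage, params: SigmoidParams) -> VolumetricImage:
    """Apply the adaptive sigmoid mapping voxelwise; output in (0, 1)."""
    if params.alpha <= 0:
        raise ParameterError(f"alpha must be > 0, got {params.alpha}")
    out = 1.0 / (1.0 + np.exp(-(voi.voxels - params.beta) / params.alpha))
    return VolumetricImage(out, voi.spacing, voi.origin, UNIT_INTERVAL)
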