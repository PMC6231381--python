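"""End-to-end segmentation pipeline and parameter sweeps.

Stages: liver-VOI masking -> K-means-initialized adaptive sigmoid contrast
enhancement -> isotropic resampling -> multiscale vesselness -> two-threshold
Otsu initialization + automatic single seed -> fuzzy-connectedness scene ->
binarization at threshold T -> resampling back to the input grid.

Modes:
  improved          vesselness (improved filter) drives the fuzzy affinity
  jerman_vesselness same pipeline with the uncompensated-background filter
  traditional_fc    affinity on the (sigmoid) intensity image, single seed
                    still selected on the vesselness image
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace
from typing import Any

import numpy as np
import pandas as pd

from . import contrast, fuzzyconn, io_resample, metrics, vesselness
from .errors import DegenerateInputError, ParameterError
from .io_resample import BinaryMask, VolumetricImage

logger = logging.getLogger("vesselfc")

MODES = ("improved", "jerman_vesselness", "traditional_fc")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the segmentation pipeline."""

    iso_spacing: float | None = None  # None: smallest in-plane spacing of the input
    k_clusters: int = 5
    sigma_min: float = 0.5
    sigma_max: float = 3.0
    n_scales: int = 5
    tau: float = 0.6
    threshold_T: float = 0.05
    otsu_bins: int = 256
    mode: str = "improved"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ParameterError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0 < self.tau <= 1:
            raise ParameterError(f"tau must be in (0, 1], got {self.tau}")
        if not 0 < self.threshold_T < 1:
            raise ParameterError(f"T must be in (0, 1), got {self.threshold_T}")

    def scale_params(self) -> vesselness.ScaleSpaceParams:
        return vesselness.ScaleSpaceParams(
            sigma_min=self.sigma_min,
            sigma_max=self.sigma_max,
            n_scales=self.n_scales,
            tau=self.tau,
        )


@dataclass
class SceneState:
    """Everything computed up to (and including) the fuzzy scene."""

    scene: fuzzyconn.FuzzyScene
    iso_mask: BinaryMask
    report: dict[str, Any]


def _stage(report: dict, name: str, t0: float, **stats) -> float:
    dt = time.perf_counter() - t0
    report.setdefault("stages", {})[name] = {"seconds": round(dt, 3), **stats}
    logger.info("stage %-16s %6.2fs %s", name, dt, stats)
    return time.perf_counter()


def run_to_scene(
    config: PipelineConfig, image: VolumetricImage, liver_mask: BinaryMask
) -> SceneState:
    """Run the pipeline through fuzzy-scene computation (before thresholding)."""
    report: dict[str, Any] = {"config": config.__dict__.copy()}
    t0 = time.perf_counter()

    voi = io_resample.apply_voi(image, liver_mask)
    fill = float(voi.voxels[~liver_mask.astype_bool()].min()) if (~liver_mask.astype_bool()).any() else float("nan")
    report["background_fill"] = fill
    t0 = _stage(report, "voi", t0)

    means = contrast.cluster_voi(voi, k=config.k_clusters, seed=config.rng_seed, mask=liver_mask)
    sig = contrast.sigmoid_params_from_clusters(means)
    enhanced = contrast.sigmoid_enhance(voi, sig)
    report["cluster_means"] = [float(m) for m in means]
    report["sigmoid"] = {"alpha": sig.alpha, "beta": sig.beta, "m1": sig.m1, "m2": sig.m2}
    t0 = _stage(report, "sigmoid", t0, alpha=round(sig.alpha, 3), beta=round(sig.beta, 3))

    target = config.iso_spacing or min(image.spacing[0], image.spacing[1])
    iso = io_resample.resample_isotropic(enhanced, target, "linear")
    iso_mask = io_resample.resample_to_reference(liver_mask, iso)
    report["iso_spacing"] = float(target)
    t0 = _stage(report, "resample", t0, spacing=target, shape=iso.shape)

    variant = "jerman" if config.mode == "jerman_vesselness" else "improved"
    vness = vesselness.multiscale_vesselness(iso, config.scale_params(), variant, iso_mask)
    t0 = _stage(report, "vesselness", t0, variant=variant)

    feature = iso if config.mode == "traditional_fc" else vness
    in_mask = iso_mask.astype_bool()
    t_low, t_high = fuzzyconn.otsu_two_threshold(feature.voxels[in_mask], config.otsu_bins)
    # (m, s) come from the upper Otsu class (the vessel class). On ideal
    # tubes the compensated response saturates at exactly 1 across vessel
    # interiors, so that class can carry zero dispersion; the transitional
    # middle class (partial-volume vessel boundary) then provides the only
    # informative statistics and is used instead.
    fg = BinaryMask(
        ((feature.voxels > t_high) & in_mask).astype(np.uint8),
        feature.spacing,
        feature.origin,
    )
    try:
        aff = fuzzyconn.affinity_stats(feature, fg)
        stats_class = "upper"
    except DegenerateInputError:
        fg = BinaryMask(
            ((feature.voxels > t_low) & (feature.voxels <= t_high) & in_mask).astype(np.uint8),
            feature.spacing,
            feature.origin,
        )
        aff = fuzzyconn.affinity_stats(feature, fg)
        stats_class = "middle (upper class saturated)"
    seed = fuzzyconn.select_seed(vness)
    report["otsu"] = {
        "t_low": t_low,
        "t_high": t_high,
        "stats_class": stats_class,
        "foreground_voxels": int(fg.voxels.sum()),
    }
    report["affinity"] = {"m": aff.m, "s": aff.s}
    report["seed"] = {"index": list(seed.index), "vesselness_mean": seed.vesselness_mean}
    t0 = _stage(report, "initialize", t0, m=round(aff.m, 4), s=round(aff.s, 4), seed=seed.index)

    scene = fuzzyconn.compute_fuzzy_scene(feature, seed, aff, region=iso_mask)
    t0 = _stage(report, "fuzzy_scene", t0)
    return SceneState(scene=scene, iso_mask=iso_mask, report=report)


def run_pipeline(
    config: PipelineConfig,
    image: VolumetricImage,
    liver_mask: BinaryMask,
) -> tuple[BinaryMask, dict[str, Any]]:
    """Full pipeline: returns the vessel mask on the input grid plus a report."""
    state = run_to_scene(config, image, liver_mask)
    t0 = time.perf_counter()
    iso_vessel = fuzzyconn.binarize_scene(state.scene, config.threshold_T)
    vessel = io_resample.resample_to_reference(iso_vessel, image)
    # keep the segmentation inside the liver on the native grid as well
    vessel = BinaryMask(
        vessel.voxels * liver_mask.voxels, vessel.spacing, vessel.origin
    )
    state.report["vessel_voxels"] = int(vessel.voxels.sum())
    _stage(state.report, "binarize", t0, T=config.threshold_T, voxels=int(vessel.voxels.sum()))
    return vessel, state.report


def sweep(
    config: PipelineConfig,
    parameter: str,
    values: list[float],
    image: VolumetricImage,
    liver_mask: BinaryMask,
    gold: BinaryMask,
) -> pd.DataFrame:
    """Score the pipeline over a range of tau or T values.

    For T the fuzzy scene is computed once and re-thresholded per value;
    for tau the vesselness stage changes, so the pipeline is re-run.
    """
    if parameter not in ("tau", "T"):
        raise ParameterError(f"sweep parameter must be 'tau' or 'T', got {parameter!r}")
    if not values:
        raise ParameterError("empty sweep value list")

    rows = []
    if parameter == "T":
        state = run_to_scene(config, image, liver_mask)
        for T in values:
            iso_vessel = fuzzyconn.binarize_scene(state.scene, float(T))
            vessel = io_resample.resample_to_reference(iso_vessel, image)
            vessel = BinaryMask(vessel.voxels * liver_mask.voxels, vessel.spacing, vessel.origin)
            sc = metrics.evaluate(vessel, gold, region=liver_mask)
            rows.append({"T": float(T), "foreground_voxels": int(vessel.voxels.sum()), **sc._asdict()})
    else:
        for tau in values:
            cfg = replace(config, tau=float(tau))
            vessel, _ = run_pipeline(cfg, image, liver_mask)
            sc = metrics.evaluate(vessel, gold, region=liver_mask)
            rows.append({"tau": float(tau), "foreground_voxels": int(vessel.voxels.sum()), **sc._asdict()})
    return pd.DataFrame(rows)
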