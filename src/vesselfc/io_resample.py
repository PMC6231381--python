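"""Volume I/O, liver-VOI masking, and isotropic/anisotropic resampling.

Images are stored as numpy arrays indexed ``voxels[i, j, k]`` for the x, y, z
axes respectively, with physical voxel spacing ``(sx, sy, sz)`` in mm and an
origin in mm. The linear index convention is x-fastest:
``lin = i + nx * (j + ny * k)``. Only identity direction matrices are
supported; oblique acquisitions must be resampled upstream.

NIfTI (.nii/.nii.gz) and MetaImage (.mha/.mhd) are read and written through
SimpleITK.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .errors import FormatError, GridError, ParameterError

SUPPORTED_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")

HU = "HU"
UNIT_INTERVAL = "unit_interval"


@dataclass
class VolumetricImage:
    """3D scalar grid with physical voxel spacing.

    Depending on the pipeline stage the voxels carry HU, sigmoid-enhanced
    values, or vesselness values (``value_domain`` distinguishes HU from
    unit-interval data).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    value_domain: str = HU

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ParameterError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be strictly positive, got {self.spacing}")
        if self.value_domain not in (HU, UNIT_INTERVAL):
            raise ParameterError(f"unknown value_domain {self.value_domain!r}")
        if self.value_domain == UNIT_INTERVAL:
            lo, hi = float(self.voxels.min()), float(self.voxels.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ParameterError(
                    f"unit_interval volume has values outside [0,1]: [{lo}, {hi}]"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def is_isotropic(self, rtol: float = 1e-6) -> bool:
        sx, sy, sz = self.spacing
        return abs(sy - sx) <= rtol * sx and abs(sz - sx) <= rtol * sx


@dataclass
class BinaryMask:
    """Binary {0,1} volume sharing the grid conventions of VolumetricImage."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ParameterError(f"mask values must be 0/1, found {uniq[:5]}")
        self.voxels = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def astype_bool(self) -> np.ndarray:
        return self.voxels.astype(bool)


# ---------------------------------------------------------------------------
# SimpleITK bridge. sitk arrays are (z, y, x); ours are (x, y, z).


def _to_sitk(voxels: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(voxels, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def read_volume(path: str) -> VolumetricImage:
    """Read a NIfTI or MetaImage volume; spacing/origin come from the header."""
    path = str(path)
    if not any(path.endswith(ext) for ext in SUPPORTED_EXTENSIONS):
        raise FormatError(f"unsupported format for {path!r} (expected one of {SUPPORTED_EXTENSIONS})")
    try:
        img = sitk.ReadImage(path, sitk.sitkFloat64)
    except Exception as exc:  # sitk raises RuntimeError on unreadable files
        raise FormatError(f"cannot read volume {path!r}: {exc}") from exc
    arr, spacing, origin = _from_sitk(img)
    return VolumetricImage(arr, spacing, origin)


def read_mask(path: str) -> BinaryMask:
    """Read a volume and binarize at 0.5 (labels >0 become foreground)."""
    vol = read_volume(path)
    return BinaryMask((vol.voxels > 0.5).astype(np.uint8), vol.spacing, vol.origin)


def write_volume(image: VolumetricImage | BinaryMask, path: str) -> None:
    path = str(path)
    if not any(path.endswith(ext) for ext in SUPPORTED_EXTENSIONS):
        raise FormatError(f"unsupported format for {path!r} (expected one of {SUPPORTED_EXTENSIONS})")
    voxels = image.voxels
    if isinstance(image, BinaryMask):
        voxels = voxels.astype(np.uint8)
    sitk.WriteImage(_to_sitk(voxels, image.spacing, image.origin), path)


# ---------------------------------------------------------------------------
# VOI masking and resampling.


def apply_voi(
    image: VolumetricImage, liver_mask: BinaryMask, background_fill: float | None = None
) -> VolumetricImage:
    """Restrict the image to the liver volume of interest.

    Voxels outside the mask are set to ``background_fill``; inside they are
    unchanged. When ``background_fill`` is None the minimum intensity of the
    masked region is used, which keeps the downstream sigmoid mapping from
    creating a spurious bright background.
    """
    if image.shape != liver_mask.shape:
        raise GridError(f"image shape {image.shape} != mask shape {liver_mask.shape}")
    inside = liver_mask.astype_bool()
    if background_fill is None:
        if not inside.any():
            raise GridError("empty liver mask: cannot infer a background fill value")
        background_fill = float(image.voxels[inside].min())
    out = np.where(inside, image.voxels, float(background_fill))
    return VolumetricImage(out, image.spacing, image.origin, image.value_domain)


def _resample(
    voxels: np.ndarray,
    spacing,
    origin,
    new_spacing,
    new_size,
    interpolation: str,
    default_value: float,
) -> np.ndarray:
    interp = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}[interpolation]
    src = _to_sitk(voxels, spacing, origin)
    res = sitk.Resample(
        src,
        [int(n) for n in new_size],
        sitk.Transform(),
        interp,
        tuple(float(o) for o in origin),
        tuple(float(s) for s in new_spacing),
        src.GetDirection(),
        float(default_value),
        sitk.sitkFloat64,
    )
    return _from_sitk(res)[0]


def resample_isotropic(
    image: VolumetricImage, target_spacing: float, interpolation: str = "linear"
) -> VolumetricImage:
    """Resample onto an isotropic grid of spacing ``target_spacing`` mm.

    The physical extent is preserved: the new size per axis is
    ``round(old_size * old_spacing / target)``.
    """
    if target_spacing <= 0:
        raise ParameterError(f"target spacing must be > 0, got {target_spacing}")
    if interpolation not in ("linear", "nearest"):
        raise ParameterError(f"unknown interpolation {interpolation!r}")
    t = float(target_spacing)
    new_size = [
        max(1, int(round(n * s / t))) for n, s in zip(image.shape, image.spacing)
    ]
    fill = float(image.voxels.min())
    out = _resample(
        image.voxels, image.spacing, image.origin, (t, t, t), new_size, interpolation, fill
    )
    if image.value_domain == UNIT_INTERVAL:
        out = np.clip(out, 0.0, 1.0)
    return VolumetricImage(out, (t, t, t), image.origin, image.value_domain)


def resample_to_reference(mask: BinaryMask, reference: VolumetricImage | BinaryMask) -> BinaryMask:
    """Resample a binary mask onto the reference grid (nearest neighbour)."""
    out = _resample(
        mask.voxels.astype(np.float64),
        mask.spacing,
        mask.origin,
        reference.spacing,
        reference.shape,
        "nearest",
        0.0,
    )
    return BinaryMask((out > 0.5).astype(np.uint8), reference.spacing, reference.origin)
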