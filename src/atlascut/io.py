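"""Reading and writing volumes, masks, seed images and atlases.

NIfTI-1 (``.nii``, ``.nii.gz``) and MetaImage (``.mha``, ``.mhd``) are
supported through SimpleITK.  On disk the formats store arrays ``[z, y, x]``;
in memory everything is ``[x, y, z]``, so arrays are transposed at the
boundary and spacing/origin (which SimpleITK already reports as ``(x, y, z)``)
pass through unchanged.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .types import (
    SEED_BACKGROUND,
    SEED_NONE,
    SEED_ORGAN,
    FormatError,
    LabelMask,
    ProbabilisticAtlas,
    SeedImage,
    Volume,
)

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_seeds",
    "write_seeds",
    "read_atlas",
    "write_atlas",
]

_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


def _read_image(path: str | os.PathLike) -> sitk.Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise FormatError(f"{path}: expected a 3D image, got {img.GetDimension()}D")
    return img


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a 3D scalar volume from a NIfTI or MetaImage file."""
    img = _read_image(path)
    data = sitk.GetArrayFromImage(img).T  # [z,y,x] on disk -> [x,y,z]
    return Volume(data=data, spacing=img.GetSpacing(), origin=img.GetOrigin())


def _to_image(data: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _write_image(img: sitk.Image, path: str | os.PathLike) -> None:
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"directory does not exist: {path.parent}")
    sitk.WriteImage(img, str(path))


def write_volume(vol: Volume, path: str | os.PathLike) -> None:
    """Write a volume; round-trips bit-exactly for integer dtypes."""
    _write_image(_to_image(vol.data, vol.spacing, vol.origin), path)


def read_mask(path: str | os.PathLike) -> LabelMask:
    img = _read_image(path)
    data = sitk.GetArrayFromImage(img).T
    return LabelMask(data=data, spacing=img.GetSpacing(), origin=img.GetOrigin())


def write_mask(mask: LabelMask, path: str | os.PathLike) -> None:
    _write_image(
        _to_image(mask.data.astype(np.uint8), mask.spacing, mask.origin), path
    )


def read_seeds(path: str | os.PathLike, alpha: float = 1.0) -> SeedImage:
    """Read a seed label volume (0 = none, 1 = organ, 2 = background)."""
    img = _read_image(path)
    data = sitk.GetArrayFromImage(img).T
    codes = np.unique(data)
    bad = codes[~np.isin(codes, (SEED_NONE, SEED_ORGAN, SEED_BACKGROUND))]
    if bad.size:
        raise FormatError(f"{path}: unknown seed label code(s) {bad.tolist()}")
    return SeedImage(
        labels=data, alpha=alpha, spacing=img.GetSpacing(), origin=img.GetOrigin()
    )


def write_seeds(seeds: SeedImage, path: str | os.PathLike) -> None:
    _write_image(
        _to_image(seeds.labels.astype(np.uint8), seeds.spacing, seeds.origin), path
    )


def read_atlas(path: str | os.PathLike) -> ProbabilisticAtlas:
    img = _read_image(path)
    return ProbabilisticAtlas(data=sitk.GetArrayFromImage(img).T.astype(float))


def write_atlas(atlas: ProbabilisticAtlas, path: str | os.PathLike) -> None:
    _write_image(_to_image(atlas.data.astype(np.float32), (1, 1, 1), (0, 0, 0)), path)
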