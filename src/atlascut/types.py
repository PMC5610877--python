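"""Core volumetric data types.

All arrays are indexed ``[x, y, z]`` with 0-based voxel indices; physical
spacing and origin are carried for I/O fidelity but the algorithms operate
in voxel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Volume",
    "LabelMask",
    "SeedImage",
    "ProbabilisticAtlas",
    "SEED_NONE",
    "SEED_ORGAN",
    "SEED_BACKGROUND",
    "FormatError",
]

# Integer codes used in persisted seed label volumes.
SEED_NONE = 0
SEED_ORGAN = 1
SEED_BACKGROUND = 2


class FormatError(ValueError):
    """Raised when a file or array does not conform to the expected format."""


def _check_geometry(data: np.ndarray, spacing, origin) -> None:
    if data.ndim != 3:
        raise FormatError(f"expected a 3D array, got {data.ndim} axes")
    if min(data.shape) < 1:
        raise FormatError(f"every axis must have positive extent, got {data.shape}")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 strictly positive components, got {spacing}")
    if len(origin) != 3:
        raise ValueError(f"origin must have 3 components, got {origin}")


@dataclass
class Volume:
    """A 3D scalar grid (CT-like intensities or probabilities).

    Parameters
    ----------
    data
        3D array, axis order ``(x, y, z)``.
    spacing
        Per-axis voxel size in mm.
    origin
        Physical position of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _check_geometry(self.data, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMask:
    """A binary mask aligned to a :class:`Volume` (ground truth or output)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError(f"mask values must be in {{0, 1}}, got {uniq[:10]}")
            arr = arr.astype(bool)
        self.data = arr
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _check_geometry(self.data, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class SeedImage:
    """Ternary per-voxel seed labels with the background coefficient ``alpha``.

    ``labels`` holds the integer codes ``SEED_NONE`` / ``SEED_ORGAN`` /
    ``SEED_BACKGROUND``.  The numeric view ``S`` used by the atlas-fitting
    energy maps organ seeds to -1, background seeds to ``+alpha`` and
    unlabeled voxels to 0, so that lowering the energy pulls the atlas onto
    organ seeds and off background seeds.
    """

    labels: np.ndarray
    alpha: float = 1.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        uniq = np.unique(arr)
        bad = uniq[~np.isin(uniq, (SEED_NONE, SEED_ORGAN, SEED_BACKGROUND))]
        if bad.size:
            raise FormatError(f"unknown seed label code(s): {bad.tolist()}")
        if not float(self.alpha) > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        self.labels = arr.astype(np.uint8)
        self.alpha = float(self.alpha)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _check_geometry(self.labels, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def organ_mask(self) -> np.ndarray:
        return self.labels == SEED_ORGAN

    @property
    def background_mask(self) -> np.ndarray:
        return self.labels == SEED_BACKGROUND

    def numeric(self) -> np.ndarray:
        """Signed numeric seed map: organ -> -1, background -> +alpha, else 0."""
        s = np.zeros(self.labels.shape, dtype=float)
        s[self.organ_mask] = -1.0
        s[self.background_mask] = self.alpha
        return s

    def counts(self) -> tuple[int, int]:
        return int(self.organ_mask.sum()), int(self.background_mask.sum())

    def require_both_classes(self) -> None:
        n_org, n_bg = self.counts()
        if n_org == 0 or n_bg == 0:
            raise ValueError(
                f"need at least one organ and one background seed voxel "
                f"(got {n_org} organ, {n_bg} background)"
            )

    def add_seeds(
        self,
        organ: np.ndarray | None = None,
        background: np.ndarray | None = None,
    ) -> "SeedImage":
        """Return a new SeedImage with additional seed voxels.

        Additions are strictly additive: a voxel may never receive both
        labels, and previously placed seeds are never erased or relabeled.
        """
        organ = np.zeros(self.shape, bool) if organ is None else np.asarray(organ, bool)
        background = (
            np.zeros(self.shape, bool) if background is None else np.asarray(background, bool)
        )
        if organ.shape != self.shape or background.shape != self.shape:
            raise ValueError("seed addition masks must match the seed image shape")
        if (organ & background).any():
            raise ValueError("a voxel was proposed as both organ and background seed")
        new = self.labels.copy()
        conflict = (organ & (new == SEED_BACKGROUND)) | (background & (new == SEED_ORGAN))
        if conflict.any():
            raise ValueError(
                f"{int(conflict.sum())} proposed seed voxel(s) contradict existing seeds"
            )
        new[organ] = SEED_ORGAN
        new[background] = SEED_BACKGROUND
        return replace(self, labels=new)


@dataclass
class ProbabilisticAtlas:
    """Per-voxel organ probabilities on a fixed lattice ``(S_x, S_y, S_z)``."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3:
            raise FormatError(f"atlas must be 3D, got {arr.ndim} axes")
        if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
            raise ValueError(
                f"atlas values must lie in [0, 1], got range "
                f"[{arr.min():.4g}, {arr.max():.4g}]"
            )
        self.data = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape
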