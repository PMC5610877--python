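"""Probabilistic-atlas construction from training label masks.

Each training mask is cropped to the bounding box of its organ, resampled
onto a common lattice ``(S_x, S_y, S_z)``, converted to a signed Euclidean
distance map (positive inside the organ, negative outside), squashed through
a sigmoid, and the per-voxel sigmoid maps are averaged over the cohort.
The result is a grid of empirical organ probabilities: ~1 deep inside the
average organ, ~0 far outside, ~0.5 along the typical boundary, with the
sigmoid gain controlling how fast that transition happens.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .types import LabelMask, ProbabilisticAtlas

__all__ = [
    "AtlasConfig",
    "bounding_box",
    "resample_to_lattice",
    "signed_distance",
    "sigmoid_probability",
    "case_probability_map",
    "build_atlas",
]


@dataclass
class AtlasConfig:
    """Atlas lattice size and sigmoid gain.

    Parameters
    ----------
    lattice
        ``(S_x, S_y, S_z)`` size of the common atlas grid, each >= 2.
    gain
        Sigmoid gain ``a_p`` applied to the signed distance (per lattice
        voxel).  Larger values sharpen the atlas toward a binary average.
    margin
        Optional fractional margin added around each training bounding box
        before resampling, so the organ boundary does not sit on the lattice
        faces.  0 keeps the box tight.
    interpolation
        ``"nearest"`` (exactly binary) or ``"linear"`` (re-binarized at 0.5).
    """

    lattice: tuple[int, int, int] = (64, 64, 32)
    gain: float = 1.0
    margin: float = 0.0
    interpolation: str = "nearest"

    def __post_init__(self) -> None:
        self.lattice = tuple(int(s) for s in self.lattice)
        if len(self.lattice) != 3 or min(self.lattice) < 2:
            raise ValueError(f"lattice components must be >= 2, got {self.lattice}")
        if not self.gain > 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if self.margin < 0:
            raise ValueError(f"margin must be >= 0, got {self.margin}")
        if self.interpolation not in ("nearest", "linear"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")


Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


def bounding_box(mask: LabelMask) -> Box:
    """Tightest axis-aligned box containing all foreground voxels.

    Returned as half-open index ranges ``((x0, x1), (y0, y1), (z0, z1))``.
    """
    data = mask.data
    if not data.any():
        raise ValueError("cannot compute the bounding box of an empty mask")
    ranges = []
    for axis in range(3):
        proj = data.any(axis=tuple(a for a in range(3) if a != axis))
        (nz,) = np.nonzero(proj)
        ranges.append((int(nz[0]), int(nz[-1]) + 1))
    return tuple(ranges)


def _expand_box(box: Box, shape: tuple[int, ...], margin: float) -> Box:
    out = []
    for (lo, hi), extent in zip(box, shape):
        pad = int(round((hi - lo) * margin))
        out.append((max(0, lo - pad), min(extent, hi + pad)))
    return tuple(out)


def resample_to_lattice(mask: LabelMask, box: Box, cfg: AtlasConfig) -> LabelMask:
    """Resample the boxed region of a binary mask onto the atlas lattice.

    The box is mapped onto the full lattice with cell-centred coordinates;
    nearest-neighbour interpolation keeps the result exactly binary, linear
    interpolation is re-binarized at 0.5.
    """
    for lo, hi in box:
        if hi <= lo:
            raise ValueError(f"degenerate box {box}")
    box = _expand_box(box, mask.shape, cfg.margin)
    extents = [hi - lo for lo, hi in box]
    # Lattice node i samples source coordinate x0 + (i + .5) * ext / S - .5
    # (cell centres of both grids aligned).
    axes = [
        lo + (np.arange(s) + 0.5) * ext / s - 0.5
        for (lo, _), ext, s in zip(box, extents, cfg.lattice)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    order = 0 if cfg.interpolation == "nearest" else 1
    vals = ndimage.map_coordinates(
        mask.data.astype(np.float32), np.stack(coords), order=order, mode="nearest"
    )
    return LabelMask(data=vals >= 0.5)


def signed_distance(mask: LabelMask) -> np.ndarray:
    """Signed Euclidean distance to the nearest voxel of the opposite class.

    Positive inside the organ, negative outside, in lattice-voxel units.
    """
    data = mask.data
    n_fg = int(data.sum())
    if n_fg == 0 or n_fg == data.size:
        raise ValueError("signed distance needs both foreground and background voxels")
    inside = ndimage.distance_transform_edt(data)
    outside = ndimage.distance_transform_edt(~data)
    return np.where(data, inside, -outside)


def sigmoid_probability(d: np.ndarray, gain: float) -> np.ndarray:
    """Elementwise sigmoid 1 / (1 + exp(-gain * d)) of a signed-distance map."""
    if not gain > 0:
        raise ValueError(f"gain must be > 0, got {gain}")
    # Evaluated in a saturation-safe split form.
    d = np.asarray(d, dtype=float)
    out = np.empty_like(d)
    pos = d >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-gain * d[pos]))
    e = np.exp(gain * d[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def case_probability_map(mask: LabelMask, cfg: AtlasConfig) -> np.ndarray:
    """Single training case -> per-voxel sigmoid probability map on the lattice."""
    box = bounding_box(mask)
    resampled = resample_to_lattice(mask, box, cfg)
    return sigmoid_probability(signed_distance(resampled), cfg.gain)


def build_atlas(masks: Sequence[LabelMask], cfg: AtlasConfig) -> ProbabilisticAtlas:
    """Average the per-case probability maps into a probabilistic atlas."""
    if len(masks) == 0:
        raise ValueError("need at least one training mask")
    acc = np.zeros(cfg.lattice, dtype=float)
    for mask in masks:
        acc += case_probability_map(mask, cfg)
    return ProbabilisticAtlas(data=acc / len(masks))
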