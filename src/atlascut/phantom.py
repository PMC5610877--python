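"""Synthetic phantom cohorts and simulated seed strokes.

The phantoms emulate the situation the segmenter is built for: a smooth,
organ-like foreground object (a randomly deformed ellipsoid) embedded in a
darker background, with optional *distractor* structures that share the
organ's intensity distribution — the way neighbouring soft-tissue organs
share CT attenuation — so that a purely intensity-driven graph cut leaks
into them while an atlas prior can exclude them.  Seed strokes are small
spherical blobs sampled strictly inside the (eroded) ground truth for the
organ class and in an annulus just outside the (dilated) truth for the
background class, mimicking a user scribbling near the target organ.

Everything is deterministic given the spec's ``rng_seed``; the generator
uses numpy's PCG64 ``default_rng``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .types import LabelMask, SeedImage, Volume

__all__ = [
    "Distractor",
    "PhantomSpec",
    "CohortVariation",
    "make_phantom",
    "make_cohort",
    "simulate_seeds",
]


@dataclass
class Distractor:
    """An ellipsoidal structure present in the image but not in the truth.

    ``intensity = None`` copies the organ's intensity distribution (the
    confounding case).
    """

    center: tuple[float, float, float]
    axes: tuple[float, float, float]
    intensity: tuple[float, float] | None = None


@dataclass
class PhantomSpec:
    """Recipe for one phantom volume and its ground-truth mask."""

    shape: tuple[int, int, int] = (48, 48, 32)
    organ_center: tuple[float, float, float] | None = None  # None = volume centre
    organ_axes: tuple[float, float, float] = (11.0, 8.0, 6.0)
    deform_amplitude: float = 0.12  # fractional radial perturbation
    deform_frequency: int = 2
    organ_intensity: tuple[float, float] = (120.0, 6.0)  # mean, per-voxel sd
    background_intensity: tuple[float, float] = (60.0, 6.0)
    distractors: list[Distractor] = field(default_factory=list)
    noise_sd: float = 3.0
    rng_seed: int = 0

    def resolved_center(self) -> np.ndarray:
        if self.organ_center is not None:
            return np.asarray(self.organ_center, dtype=float)
        return (np.asarray(self.shape, dtype=float) - 1.0) / 2.0


def _deformed_ellipsoid(
    shape, center, axes, amplitude, frequency, rng: np.random.Generator
) -> np.ndarray:
    """Ellipsoid with a smooth sinusoidal radial perturbation."""
    grid = np.indices(shape).astype(float)
    d = grid - np.asarray(center).reshape(3, 1, 1, 1)
    scaled = d / np.asarray(axes).reshape(3, 1, 1, 1)
    rho = np.sqrt((scaled**2).sum(axis=0))
    if amplitude > 0:
        azimuth = np.arctan2(d[1], d[0])
        with np.errstate(invalid="ignore"):
            polar = np.arccos(np.clip(d[2] / np.maximum(np.linalg.norm(d, axis=0), 1e-9), -1, 1))
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        bump = amplitude * np.sin(frequency * azimuth + ph1) * np.cos(frequency * polar + ph2)
    else:
        bump = 0.0
    return rho <= 1.0 + bump


def make_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMask]:
    """Render one phantom: intensity volume plus ground-truth organ mask.

    Distractors appear only in the intensities, never in the mask.  The
    organ must sit fully inside the volume with a >= 2-voxel margin.
    """
    rng = np.random.default_rng(spec.rng_seed)
    center = spec.resolved_center()
    axes = np.asarray(spec.organ_axes, dtype=float)
    reach = axes * (1.0 + spec.deform_amplitude) + 2.0
    if np.any(center - reach < 0) or np.any(center + reach > np.asarray(spec.shape) - 1):
        raise ValueError("organ (plus 2-voxel margin) does not fit inside the volume")

    organ = _deformed_ellipsoid(
        spec.shape, center, axes, spec.deform_amplitude, spec.deform_frequency, rng
    )
    mu_bg, sd_bg = spec.background_intensity
    mu_org, sd_org = spec.organ_intensity
    vol = np.full(spec.shape, mu_bg, dtype=float)
    if sd_bg > 0:
        vol += rng.normal(0.0, sd_bg, size=spec.shape)
    for dis in spec.distractors:
        blob = _deformed_ellipsoid(spec.shape, dis.center, dis.axes, 0.0, 1, rng)
        mu_d, sd_d = dis.intensity if dis.intensity is not None else spec.organ_intensity
        vol[blob] = mu_d
        if sd_d > 0:
            vol[blob] += rng.normal(0.0, sd_d, size=int(blob.sum()))
    vol[organ] = mu_org
    if sd_org > 0:
        vol[organ] += rng.normal(0.0, sd_org, size=int(organ.sum()))
    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return Volume(data=vol), LabelMask(data=organ)


@dataclass
class CohortVariation:
    """Inter-case jitter emulating inter-patient variability.

    ``seed_stride`` offsets each case's rng seed; 0 (together with zero
    jitters) makes every case bit-identical.
    """

    center_jitter: float = 2.0  # voxels, uniform per axis
    axes_jitter: float = 0.12  # fractional, uniform per axis
    seed_stride: int = 1

    @classmethod
    def none(cls) -> "CohortVariation":
        return cls(center_jitter=0.0, axes_jitter=0.0, seed_stride=0)


def make_cohort(
    n: int,
    base_spec: PhantomSpec,
    variation: CohortVariation | None = None,
) -> list[tuple[Volume, LabelMask]]:
    """Generate ``n`` phantoms with jittered organ pose and axes."""
    if n < 2:
        raise ValueError("a cohort needs at least 2 cases")
    variation = variation or CohortVariation()
    jit_rng = np.random.default_rng([base_spec.rng_seed, 7919])
    center0 = base_spec.resolved_center()
    axes0 = np.asarray(base_spec.organ_axes, dtype=float)
    out = []
    for i in range(n):
        dc = jit_rng.uniform(-variation.center_jitter, variation.center_jitter, 3)
        da = 1.0 + jit_rng.uniform(-variation.axes_jitter, variation.axes_jitter, 3)
        spec_i = replace(
            base_spec,
            organ_center=tuple(center0 + dc),
            organ_axes=tuple(axes0 * da),
            rng_seed=base_spec.rng_seed + i * variation.seed_stride,
        )
        out.append(make_phantom(spec_i))
    return out


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    g = np.indices((2 * r + 1,) * 3) - r
    return (g**2).sum(axis=0) <= r * r


def _stamp_strokes(
    allowed: np.ndarray, n_strokes: int, radius: int, rng: np.random.Generator
) -> np.ndarray:
    """Spherical strokes centred on random allowed voxels, clipped to allowed."""
    out = np.zeros(allowed.shape, dtype=bool)
    centers = np.argwhere(allowed)
    if n_strokes == 0:
        return out
    if len(centers) == 0:
        raise ValueError("no admissible voxels to place strokes in")
    picks = centers[rng.choice(len(centers), size=n_strokes, replace=True)]
    ball = _ball(radius)
    r = radius
    for c in picks:
        lo = np.maximum(c - r, 0)
        hi = np.minimum(c + r + 1, np.asarray(allowed.shape))
        blo = lo - (c - r)
        bhi = ball.shape[0] - ((c + r + 1) - hi)
        region = tuple(slice(a, b) for a, b in zip(lo, hi))
        bregion = tuple(slice(a, b) for a, b in zip(blo, bhi))
        out[region] |= ball[bregion]
    return out & allowed


def simulate_seeds(
    truth: LabelMask,
    n_organ_strokes: int = 3,
    n_bg_strokes: int = 8,
    stroke_radius: int = 2,
    rng_seed: int = 0,
    erode: int = 2,
    bg_band: tuple[int, int] = (2, 7),
    alpha: float = 1.0,
) -> SeedImage:
    """Simulated user scribbles consistent with the ground truth.

    Organ strokes are confined to the truth eroded by ``erode`` voxels;
    background strokes to the annulus between the truth dilated by
    ``bg_band[0]`` and by ``bg_band[1]`` voxels (a user scribbles *near*
    the organ, not across the whole field of view).  Seeds therefore never
    contradict the truth.
    """
    if not truth.data.any():
        raise ValueError("truth mask is empty")
    rng = np.random.default_rng(rng_seed)
    labels = np.zeros(truth.shape, dtype=np.uint8)
    if n_organ_strokes > 0:
        interior = ndimage.binary_erosion(truth.data, iterations=erode)
        if not interior.any():
            raise ValueError(f"mask too thin to erode by {erode} voxels")
        labels[_stamp_strokes(interior, n_organ_strokes, stroke_radius, rng)] = 1
    if n_bg_strokes > 0:
        inner = ndimage.binary_dilation(truth.data, iterations=bg_band[0])
        outer = ndimage.binary_dilation(truth.data, iterations=bg_band[1])
        ring = outer & ~inner
        bg = _stamp_strokes(ring, n_bg_strokes, stroke_radius, rng) & ~inner
        bg &= labels == 0
        labels[bg] = 2
    return SeedImage(labels=labels, alpha=alpha)
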