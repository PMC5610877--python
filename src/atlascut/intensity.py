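"""Histogram intensity likelihoods and graph-cut data terms.

The class-conditional likelihoods Pr(v | organ) and Pr(v | background) are
empirical histograms of the voxel values inside the organ and background
seed regions, on a common binning spanning the test volume's intensity
range.  Empty bins are floored at a small mass epsilon and renormalized so
the negative-log data terms stay finite.

Without a prior the data terms are plain negative log likelihoods; with a
fitted atlas prior A* they become negative log posteriors

    R_PC(p) = -log( Pr(v_p | PC) * A*(p)       + eps )
    R_BG(p) = -log( Pr(v_p | BG) * (1 - A*(p)) + eps )

so the atlas acts as a per-voxel prior weighting of the organ hypothesis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .types import SeedImage, Volume

__all__ = ["IntensityHistogramModel", "fit_histograms", "data_term"]


@dataclass
class IntensityHistogramModel:
    bin_edges: np.ndarray  # (n_bins + 1,) monotone
    p_pc: np.ndarray  # per-bin organ masses, sum to 1
    p_bg: np.ndarray  # per-bin background masses, sum to 1
    floor: float = 1e-6

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.p_pc = np.asarray(self.p_pc, dtype=float)
        self.p_bg = np.asarray(self.p_bg, dtype=float)
        n = len(self.bin_edges) - 1
        if self.p_pc.shape != (n,) or self.p_bg.shape != (n,):
            raise ValueError("histogram masses must have one entry per bin")
        for name, m in (("p_pc", self.p_pc), ("p_bg", self.p_bg)):
            if abs(m.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {m.sum()}")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def _bin_of(self, values: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.bin_edges, values, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)

    def prob(self, values: np.ndarray, label: str) -> np.ndarray:
        """Per-voxel likelihood Pr(v | label) with label 'organ'/'background'."""
        masses = {"organ": self.p_pc, "background": self.p_bg}[label]
        return masses[self._bin_of(np.asarray(values, dtype=float))]

    def to_json(self) -> str:
        return json.dumps(
            {
                "bin_edges": self.bin_edges.tolist(),
                "p_pc": self.p_pc.tolist(),
                "p_bg": self.p_bg.tolist(),
                "floor": self.floor,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "IntensityHistogramModel":
        d = json.loads(text)
        return cls(
            bin_edges=np.array(d["bin_edges"]),
            p_pc=np.array(d["p_pc"]),
            p_bg=np.array(d["p_bg"]),
            floor=float(d["floor"]),
        )


def _floored(masses: np.ndarray, floor: float) -> np.ndarray:
    """Normalize, then clamp every bin to >= floor, rescaling the rest so
    the total stays 1 and no bin ends below the floor."""
    total = masses.sum()
    m = masses / total if total > 0 else np.full_like(masses, 1.0 / len(masses))
    for _ in range(10):
        low = m < floor
        if not low.any():
            break
        m[low] = floor
        scale = (1.0 - low.sum() * floor) / m[~low].sum()
        m[~low] *= scale
    return m


def fit_histograms(
    vol: Volume,
    seeds: SeedImage,
    n_bins: int = 64,
    floor: float = 1e-6,
) -> IntensityHistogramModel:
    """Per-class seed histograms over the volume's observed intensity range."""
    seeds.require_both_classes()
    if seeds.shape != vol.shape:
        raise ValueError(f"seed shape {seeds.shape} != volume shape {vol.shape}")
    data = np.asarray(vol.data, dtype=float)
    vmin, vmax = float(data.min()), float(data.max())
    if vmin == vmax:  # flat volume: widen so one valid bin range exists
        vmin, vmax = vmin - 0.5, vmax + 0.5
    edges = np.linspace(vmin, vmax, n_bins + 1)
    h_pc, _ = np.histogram(data[seeds.organ_mask], bins=edges)
    h_bg, _ = np.histogram(data[seeds.background_mask], bins=edges)
    return IntensityHistogramModel(
        bin_edges=edges,
        p_pc=_floored(h_pc.astype(float), floor),
        p_bg=_floored(h_bg.astype(float), floor),
        floor=floor,
    )


def data_term(
    model: IntensityHistogramModel,
    vol: Volume,
    prior: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel costs (R_PC, R_BG), optionally weighted by an atlas prior."""
    p_pc = model.prob(vol.data, "organ")
    p_bg = model.prob(vol.data, "background")
    if prior is None:
        return -np.log(p_pc), -np.log(p_bg)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != vol.shape:
        raise ValueError(f"prior shape {prior.shape} != volume shape {vol.shape}")
    if prior.size and (prior.min() < 0.0 or prior.max() > 1.0):
        raise ValueError("prior values must lie in [0, 1]")
    eps = model.floor
    return -np.log(p_pc * prior + eps), -np.log(p_bg * (1.0 - prior) + eps)
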