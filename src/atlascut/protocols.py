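"""Canonical benchmark protocols on synthetic phantom cohorts.

These bundle the study conditions used throughout the package's evaluation:
a 15-case cohort of deformed-ellipsoid organs with intensity-confounding
distractor structures (the conditions under which an intensity-only graph
cut leaks and an atlas prior should not), and an easier distractor-free
setting for the interactive refinement loop.  Fixing them here keeps tests,
examples and the reproduction script on identical inputs.
"""

from __future__ import annotations

import numpy as np

from .atlas import AtlasConfig
from .evaluate import CorrectiveSeedOracle, iterative_refinement, leave_one_out
from .graphcut import GraphCutConfig
from .homography import FitOptions
from .phantom import Distractor, PhantomSpec, make_cohort, simulate_seeds
from .types import LabelMask, SeedImage, Volume

__all__ = [
    "confounded_cohort_spec",
    "easy_refinement_spec",
    "evaluation_atlas_config",
    "evaluation_fit_options",
    "build_confounded_cohort",
    "run_headline_comparison",
    "run_refinement",
]

#: Atlas settings used by the benchmark protocols: a modest lattice with a
#: 25% padded border around the training boxes and unit sigmoid gain.
def evaluation_atlas_config() -> AtlasConfig:
    return AtlasConfig(lattice=(32, 32, 24), gain=1.0, margin=0.25)


def evaluation_fit_options(mode: str = "projective") -> FitOptions:
    cfg = evaluation_atlas_config()
    return FitOptions(mode=mode, target_fraction=1.0 / (1.0 + 2.0 * cfg.margin))


def confounded_cohort_spec(rng_seed: int = 11) -> PhantomSpec:
    """Organ plus two distractors drawn from the organ's own intensity
    distribution, as neighbouring soft-tissue structures are in CT."""
    return PhantomSpec(
        shape=(48, 48, 32),
        organ_center=(17.0, 22.0, 15.0),
        organ_axes=(9.0, 6.5, 5.0),
        distractors=[
            Distractor(center=(38.0, 30.0, 16.0), axes=(5.0, 5.0, 4.0)),
            Distractor(center=(36.0, 10.0, 14.0), axes=(4.0, 4.0, 3.5)),
        ],
        rng_seed=rng_seed,
    )


def easy_refinement_spec(rng_seed: int) -> PhantomSpec:
    """Distractor-free phantom with moderate contrast for the seed loop."""
    return PhantomSpec(
        shape=(40, 40, 28),
        organ_axes=(9.0, 7.0, 5.5),
        organ_intensity=(105.0, 7.0),
        background_intensity=(70.0, 7.0),
        noise_sd=3.0,
        rng_seed=rng_seed,
    )


def build_confounded_cohort(
    n: int = 15, rng_seed: int = 11
) -> list[tuple[Volume, LabelMask, SeedImage]]:
    """The 15-case benchmark cohort with per-case simulated seeds."""
    cohort = make_cohort(n, confounded_cohort_spec(rng_seed))
    return [
        (vol, truth, simulate_seeds(truth, rng_seed=rng_seed + 89 + i))
        for i, (vol, truth) in enumerate(cohort)
    ]


def run_headline_comparison(n: int = 15, rng_seed: int = 11):
    """Leave-one-out CGC-vs-AGC on the confounded cohort."""
    cases = build_confounded_cohort(n, rng_seed)
    return leave_one_out(
        cases,
        atlas_cfg=evaluation_atlas_config(),
        gc_cfg=GraphCutConfig(),
        fit_opts=evaluation_fit_options(),
    )


def run_refinement(rng_seed: int, max_rounds: int = 5):
    """One interactive-loop replay on an easy phantom."""
    from .phantom import make_phantom

    vol, truth = make_phantom(easy_refinement_spec(rng_seed))
    seeds = simulate_seeds(
        truth, n_organ_strokes=4, n_bg_strokes=8, stroke_radius=3, rng_seed=rng_seed + 100
    )
    return iterative_refinement(
        vol,
        truth,
        seeds,
        oracle=CorrectiveSeedOracle(strokes_per_class=5),
        max_rounds=max_rounds,
        n_bins=32,
    )
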