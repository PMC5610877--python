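"""Conventional vs atlas-weighted graph cut on a confounded phantom.

The phantom contains a distractor blob drawn from the organ's own
intensity distribution.  An intensity-only graph cut (CGC) leaks into it;
weighting the data term with the fitted atlas prior (AGC) excludes it.
"""

from atlascut import jaccard, segment
from atlascut.evaluate import fit_and_warp
from atlascut.protocols import (
    build_confounded_cohort,
    evaluation_atlas_config,
    evaluation_fit_options,
)
from atlascut.atlas import build_atlas

cases = build_confounded_cohort(n=5, rng_seed=11)
vol, truth, seeds = cases[0]
atlas = build_atlas([t for _, t, _ in cases[1:]], evaluation_atlas_config())

seg_cgc = segment(vol, seeds)
prior = fit_and_warp(atlas, seeds, vol.shape, evaluation_fit_options())
seg_agc = segment(vol, seeds, atlas_prior=prior)

fp_cgc = (seg_cgc.data & ~truth.data).sum()
fp_agc = (seg_agc.data & ~truth.data).sum()
print(f"Jaccard, intensity-only cut (CGC): {jaccard(seg_cgc, truth):.3f}  ({fp_cgc} false-positive voxels)")
print(f"Jaccard, atlas-weighted cut (AGC): {jaccard(seg_agc, truth):.3f}  ({fp_agc} false-positive voxels)")
# The CGC false positives are the distractor; the atlas prior assigns it
# near-zero organ probability, so the AGC labels it background.
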