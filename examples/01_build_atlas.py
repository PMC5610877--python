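"""Build a probabilistic atlas from a small phantom cohort.

Generates 8 organ-like phantoms with inter-case shape jitter, averages
their signed-distance sigmoid maps on a common lattice, and prints where
the atlas is confident.
"""

import numpy as np

from atlascut import AtlasConfig, PhantomSpec, build_atlas, make_cohort

cohort = make_cohort(8, PhantomSpec(rng_seed=1))
masks = [mask for _, mask in cohort]

cfg = AtlasConfig(lattice=(32, 32, 24), gain=1.0, margin=0.25)
atlas = build_atlas(masks, cfg)

core = (atlas.data > 0.9).sum()
uncertain = ((atlas.data > 0.25) & (atlas.data < 0.75)).sum()
print(f"atlas lattice: {atlas.shape}, values in ({atlas.data.min():.4f}, {atlas.data.max():.4f})")
print(f"confident organ core (>0.9): {core} voxels")
print(f"uncertain boundary band (0.25-0.75): {uncertain} voxels")
# The core is where every training organ overlaps after box normalization;
# the band is the inter-case boundary variability the atlas encodes.
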