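"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library's own code paths: the min-cut oracle
enumerates every labeling and evaluates the energy directly from its
definition, and the signed-distance oracle compares all voxel pairs.
"""

import numpy as np


def enumerate_min_energy(vol_data, seeds, terms, lam, sigma, normalize=True):
    """Exhaustive minimum of E = B + lam*R over seed-consistent labelings.

    Returns (best energy, energy of every consistent labeling is >= best).
    Volumes must have at most ~16 voxels.
    """
    shape = vol_data.shape
    n = int(np.prod(shape))
    v = np.asarray(vol_data, float)
    if normalize:
        lo, hi = v.min(), v.max()
        v = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    r_pc, r_bg = (np.asarray(t, float).ravel() for t in terms)
    # neighbour pair list with boundary weights
    pairs = []
    weights = []
    index = np.arange(n).reshape(shape)
    for off in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]:
        sl_p = tuple(slice(0, s - o) for s, o in zip(shape, off))
        sl_q = tuple(slice(o, s) for s, o in zip(shape, off))
        p, q = index[sl_p].ravel(), index[sl_q].ravel()
        pairs.append(np.stack([p, q], 1))
        dv = v.ravel()[p] - v.ravel()[q]
        weights.append(np.exp(-dv * dv / (2 * sigma * sigma)))
    pairs = np.concatenate(pairs) if pairs else np.empty((0, 2), int)
    weights = np.concatenate(weights) if weights else np.empty(0)

    labelings = (
        (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
    ).astype(bool)
    organ = seeds.organ_mask.ravel()
    bg = seeds.background_mask.ravel()
    ok = labelings[:, organ].all(axis=1) & (~labelings[:, bg]).all(axis=1)
    labelings = labelings[ok]
    data = labelings @ r_pc + (~labelings) @ r_bg
    boundary = (labelings[:, pairs[:, 0]] != labelings[:, pairs[:, 1]]) @ weights
    return float((boundary + lam * data).min())


def rim_shell_seeds(truth):
    """Dense deterministic seeds: a 2-voxel organ shell just inside the
    boundary and a 2-voxel background shell just outside.  Covering both
    sides of the boundary makes the atlas-fit energy sharply curved, so the
    pose optimum is well-conditioned."""
    from scipy import ndimage

    from atlascut import SeedImage

    t = truth.data
    organ = ndimage.binary_erosion(t, iterations=1) & ~ndimage.binary_erosion(
        t, iterations=3
    )
    bg = ndimage.binary_dilation(t, iterations=3) & ~ndimage.binary_dilation(
        t, iterations=1
    )
    labels = np.zeros(t.shape, np.uint8)
    labels[organ] = 1
    labels[bg] = 2
    return SeedImage(labels)


def grid_search_translation(atlas, seeds, h_base, radius=4.0, step=0.25):
    """Independent pose oracle: dense (chunked) grid search over 3D
    translations of the atlas-fit energy."""
    from atlascut import apply_homography, sample_atlas

    sv = seeds.numeric()
    pts = np.argwhere(sv != 0).astype(float)
    s = sv[sv != 0]
    base = apply_homography(h_base, pts)
    r = np.arange(-radius, radius + 1e-9, step)
    grid = np.stack(np.meshgrid(r, r, r, indexing="ij"), -1).reshape(-1, 3)
    best_e, best_t = np.inf, None
    for chunk in np.array_split(grid, max(1, len(grid) // 256)):
        coords = (base[None, :, :] + chunk[:, None, :]).reshape(-1, 3)
        vals = sample_atlas(atlas, coords).reshape(len(chunk), -1)
        energies = vals @ s
        k = int(np.argmin(energies))
        if energies[k] < best_e:
            best_e, best_t = float(energies[k]), chunk[k]
    return best_t, best_e


def brute_signed_distance(data):
    """All-pairs squared-Euclidean signed distance (integer-exact)."""
    pts = np.indices(data.shape).reshape(3, -1).T
    fg = pts[data.ravel()]
    bg = pts[~data.ravel()]
    d2_fg = ((pts[:, None, :] - bg[None, :, :]) ** 2).sum(-1).min(1)
    d2_bg = ((pts[:, None, :] - fg[None, :, :]) ** 2).sum(-1).min(1)
    inside = data.ravel()
    d2 = np.where(inside, d2_fg, d2_bg).reshape(data.shape)
    sign = np.where(data, 1.0, -1.0)
    return sign * d2  # signed *squared* distance, for exact comparison
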