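"""Fitting the probabilistic atlas to seed voxels with a 3D homography.

A 4x4 projective matrix ``H`` maps test-image voxel coordinates into atlas
lattice coordinates: ``(X', Y', Z', W')^T = H (x, y, z, 1)^T`` followed by
division by ``W'``.  The fidelity energy

    E_H = sum over seed voxels of  A(H(x, y, z)) * S(x, y, z)

(with ``S = -1`` on organ seeds and ``+alpha`` on background seeds) is
minimized by steepest descent with a backtracking line search: lowering E_H
pulls high atlas probability onto organ seeds and off background seeds.
Constrained modes restrict the free parameters to a pure translation
(3 dof, the behaviour of an earlier translation-only fitting scheme),
an affine map (12 dof) or the full projective transform (15 dof, the
``h44`` entry being gauge-fixed to 1 because ``H`` and ``cH`` describe the
same map).

Internally the optimizer works in a normalized seed frame (seed centroid at
the origin, seed bounding box scaled to roughly [-1, 1]^3) so that all free
parameters have comparable sensitivity; the reported homography is always in
raw image-voxel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ProbabilisticAtlas, SeedImage

__all__ = [
    "Homography",
    "FitOptions",
    "FitResult",
    "DegenerateProjectionError",
    "OptimizationError",
    "apply_homography",
    "sample_atlas",
    "sample_atlas_with_gradient",
    "fidelity_energy",
    "initial_homography",
    "fit_homography",
    "fit_homography_staged",
    "warp_atlas_to_image",
]

MODES = ("translation", "affine", "projective")


class DegenerateProjectionError(ValueError):
    """The homogeneous coordinate W' vanished during projection."""


class OptimizationError(RuntimeError):
    """The energy became non-finite during the descent."""


@dataclass
class Homography:
    """A 4x4 projective transform from image coordinates to atlas coordinates."""

    matrix: np.ndarray
    det_epsilon: float = 1e-9

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"homography matrix must be 4x4, got {m.shape}")
        if abs(np.linalg.det(m)) <= self.det_epsilon:
            raise ValueError("homography matrix is (near-)singular")
        self.matrix = m

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(4))

    @classmethod
    def translation(cls, t) -> "Homography":
        m = np.eye(4)
        m[:3, 3] = t
        return cls(m)

    @classmethod
    def affine(cls, linear, t=(0.0, 0.0, 0.0)) -> "Homography":
        m = np.eye(4)
        m[:3, :3] = linear
        m[:3, 3] = t
        return cls(m)

    def compose(self, other: "Homography") -> "Homography":
        """Return self applied after ``other`` (self @ other)."""
        return Homography(self.matrix @ other.matrix)

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    def normalized(self) -> "Homography":
        """Rescale so that h44 = 1 (the gauge used by the optimizer)."""
        h44 = self.matrix[3, 3]
        if abs(h44) < 1e-12:
            raise ValueError("cannot normalize: h44 is zero")
        return Homography(self.matrix / h44)


def apply_homography(h: Homography, points, w_epsilon: float = 1e-9) -> np.ndarray:
    """Map points ``(..., 3)`` through H with the projective W' division."""
    pts = np.asarray(points, dtype=float)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    hom = np.concatenate([pts, np.ones((len(pts), 1))], axis=1)
    proj = hom @ h.matrix.T
    w = proj[:, 3]
    if np.any(np.abs(w) <= w_epsilon):
        raise DegenerateProjectionError(
            "projection degenerate: |W'| <= epsilon at some point"
        )
    out = proj[:, :3] / w[:, None]
    return out[0] if squeeze else out


def _trilinear(data: np.ndarray, coords: np.ndarray, outside: float):
    """Vectorized trilinear interpolation with constant `outside` padding.

    Returns (values, gradients, inbounds-mask); gradients are the spatial
    derivative of the interpolant, zero wherever the point lies fully
    outside the padded support.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    shape = np.array(data.shape)
    padded = np.pad(data.astype(float), 1, constant_values=outside)
    c = coords + 1.0  # coordinates in the padded grid
    # Fully outside: beyond one voxel of padding on any axis.
    valid = np.all((c >= 0.0) & (c <= shape + 1.0), axis=1)
    cc = np.clip(c, 0.0, shape + 1.0 - 1e-9)
    i0 = np.floor(cc).astype(int)
    i0 = np.minimum(i0, shape)  # keep i0+1 a valid padded index
    f = cc - i0
    x0, y0, z0 = i0.T
    fx, fy, fz = f.T
    g = lambda dx, dy, dz: padded[x0 + dx, y0 + dy, z0 + dz]
    c000, c001 = g(0, 0, 0), g(0, 0, 1)
    c010, c011 = g(0, 1, 0), g(0, 1, 1)
    c100, c101 = g(1, 0, 0), g(1, 0, 1)
    c110, c111 = g(1, 1, 0), g(1, 1, 1)
    c00 = c000 * (1 - fz) + c001 * fz
    c01 = c010 * (1 - fz) + c011 * fz
    c10 = c100 * (1 - fz) + c101 * fz
    c11 = c110 * (1 - fz) + c111 * fz
    c0 = c00 * (1 - fy) + c01 * fy
    c1 = c10 * (1 - fy) + c11 * fy
    values = c0 * (1 - fx) + c1 * fx
    # Analytic gradient of the trilinear interpolant.
    dx = c1 - c0
    dy = (c01 - c00) * (1 - fx) + (c11 - c10) * fx
    dz = (
        (c001 - c000) * (1 - fy) + (c011 - c010) * fy
    ) * (1 - fx) + ((c101 - c100) * (1 - fy) + (c111 - c110) * fy) * fx
    grads = np.stack([dx, dy, dz], axis=1)
    values = np.where(valid, values, outside)
    grads[~valid] = 0.0
    return values, grads, valid


def sample_atlas(
    atlas: ProbabilisticAtlas, coords, outside: float = 0.0
) -> np.ndarray | float:
    """Trilinear probability lookup; coordinates off the lattice return
    ``outside`` (default 0: certainly not organ)."""
    arr = np.asarray(coords, dtype=float)
    values, _, _ = _trilinear(atlas.data, arr, outside)
    return float(values[0]) if arr.ndim == 1 else values


def sample_atlas_with_gradient(atlas: ProbabilisticAtlas, coords, outside: float = 0.0):
    values, grads, _ = _trilinear(atlas.data, coords, outside)
    return values, grads


def _seed_points(seeds: SeedImage) -> tuple[np.ndarray, np.ndarray]:
    seeds.require_both_classes()
    s = seeds.numeric()
    idx = np.argwhere(s != 0.0)
    return idx.astype(float), s[tuple(idx.T)]


def fidelity_energy(
    atlas: ProbabilisticAtlas,
    seeds: SeedImage,
    h: Homography,
    outside: float = 0.0,
) -> float:
    """E_H = sum over seed voxels of A(H(x,y,z)) * S(x,y,z)."""
    pts, svals = _seed_points(seeds)
    probs = sample_atlas(atlas, apply_homography(h, pts), outside=outside)
    return float(np.sum(probs * svals))


@dataclass
class FitOptions:
    """Steepest-descent settings for the atlas fit."""

    mode: str = "projective"
    max_iters: int = 500
    tol: float = 1e-6
    gradient: str = "fd"  # "fd" (central differences) or "analytic"
    fd_step: float = 1e-4
    init_margin: float = 1.1
    target_fraction: float = 1.0  # lattice fraction the training organ boxes span
    outside: float = 0.0
    max_backtracks: int = 40

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.gradient not in ("fd", "analytic"):
            raise ValueError(f"gradient must be 'fd' or 'analytic', got {self.gradient!r}")


@dataclass
class FitResult:
    homography: Homography
    energy: float
    trajectory: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def _free_indices(mode: str) -> list[tuple[int, int]]:
    if mode == "translation":
        return [(0, 3), (1, 3), (2, 3)]
    if mode == "affine":
        return [(i, j) for i in range(3) for j in range(4)]
    return [(i, j) for i in range(4) for j in range(4) if (i, j) != (3, 3)]


def _normalization(seeds: SeedImage) -> np.ndarray:
    """Affine N with q = (p - centroid) / halfextent, per axis."""
    pts, svals = _seed_points(seeds)
    organ = pts[svals < 0]
    c = organ.mean(axis=0)
    half = np.maximum((organ.max(axis=0) - organ.min(axis=0)) / 2.0, 1.0)
    n = np.eye(4)
    n[:3, :3] = np.diag(1.0 / half)
    n[:3, 3] = -c / half
    return n


def initial_homography(
    atlas: ProbabilisticAtlas,
    seeds: SeedImage,
    margin: float = 1.1,
    target_fraction: float = 1.0,
) -> Homography:
    """Default starting pose: organ-seed centroid to lattice centre, axes
    scaled so the seed bounding box (times ``margin``) spans the central
    ``target_fraction`` of the lattice.

    When the atlas was built with a fractional box margin ``m``, the
    training organs occupy the central ``1 / (1 + 2m)`` of the lattice;
    passing that as ``target_fraction`` aligns the seed extent with the
    organ region of the atlas rather than with its padded border.
    """
    n = _normalization(seeds)
    g = np.eye(4)
    half_lat = (np.array(atlas.shape) - 1) / 2.0
    g[:3, :3] = np.diag(half_lat * target_fraction / margin)
    g[:3, 3] = half_lat
    return Homography(g @ n)


def fit_homography(
    atlas: ProbabilisticAtlas,
    seeds: SeedImage,
    init: Homography | None = None,
    opts: FitOptions | None = None,
) -> FitResult:
    """Minimize the fidelity energy over the free homography parameters.

    Steepest descent with backtracking (halving) line search; stops when the
    accepted energy decrease falls below ``tol * (1 + |E|)``, the line search
    fails to find any decrease, or ``max_iters`` is reached.
    """
    opts = opts or FitOptions()
    pts, svals = _seed_points(seeds)
    norm = _normalization(seeds)
    norm_inv = np.linalg.inv(norm)
    if init is None:
        g0 = (
            initial_homography(
                atlas, seeds, margin=opts.init_margin, target_fraction=opts.target_fraction
            ).matrix
            @ norm_inv
        )
    else:
        g0 = init.matrix @ norm_inv
        if abs(g0[3, 3]) < 1e-12:
            raise OptimizationError("initial homography has h44 = 0 in the seed frame")
        g0 = g0 / g0[3, 3]
    free = _free_indices(opts.mode)
    rows = np.array([i for i, _ in free])
    cols = np.array([j for _, j in free])

    q = (np.concatenate([pts, np.ones((len(pts), 1))], axis=1) @ norm.T)

    def project(g: np.ndarray):
        proj = q @ g.T
        w = proj[:, 3]
        bad = np.abs(w) <= 1e-9
        if bad.any():
            return None, None
        return proj[:, :3] / w[:, None], w

    def energy(g: np.ndarray) -> float:
        x, w = project(g)
        if x is None:
            return np.inf
        vals, _, _ = _trilinear(atlas.data, x, opts.outside)
        return float(np.sum(vals * svals))

    def grad_analytic(g: np.ndarray) -> np.ndarray:
        x, w = project(g)
        if x is None:
            raise OptimizationError("degenerate projection while computing gradient")
        vals, ga, _ = _trilinear(atlas.data, x, opts.outside)
        out = np.zeros(len(free))
        winv = 1.0 / w
        for k, (i, j) in enumerate(free):
            if i < 3:
                dxdh = q[:, j] * winv  # affects coordinate i only
                out[k] = np.sum(svals * ga[:, i] * dxdh)
            else:  # bottom row: all three coordinates scale as -X_k q_j / W'
                out[k] = np.sum(svals * (ga * x).sum(axis=1) * (-q[:, j] * winv))
        return out

    def grad_fd(g: np.ndarray) -> np.ndarray:
        out = np.zeros(len(free))
        h = opts.fd_step
        for k, (i, j) in enumerate(free):
            gp = g.copy()
            gp[i, j] += h
            gm = g.copy()
            gm[i, j] -= h
            out[k] = (energy(gp) - energy(gm)) / (2 * h)
        return out

    grad = grad_analytic if opts.gradient == "analytic" else grad_fd

    g = g0.copy()
    e = energy(g)
    if not np.isfinite(e):
        raise OptimizationError("non-finite energy at the initial homography")
    trajectory = [e]
    converged = False
    step = None
    it = 0
    for it in range(1, opts.max_iters + 1):
        gr = grad(g)
        gnorm = np.max(np.abs(gr))
        if not np.isfinite(gnorm):
            raise OptimizationError("non-finite gradient during descent")
        if gnorm < 1e-14:
            converged = True
            break
        if step is None:
            step = 0.25 / gnorm  # first trial moves the largest parameter by 0.25
        t = step
        accepted = False
        for _ in range(opts.max_backtracks):
            g_new = g.copy()
            g_new[rows, cols] -= t * gr
            e_new = energy(g_new)
            if e_new < e - 1e-15:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            converged = True
            break
        g = g_new
        trajectory.append(e_new)
        step = t * 2.0
        if abs(e - e_new) < opts.tol * (1.0 + abs(e_new)):
            e = e_new
            converged = True
            break
        e = e_new
    # Back to raw image coordinates.
    h_final = Homography(g @ norm)
    return FitResult(
        homography=h_final.normalized(),
        energy=e,
        trajectory=trajectory,
        converged=converged,
        n_iter=it,
    )


def fit_homography_staged(
    atlas: ProbabilisticAtlas,
    seeds: SeedImage,
    init: Homography | None = None,
    opts: FitOptions | None = None,
) -> FitResult:
    """Warm-started fit: translation, then affine, then projective.

    Steepest descent on the full 15-parameter problem is sensitive to the
    starting point; optimizing the nested transform families in order of
    increasing freedom keeps each stage near its basin.  Stops at
    ``opts.mode`` (so ``mode="translation"`` reproduces a single-stage
    translation-only fit).
    """
    from dataclasses import replace as _replace

    opts = opts or FitOptions()
    stages = MODES[: MODES.index(opts.mode) + 1]
    res: FitResult | None = None
    h = init
    for mode in stages:
        res = fit_homography(atlas, seeds, init=h, opts=_replace(opts, mode=mode))
        h = res.homography
    return res


def warp_atlas_to_image(
    atlas: ProbabilisticAtlas,
    h: Homography,
    shape: tuple[int, int, int],
    outside: float = 0.0,
) -> np.ndarray:
    """Fitted prior A* on the test grid: A*(p) = A(H(p)) for every voxel p."""
    grid = np.indices(shape).reshape(3, -1).T.astype(float)
    coords = apply_homography(h, grid)
    values, _, _ = _trilinear(atlas.data, coords, outside)
    return values.reshape(shape)
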