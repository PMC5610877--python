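# Methods

## Model

The segmenter combines two sources of information: user-marked seed voxels
(hard anatomical evidence) and a probabilistic atlas (statistical shape
evidence), fused inside a binary graph-cut energy.

**Atlas construction.** Each training mask is cropped to the bounding box
of its organ, optionally expanded by a fractional margin, and resampled to
a common lattice with nearest-neighbour interpolation (the mask stays
exactly binary; linear interpolation with a 0.5 threshold is available as a
config flag). The signed Euclidean distance transform — distance in lattice
voxels to the nearest voxel of the opposite class, positive inside — is
pushed through the sigmoid `1 / (1 + exp(-a_p d))` and the per-case sigmoid
maps are averaged. The result is a per-voxel organ probability on the
lattice: ≈1 in the common core, ≈0 far outside, with a transition band
whose width reflects both the gain `a_p` and inter-case shape variability.
Distances are consumed dimensionlessly by the gain, so all atlas math is in
lattice-voxel units; physical spacing is carried only for I/O fidelity.

**Seed images.** Seeds are a ternary label volume (0 none, 1 organ,
2 background) rather than GUI strokes, so runs are reproducible headlessly.
The numeric view used by the fitting energy maps organ seeds to −1,
background seeds to +α (default α = 1, weighting the two classes
symmetrically) and everything else to 0. Seed updates are strictly
additive; a voxel can never hold both labels.

**Homography fitting.** A 4×4 projective matrix maps image coordinates to
atlas coordinates, with the usual division by the fourth homogeneous
coordinate. The fidelity energy is the sum over seed voxels of
atlas probability × signed seed value; since unlabeled voxels contribute
zero, the sum is evaluated over seed voxels only. Minimization is steepest
descent over the free matrix entries with a backtracking (halving) line
search; the trajectory of accepted energies is therefore non-increasing by
construction. Because a homography and any nonzero scalar multiple of it
define the same map, the `h44` entry is gauge-fixed to 1, leaving 15 free
parameters (3 in `translation` mode, 12 in `affine` mode).

Three choices matter for making this optimization behave:

- *Seed-frame preconditioning.* The descent runs in a normalized frame
  (organ-seed centroid at the origin, seed bounding box scaled to roughly
  [-1, 1]³) so all free parameters have comparable sensitivity; the
  reported matrix is always in raw voxel coordinates.
- *Warm-started stages.* `fit_homography_staged` optimizes translation,
  then affine, then projective, each stage initialized from the last.
  Plain 15-parameter steepest descent from a cold start is prone to poor
  local minima; the nested families keep each stage near its basin.
- *Initialization.* The default start maps the organ-seed bounding box
  (times a margin, default 1.1) onto the central fraction of the lattice
  that the training organ boxes occupy (`target_fraction`; 1/(1+2m) for an
  atlas built with box margin m).

Gradients default to central finite differences (step 1e-4 per entry); an
analytic gradient through the trilinear interpolant is available and agrees
with the numerical one on smooth test poses. Atlas sampling is trilinear
with a constant outside value of 0 ("certainly not organ"), which both
prevents the prior from hallucinating organ beyond the lattice and
penalizes transforms that throw organ seeds off the atlas support.

**Graph cut.** The energy is `E = B + λ·R` — note the trade-off weight
multiplies the *data* term, which follows the formulation this package
implements rather than the more common convention of weighting the
boundary term. The boundary weight is
`exp(-(v_p - v_q)² / 2σ²) / dist(p, q)` on min-max normalized intensities;
σ = 1/√2 (the default) makes it exactly `exp(-Δv²)/dist`. Neighbourhoods
are 6- or 26-connected with voxel-unit (optionally spacing-scaled)
distances. Data terms are negative log likelihoods from per-class seed
histograms (64 equal-width bins over the observed intensity range by
default), ε-floored so every capacity is finite; with a prior they become
negative log posteriors with the same ε guarding saturated prior values.
The binary energy is submodular, so the s-t min-cut (solved exactly with
igraph's max-flow) is a global optimum. Seeds get terminal capacities of
10× the total finite capacity, which no minimum cut can sever, so seed
labels are guaranteed in the output. A flat prior of 0.5 shifts both data
terms by the same constant and provably reproduces the no-prior labeling.

**Evaluation.** Jaccard index on voxel counts, with the artifact-defined
conventions JI(∅, ∅) = 1 and JI(∅, nonempty) = 0. The leave-one-out driver
computes each case's per-case sigmoid map once and averages all-but-one,
then runs the conventional cut (CGC) and the atlas-weighted cut (AGC) on
identical seeds. The interactive protocol replaces the human with a
deterministic corrective oracle: each round it takes the largest connected
false-negative and false-positive components, stamps a small spherical
stroke at each component's innermost voxel (arg-max of the component's
distance transform), clipped to the component so seeds never contradict
ground truth, refits the atlas to the grown seed set, and re-segments.
The human time budget of the interactive setting is replaced by a round
count.

## Synthetic phantoms

The generator emulates the structure of the clinical problem, not its
appearance: a smooth organ (ellipsoid with a low-frequency sinusoidal
radial deformation) on a darker background, Gaussian intensity texture and
noise, and *distractor* blobs that share the organ's intensity
distribution — the way neighbouring soft-tissue organs share CT
attenuation. Distractors appear in the intensities but never in the truth
mask, which is exactly the failure mode that separates an intensity-only
cut from an atlas-weighted one. Simulated scribbles are spherical strokes
strictly inside the eroded truth (organ) and in an annulus just outside the
dilated truth (background) — a user scribbles near the organ, not across
the whole field of view. Everything is deterministic given the spec's
`rng_seed` (numpy PCG64).

What the phantoms do **not** model: CT noise structure (streaks, beam
hardening), partial-volume boundaries, anatomically realistic shapes or
poses, contact between organ and distractor, and human seed-placement
behaviour. Passing results therefore demonstrate the mechanics of the
method — the prior excluding intensity confounders, the loop converging —
on favorable geometry, and say nothing quantitative about clinical CT.

## Benchmark protocols and problem sizes

`atlascut.protocols` freezes the study conditions used by the tests,
examples and `scripts/acceptance.py`:

- **Headline comparison**: 15 cases of 48×48×32 voxels, organ half-axes
  ≈ (9, 6.5, 5) with pose/axis jitter, two same-intensity distractors,
  organ 120±6 vs background 60±6 with additive σ=3 noise; atlas lattice
  32×32×24, gain 1.0, box margin 0.25; projective staged fit; λ = 1,
  6-connectivity. Leave-one-out under these conditions gives mean Jaccard
  ≈ 0.65 for the plain cut vs ≈ 0.90 for the atlas-weighted cut.
- **Interactive loop**: distractor-free 40×40×28 phantoms at moderate
  contrast (105±7 vs 70±7, noise 3), 4 organ / 8 background strokes of
  radius 3, 32 histogram bins, up to 5 corrective strokes per class and
  round.

These sizes are deliberate scale-downs of the clinical setting (512×512
slices) chosen so a full leave-one-out runs in minutes on one CPU; the
phenomena being measured (confounder exclusion, corrective convergence) do
not depend on absolute volume size.

## Numerical choices and degenerate inputs

- Histogram floor: empirical −log likelihoods are infinite on empty bins;
  bins are clamped to ε = 1e-6 with the remaining mass rescaled so floored
  bins stay exactly at ε and totals stay 1.
- Projection guard: |W′| ≤ 1e-9 raises a degenerate-projection error;
  singular matrices are rejected at construction.
- Descent stopping: accepted decrease below `tol · (1 + |E|)`
  (tol = 1e-6 by default), a failed line search (40 halvings), or
  `max_iters`.
- Graph-cut ties are resolved by the solver's deterministic cut; tests
  avoid exact ties.
- A solid cuboid mask resampled on its tight bounding box has no
  background voxels, so its signed distance is undefined; atlas
  construction raises in that case (a box margin > 0 avoids it, and real
  organ shapes are not axis-aligned cuboids).
- The pose-recovery benchmark uses dense rim-shell seeds (2-voxel shells
  either side of the boundary). Sparse random scribbles can leave the
  pose energy nearly flat along some directions, in which case "the"
  optimal translation is ill-conditioned even though the energies agree;
  shells keep the optimum sharply curved and the comparison against the
  grid-search oracle meaningful.

## Known limitations

- Steepest descent on the full projective family can still underperform
  the affine stage on occasional cases; the staged warm start mitigates
  but does not eliminate this.
- The atlas prior multiplies the likelihood voxelwise; there is no
  spatial regularization of the prior itself, so a badly fitted pose
  degrades the data term everywhere at once.
- With very small seed sets the class histograms are fragile: a handful of
  corrective strokes in dim rim regions can broaden the organ model and
  transiently grow false positives before later rounds correct them.
- Only binary (organ vs background) segmentation; no multi-label support.
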