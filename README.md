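# atlascut

Interactive, atlas-weighted graph-cut segmentation of 3D organ volumes.

Segmenting a low-contrast organ such as the pancreas in abdominal CT is hard
for purely automatic methods (atypical shapes break shape priors) and tedious
for purely manual ones. `atlascut` implements the interactive middle ground:
a user marks a few *seed voxels* as organ or background, a statistical shape
prior — a **probabilistic atlas** — is warped onto those seeds, and an exact
graph cut produces the segmentation, with the user free to add corrective
seeds and iterate. The package targets researchers who want a reproducible,
scriptable implementation of this pipeline: there is no GUI, seeds live in
label volumes, and a synthetic phantom generator stands in for clinical data.

## Method

**Probabilistic atlas.** Training organ masks are cropped to their bounding
boxes, resampled to a common lattice $S_x \times S_y \times S_z$, and turned
into per-voxel organ probabilities via the sigmoid of the signed Euclidean
distance $d$ to the organ boundary (positive inside),

$$\varsigma(d; a_p) = \frac{1}{1 + e^{-a_p d}},$$

then averaged over cases: $A(x,y,z)$ is the empirical probability that a
box-normalized voxel lies inside the organ.

**Seed fitting by 3D homography.** Seeds form a ternary image
$S(x,y,z) \in \{-1, \alpha, 0\}$ (organ, background, unlabeled). A 4×4
projective matrix $H$ maps image coordinates to atlas coordinates
($P' = H p$, then division by the fourth component $W'$), and is chosen by
steepest descent to minimize the fidelity energy

$$E_H = \sum_{x,y,z} A(X, Y, Z)\, S(x,y,z),$$

which rewards putting high atlas probability on organ seeds and off
background seeds. Constrained modes (`translation`, `affine`, `projective`)
are available; the projective fit is warm-started through the nested
families.

**Atlas-weighted graph cut.** Segmentation minimizes
$E(\Omega) = B(\Omega) + \lambda R(\Omega)$ exactly by s-t min-cut:
$B$ penalizes label changes between similar neighbours with
$\exp(-(v_p - v_q)^2 / 2\sigma^2)/\mathrm{dist}(p,q)$, and $R$ sums per-voxel
negative log likelihoods from seed-region intensity histograms. With the
fitted prior $A^*$ the data term becomes the negative log posterior
$-\log(\Pr(v_p\,|\,\mathrm{PC}) \cdot A^*(p) + \epsilon)$ and
$-\log(\Pr(v_p\,|\,\mathrm{BG}) \cdot (1 - A^*(p)) + \epsilon)$ — so
structures that merely *look* like the organ but lie outside the atlas
support are rejected. Seeds are hard constraints. Accuracy is scored with
the Jaccard index $JI(E,G) = |E \cap G| / |E \cup G|$.

## Worked example

`examples/03_segment_with_and_without_prior.py` builds a 5-case phantom
cohort in which a distractor blob shares the organ's intensity
distribution, builds the atlas from four cases, and segments the fifth:

```
Jaccard, intensity-only cut (CGC): 0.671  (650 false-positive voxels)
Jaccard, atlas-weighted cut (AGC): 0.989  (0 false-positive voxels)
```

The 650 false positives of the conventional cut are exactly the distractor,
which is indistinguishable from the organ by intensity alone; the fitted
atlas assigns it near-zero prior probability, so the atlas-weighted cut
excludes it. The other examples cover atlas building, seed fitting
(`E_H` dropping from −81.8 to −103.8 against a −106 lower bound),
leave-one-out evaluation, and the corrective-seeding loop (Jaccard
0.986 → 1.000 in three rounds). Each is a short script you can read
top to bottom.

A thin CLI mirrors the library for shell pipelines:

```bash
atlascut simulate --spec spec.yaml -o cohort/
atlascut build-atlas --masks cohort/case00_mask.nii.gz ... -o atlas.nii.gz
atlascut fit --atlas atlas.nii.gz --seeds seeds.nii.gz -o prior.nii.gz
atlascut segment --volume v.nii.gz --seeds seeds.nii.gz --prior prior.nii.gz -o mask.nii.gz
atlascut evaluate --cohort cohort/manifest.yaml -o results/
```

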