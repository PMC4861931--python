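# Methods

`ribbonquant` quantifies inner-hair-cell (IHC) ribbon synapses from
two-channel 3D fluorescence stacks: a pre-synaptic ribbon channel (Ctbp2)
and a post-synaptic AMPA-receptor channel (Gria2).  The pipeline runs
deconvolution → segmentation → proximity pairing → per-cell counting →
positional clustering → distributional statistics.  Because no public
image dataset accompanies this quantification problem, validation is
simulation-based: a generator produces scenes with known ground truth and
the pipeline is scored on how well it recovers the generating parameters.

## Synthetic scenes

### Counts

Per cell, the numbers of paired ribbons, orphan (unpaired) ribbons and
orphan receptor patches are independent Poisson draws.  The packaged
presets carry the per-condition census means (per IHC):

| preset        | paired | orphan ribbons | total |
|---------------|--------|----------------|-------|
| `control_12k` | 15.8   | 1.5            | 17.3  |
| `control_24k` | 17.0   | 1.4            | 18.4  |
| `noise30_12k` | 14.2   | 1.9            | 16.1  |
| `noise30_24k` | 12.3   | 2.9            | 15.2  |
| `noise60_12k` | 11.0   | 3.4            | 14.4  |
| `noise60_24k` | 9.0    | 4.5            | 13.5  |

Totals are always the exact sum of the paired and orphan means.  Orphan
*receptor* rates are not reported per condition in the source census; the
presets use modest values rising with exposure (1.0 → 3.0 per IHC), chosen
once for plausibility.

### Positions

Each cell is an ellipsoid (semi-axes 4.5 × 3.0 × 3.0 µm in z, y, x) with
the cuticular–habenular axis along +z and the modiolar–pillar axis along
y; cells sit in a row along x at 8.5 µm pitch.  A synapse lies on the
basolateral band of the soma surface (20–92 % of the axial semi-axis
toward the habenular pole), displaced along the modiolar–pillar axis by
±`cluster_separation`/2 (default 3 µm) according to its cluster label
(modiolar with probability `cluster_mix`, default 0.5), plus isotropic
Gaussian jitter (σ = 0.5 µm).  The modiolar–pillar coordinate is therefore
an exact two-point Gaussian location mixture with variance
`w(1−w)d² + σ²`, which the tests verify in closed form.

Placement enforces two constraints, both part of what the scenes are meant
to emulate rather than tuning knobs:

* **Resolvability.** Same-channel puncta keep a surface-to-surface
  clearance of at least 0.7 µm (center distance ≥ r₁ + r₂ + 0.7).  The
  counting analysis — like the human counts it automates — presumes
  components that are individually resolvable at confocal resolution; the
  axial PSF (σ_z = 0.35 µm) makes closer same-channel puncta merge into
  one connected component for *any* threshold, which is a property of the
  optics, not of the algorithm under test.
* **Orphan consistency.** A ground-truth orphan must not sit within the
  pairing distance (plus a 0.2 µm margin for centroid-estimation error) of
  any opposite-channel component.  Otherwise the ground-truth labels would
  contradict the proximity definition of a pair that the analysis — and
  the generator's own bookkeeping — uses.

Paired receptors are placed at a uniform 0.15–0.45 µm offset in a random
direction from their ribbon.  Orphan receptors are placed uniformly on the
basolateral surface (whether real orphan receptors cluster spatially is
unknown; uniform is the least-informative choice).

### Volumes

Ribbon and receptor volumes are three-component log-normal mixtures
(small / medium / large sub-populations).  The control ribbon mixture has
modes near 0.05, 0.15 and 0.45 µm³ with weights 0.40/0.40/0.20; the
post-exposure 24 kHz mixtures deplete the tails, and the 60-min mixture
collapses onto the medium mode (weights 0.05/0.90/0.05, reduced log-sd),
giving an analytic variance about 5× below control.  These parameters are
package calibration choices that reproduce the qualitative structure of
the observed distributions (multi-modality; post-noise variance collapse);
they are not claimed literature values.

### Image formation

Each component is rendered as a solid sphere of its true volume.  Voxel
coverage is computed on a 3×3×3 sub-voxel grid, so total rendered mass
equals volume / voxel-volume even for sub-voxel puncta.  The coverage
image is blurred with a separable-Gaussian PSF (σ_xy = 0.12 µm,
σ_z = 0.35 µm — a standard confocal approximation; no vector diffraction
or depth aberration), scaled by `photon_scale` (200 photons per fully
covered voxel), offset by a flat background (5 photons), and corrupted
with Poisson shot noise plus Gaussian read noise (σ = 2), then quantized
to 16-bit.  Voxel size defaults to (0.3, 0.08, 0.08) µm (z, y, x), typical
of a high-NA confocal stack.  All stochastic steps consume one seeded
NumPy generator; the seed is stored in the truth sidecar JSON.

What the scenes deliberately do **not** model: tissue-dependent scattering
(the depth-varying PSF option exists but defaults off), fluorophore
bleed-through, background structures (cell bodies beyond a soft absence of
structure, stereocilia, nerve fibers), non-spherical component shapes, and
spatial correlation between volume and position.  Passing tests therefore
show that the algorithms recover truth under an idealized but
noise-realistic forward model — not that they are robust to every artifact
of real whole-mount tissue.

## Deconvolution

Richardson–Lucy (the maximum-likelihood deconvolution for Poisson noise),
25 iterations by default, initialized at the observed image.  For the
parametric Gaussian PSF the blur operator is the separable Gaussian filter
(reflective boundaries), which makes a flat image an exact fixed point and
conserves interior flux; an explicit-kernel FFT path exists for arbitrary
PSF arrays, and an optional per-plane σ_z profile models depth-varying
axial blur (the z-convolution then uses a column-normalized matrix and its
transpose as the adjoint).  Iteration counts beyond ~25 sharpen little on
these scenes.

## Segmentation

Foreground is `intensity > threshold`; default threshold is Otsu per
channel on the deconvolved stack (fixed-value and quantile alternatives
are config options).  Components are maximal 26-connected voxel sets;
those under `min_voxels` = 4 are discarded as sub-resolution specks.
Centroids are intensity-weighted, reported in µm with the voxel-centre
convention (position = (index + 0.5) × voxel size); volume is voxel count
× voxel volume; bounding boxes are half-open index ranges.  Component ids
follow raster-scan order, so segmentation is bit-reproducible.

## Pairing and counting

Greedy globally-closest matching: candidate ribbon–receptor pairs within
`max_pair_distance` (default 1.0 µm, centroid-to-centroid — "proximity" at
synapse scale; no published value exists) are sorted by distance, ties
broken by (ribbon id, receptor id), and accepted while both ends are
unmatched.  Greedy was chosen over optimal assignment for determinism and
speed; an exhaustive maximum-matching oracle in the tests bounds the
optimality gap (zero on resolvable scenes; at worst the ½-approximation
guarantee on adversarial clouds).  Components are assigned to the nearest
soma centre (cutoff 7 µm, beyond which they are flagged unassigned);
per-cell tables report paired / orphan / total with total = paired +
orphan by construction, and summaries give mean ± s.e.m. (sd/√n) by
condition × frequency.

## Positional analysis

Paired-ribbon centroids are projected onto each cell's modiolar–pillar (u)
and cuticular–habenular (v) axes (axes must be orthonormal; synthetic
scenes carry exact axes in metadata, external data must supply them —
axis estimation from a cell-body channel is out of scope).  Per-stack
clouds are aligned by translating each stack's paired-synapse centroid to
the origin, then pooled.

Clustering is full-covariance Gaussian-mixture EM over k ∈ {1, 2, 3}:
10 restarts from seeded k-means++ centres, convergence at log-likelihood
gain < 1e-8, and BIC = −2 logL + p ln n with p = (k−1) + 2k + 3k free
parameters; the k minimizing BIC is reported (a `force_k` option pins
k = 2 for the modiolar/pillar two-population assumption).  Two numerical
guards matter:

* a covariance with determinant ≤ 1e-12 µm⁴ mid-run is treated as
  singular and the run restarts with ridge regularization 1e-6 µm² · I;
* a converged component whose responsibility mass is below d + 1 = 3
  points is rejected as a likelihood spike — the classic unbounded-MLE
  degeneracy of unconstrained Gaussian mixtures.  Without this guard,
  best-of-restarts reliably finds Dirac-spike "clusters" of 2 points whose
  inflated likelihood beats the BIC penalty and corrupts model selection.

For k = 2 the angle between the cluster-mean difference vector and the
modiolar–pillar axis is exported (no acceptance value is attached to it;
no standard rotation metric exists for this quantity).

Volumetric outliers: a point is flagged iff its volume strictly exceeds
the empirical q-quantile (default 0.9; linear interpolation between order
statistics) of the pooled volumes; fewer than 10 points are refused as too
few for a stable quantile.  The flag summary reports mean (u, v) of
flagged vs unflagged points.

## Statistics

* Rank-sum: two-sided Wilcoxon/Mann–Whitney; exact enumeration when the
  combined n ≤ 12 with no ties, otherwise the normal approximation with
  tie and continuity corrections (at n = 6 + 6 the approximation is within
  0.02 of exact, verified against brute-force enumeration).  Two samples
  with all values identical return p = 1 with a warning.
* Count comparisons: Welch (unequal-variance) t-test of each condition
  against a baseline, Bonferroni-multiplied by the number of comparisons,
  capped at 1.  Zero variance in both groups with different means is an
  error (t undefined).
* Volume summaries: mean, unbiased variance, deciles, and a Gaussian KDE
  (Silverman bandwidth by default, recorded in the output) whose density
  integrates to 1 ± 1e-3 on its grid; constant samples are reported as a
  point mass.
* Energy dose: acoustic energy ∝ duration × 10^(dB/10) at equal source
  and spectrum, so the fold ratio of two exposures is
  (t_a 10^(L_a/10)) / (t_b 10^(L_b/10)).

## Pipeline and reproducibility

`run_pipeline` chains simulate → segment → pair → cluster/outliers →
stats under one validated config (unknown keys are rejected before any
computation).  Organ i is simulated with seed `config_seed + i`, so the
whole run derives from one seed with no hidden entropy.  The run manifest
records the config snapshot, seeds, package version, timestamps and
SHA-256 digests of every stage's inputs and outputs; re-running skips
stages whose input digests and outputs are unchanged, and a fresh rerun
with the same seed reproduces identical output digests.

## Problem sizes used in validation

End-to-end count recovery uses 3 simulated organs × 10 IHCs per condition
(matching the scale of tissue analyzed per condition in the source
census), with recovery required within 3 generator standard errors of the
Poisson mean — the generator's own sampling noise at that n.  BIC
consistency is checked on 100 seeded two-cluster ensembles of 120 points
at 6σ separation (and 100 single-cluster ensembles).  The variance-
collapse property uses 100 paired seeded runs of 2 cells per preset,
ribbon channel only, comparing pipeline-estimated volume variances between
the 24 kHz control and 60-min presets.

## Known limitations

* Estimated volumes are threshold-dependent and systematically compressed
  relative to truth (PSF broadening vs thresholding); tests assert
  monotone (Spearman ≥ 0.9) agreement, not unbiasedness.  Variance
  comparisons between conditions are valid because the compression is
  shared.
* Nearest-centre cell assignment misassigns synapses lying near the
  midplane between adjacent cells; at the default 8.5 µm pitch this is
  rare and symmetric, so per-condition means are unaffected.
* Otsu thresholding assumes a clearly bimodal intensity histogram; very
  sparse or very dense scenes may need the fixed or quantile alternatives.
* The greedy pairing is a ½-approximation in the worst case; the gap is
  zero in the resolvable-synapse regime the generator produces.
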