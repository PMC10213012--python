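# Methods

## Problem and model

A radiograph pixel records the line integral of the linear attenuation
coefficient (AC) along the ray that reaches it.  Under a monoenergetic
assumption the AC is an affine function of the CT number,
`mu = mu_water (1 + HU/1000)` (clamped at zero below air), and the
composite image separates additively over any partition of the volume
into structures `c_1..c_{K+1}` with binary masks `delta_n`:

    I(u) = integral mu(s; u) ds = sum_n integral delta_n mu ds = sum_n I_n(u).

`raddecomp` treats the inverse problem — recovering the per-structure
projections `I_n` ("decomposed DRRs") from a single composite radiograph —
as unpaired image translation between the radiograph domain and the
multichannel DRR domain, because muscles deform between CT (supine) and
radiography (standing) and paired, registered training data cannot be
obtained.  The translator is a cycle-consistent adversarial pair
(`G_DRR`: radiograph -> K+1 channels, `G_Xp`: channels -> radiograph, one
patch discriminator per domain) with two additions:

* **Hierarchical (coarse-to-fine) generators** — a global generator is
  trained on half-resolution images first; a local enhancer then refines
  at full resolution.  The composed output is the upsampled global output
  plus an image-space correction whose final convolution is
  zero-initialized, so composition starts exactly at the global solution.
  The enhancer's half-resolution features are fused (by addition) with
  the global generator's backbone features.
* **Reconstruction gradient-correlation (GC) loss** — the channel-sum of
  the decomposition must reproduce the *gradients* of the input
  radiograph: `L_reconGC = 1/2[(1 - GC(x, sum_n G_DRR,n(x))) +
  (1 - GC(sum_n y_n, G_Xp(y)))]`.  GC is the mean of the NCCs of the two
  Sobel gradient components and is invariant to positive affine intensity
  changes, which makes the constraint robust to the absolute-intensity
  gap between rendered projections and real radiographs.  An l2
  reconstruction penalty (weight 0.5) is kept for the second baseline of
  the ablation matrix.

The total generator objective is
`L_GAN + lambda_cyc L_cyc + lambda_GC L_reconGC` with
`lambda_cyc = 10`, `lambda_GC = 1.0`.  The printed definition of GC
repeats the same cross-component NCC term twice; this package implements
the component-matched form `1/2[NCC(grad_u A, grad_u B) +
NCC(grad_v A, grad_v B)]`, which is the standard definition in the
gradient-correlation registration literature the loss derives from.  The
gradient operator is a 3x3 Sobel (valid interior, no padding), with
central differences available as an option.

## Downstream metric: muscle asymmetry

Under a parallel projection the sum of a uniform-AC structure's line
integrals times the pixel area equals `alpha * V` (average AC times
volume).  The affected/unaffected volume ratio of a bilateral muscle is
therefore estimated from a single decomposed channel as

    r^{A:U} = sum_{Omega_A} I_n / sum_{Omega_U} I_n  ~=  alpha_A V_A / (alpha_U V_U),

where the side regions Omega split the channel's support at the detector
midline.  A 10 HU side-to-side difference changes the AC ratio by only
~1% (10/1050), so `r` is dominated by the volume ratio.  Channels must be
denormalized to raw line-integral units before summation; the shared
normalization (below) keeps denormalization exact.

## Synthetic phantoms: what they emulate and what they do not

Real training data (CT + standing radiographs of hip-disease patients)
is not available, so a generator produces 3-D phantoms: an ellipsoidal
body, bones (a midline capsule plus mirrored capsule pairs, HU
400–800), bilateral ellipsoidal muscles (HU 40–80, uniform per
structure), and a residual background channel (HU -30).  The default
layout is 3 bones + 19 muscles (+ background = 23 channels).  Muscles
are mirrored exactly; on the affected side one semi-axis is scaled by
the asymmetry factor, so the analytic volume ratio equals the factor
(V ∝ abc), giving exact ground truth for the ratio metric.  Uniform
per-structure HU makes `alpha` constant, so the `alpha V` identity is
exact up to voxelization.  Placement uses a jittered slot lattice in the
left half-body with bones and muscles in disjoint bands; masks are
mutually exclusive by construction.

The unpaired condition is emulated by rendering each case's noisy
composite radiograph at a random rigid pose perturbation (default ±5°,
±6 mm) while per-structure DRRs use the unperturbed pose.  Quantum noise
follows the transmission model: `N ~ Poisson(i0 exp(-p))`,
`p' = -ln(max(N,1)/i0)`, default `i0 = 1e4` photons per unexposed pixel.

Phantoms do not emulate: anatomical shape realism, CT noise or beam
hardening, soft-tissue deformation (the pose mismatch is rigid), scatter,
detector blur, or intensity post-processing of clinical radiographs.
Passing tests therefore demonstrate the correctness of the projection
model, losses, training mechanics and metrics — not clinical-grade
decomposition accuracy on real radiographs.

## Projection and normalization

Two geometries (axis-aligned parallel; pinhole with source–detector
distance `d`, principal point at the detector centre) and three
integrators:

* **aligned** — closed-form column sum when the parallel geometry
  matches the voxel lattice; conservation and the `alpha V` identity are
  exact here.
* **exact** — Siddon-style ray/voxel intersection lengths; the in-repo
  oracle for every other integrator.
* **sampling** — midpoint rule on the piecewise-constant voxel field
  (nearest-voxel lookup) at step `min(spacing)/16`.  Nearest-voxel
  sampling, rather than trilinear interpolation, is used because it
  integrates the same piecewise-constant field as the exact oracle: the
  error then vanishes linearly with the step (measured max relative
  error ~0.5% at the default step on a rotated two-box phantom), whereas
  trilinear interpolation differs from that field near structure edges
  by an amount that does not shrink with the step (~10%).  Trilinear
  remains available via `order=1`.

Intensities are normalized to [0, 255] by one fixed affine map shared by
every image of a dataset, computed from the training split only:
`raw_min = 0` (line integrals are non-negative) and `raw_max` = the
training split's composite maximum.  Keeping `raw_min = 0` preserves
additivity (the normalized channel-sum equals the normalized composite),
and the shared map makes denormalized intensities comparable across
cases.

## Training

Adam (betas 0.5/0.999), learning rate 0.0002 for the first half of the
epochs then linearly decayed to zero (defaults: 200 epochs), batch size
1, a 50-image history pool feeding each discriminator, non-saturating
log-form adversarial loss with scores clamped at 1e-7.  Pixel losses
(cycle, reconstruction l2) are computed on the [-1, 1] scale — the
convention of the CycleGAN framework the weight balance derives from —
so `lambda_cyc = 10` weighs an O(0.1–1) term against an O(1) adversarial
term; computing them on the [0, 255] scale inflates them ~127-fold and
collapses training into pure autoencoding (the discriminator reaches its
supremum).  The GC term is scale-invariant.

Ablation variants (generator downsample layers / discriminator stride-2
layers): conventional1 = plain CycleGAN (3/4); conventional2 adds the l2
reconstruction loss (3/4); proposed1 trains hierarchically (2/3);
proposed2 adds the reconstruction GC loss (2/3).  Hierarchical variants
run the global stage for the full schedule, then the local stage with
fresh discriminators and the global generator frozen for the first 10%
of epochs (the stage handover is not fully specified by the source
method; both choices are configurable).

All computation runs on an in-package reverse-mode autodiff engine
(float64, numpy; im2col-GEMM convolutions) — the package has no
deep-learning framework dependency.  Training is bit-deterministic for a
fixed seed, and checkpoints serialize the full state (parameters,
optimizer moments, image pools, RNG state) so resumed runs reproduce
straight runs exactly.

## Evaluation

Per structure: PSNR (reported on both the normalized 8-bit scale and the
denormalized line-integral scale, capped at 99 dB for exact matches) and
Dice after binarization.  The binarization threshold is selected per
method and structure as the sweep value maximizing mean Dice across
cases (41 evenly spaced values over 1–25% of the ground-truth channel
maximum; smallest value on ties).  The ground-truth silhouette is the
exact support of the rendered channel (`> 0`), which synthetic ground
truth makes unambiguous.  Structures aggregate into bone / hip-muscle /
thigh-muscle groups (muscle group assigned by superior/inferior slot
position).  Ratio agreement across cases uses the two-way, single-
measure, absolute-agreement intraclass correlation (verified against
pingouin's ICC(A,1)).  Side regions for the ratio are defined from the
ground-truth projections, isolating metric correctness from localization
error; the decomposed radiograph is rendered at a perturbed pose, so
even a perfect decomposition has a Dice ceiling (~0.5–0.8 for the toy
structures) against the unperturbed ground truth.

## Toy benchmark scale

The packaged ablation benchmark (`raddecomp.benchmark`) uses 32 cases
(24 train / 8 test) of 32^3 phantoms with 1 bone + 2 muscles (K+1 = 4),
32 x 32 images, generator base width 8 with 3 residual blocks, 20 epochs
per stage, 3 seeds, and shifts both variant families' discriminator
depth down one stride-2 layer (`disc_s2_delta = 1`) so the patch score
map remains non-empty at 32 pixels while preserving the
conventional-vs-proposed depth contrast.  This runs in roughly ten
minutes on one CPU.  At this scale both hierarchical variants
consistently outperform the plain baseline, while the finer margin
between the two proposed variants is smaller than run-to-run GAN
variance; the full-resolution configuration (512 x 512, 23 channels,
width 64, 200 epochs) remains available through the same configs.

## Known limitations

* The numpy training stack is single-CPU; full-scale (512 x 512)
  training is out of desk reach.
* Rays are infinitesimal (no focal spot or detector aperture), the
  spectrum is monoenergetic, and scatter is ignored — exactly the
  assumptions of the line-integral model.
* The Dice evaluation compares against unperturbed-pose ground truth;
  with nonzero pose perturbation it measures decomposition and implicit
  localization jointly.
* `r^{A:U}` under a pinhole geometry carries a small magnification bias
  (< 0.02 for centred toy phantoms at d = 1000 mm); the parallel model
  is the metric's stated regime.
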