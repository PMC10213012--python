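# raddecomp

Decomposition of musculoskeletal radiographs into per-structure
projection images — individual bones, individual muscles and a residual
background — from a **single** plain radiograph, plus a muscle-asymmetry
metric read directly off the decomposed channels.

## Who this is for

Radiographs are cheap and low-dose, but quantitative muscle assessment
(sarcopenia, post-operative atrophy, biomechanics) normally requires CT
or MRI.  If the intensity a radiograph records — the line integral of
the attenuation coefficient along each ray — can be separated into the
additive contributions of individual structures, then muscle-wise
quantities such as the left/right volume ratio become measurable from a
standing radiograph.  This package implements that decomposition
framework end to end for researchers in medical image analysis:
projection modelling, the unpaired translation network and its losses,
training, and the evaluation metrics, exercised on synthetic 3-D
phantoms with exact ground truth.

## The model

With `delta_n` the binary mask of structure `c_n` and `mu` the linear
attenuation coefficient (`mu = mu_water (1 + HU/1000)`, monoenergetic),

    I(u) = ∫ mu(s; u) ds = Σ_{n=1}^{K+1} ∫ delta_n mu ds = Σ_n I_n^DRR(u),

so the radiograph is the superimposition of per-structure projections.
Recovering the `I_n^DRR` from `I` is posed as unpaired image translation
(muscles deform between supine CT and standing radiography, so paired
data cannot be registered): a cycle-consistent adversarial pair
`G_DRR : I -> {I_n}` and `G_Xp : {I_n} -> I` with patch discriminators,
trained by

    min_G max_D  L_GAN + lambda_cyc L_cyc + lambda_GC L_reconGC,

`lambda_cyc = 10`, `lambda_GC = 1`.  Two features stabilize and sharpen
the translation: **hierarchical learning** (a global half-resolution
generator, then a local enhancer at full resolution) and the
**reconstruction gradient-correlation loss**
`1 - GC(x, Σ_n G_DRR,n(x))`, where GC is the mean NCC of the two Sobel
gradient components — invariant to affine intensity changes, so it
enforces edge alignment without requiring absolute-intensity agreement.

Because `Σ_Ω I_n^DRR × pixel-area = alpha V` under a parallel projection
(average AC times volume), the affected/unaffected volume ratio of a
bilateral muscle is estimated from one decomposed channel:

    r^{A:U} = Σ_{Ω_A} I_n / Σ_{Ω_U} I_n ≈ alpha^A V^A / (alpha^U V^U).

## Worked example

```python
import numpy as np
from raddecomp import (PhantomSpec, generate_phantom, default_geometry_for,
                       render, volume_ratio, receptive_field)

spec = PhantomSpec(grid_shape=(96, 96, 96), spacing=(1.5, 1.5, 1.5),
                   n_bones=1, n_muscles=2, asymmetry_factor=0.8, seed=7)
phantom = generate_phantom(spec)
geometry = default_geometry_for(spec.grid_shape, spec.spacing)
drrs, radiograph = render(phantom, geometry)

print("channels:", drrs.channels.shape)
err = np.abs(drrs.channel_sum() - radiograph.pixels).max() / radiograph.pixels.max()
print(f"conservation error: {err:.2e}")

nu = drrs.channels.shape[2]
left = np.zeros(drrs.channels.shape[1:], bool)
left[:, np.arange(nu) - (nu - 1) / 2.0 < 0] = True
for ci, lab in enumerate(phantom.labels):
    if lab.name.startswith("muscle"):
        ch = drrs.channels[ci]
        res = volume_ratio(ch, left & (ch > 0), ~left & (ch > 0))
        v = phantom.true_side_volumes[lab.name]
        print(f"{lab.name}: r = {res.r:.4f} (voxel truth {v['left']/v['right']:.4f})")

print("patch size:", receptive_field(4, 4, 2))
```

prints

```
channels: (4, 96, 96)
conservation error: 1.56e-15
muscle_01: r = 0.8004 (voxel truth 0.8004)
muscle_02: r = 0.7980 (voxel truth 0.7980)
patch size: 142
```

The phantom's muscles were built with their affected-side volume scaled
by 0.8; the ratio recovered from the rendered channels matches that
factor to voxelization accuracy, the channel-sum reproduces the
composite radiograph to machine precision (the additive model is exact),
and the default patch discriminator judges 142 x 142-pixel patches.

## Command line

Every stage of an experiment runs from one YAML config:

```
raddecomp dataset  --config experiment.yaml        # phantoms + rendering
raddecomp train    --config experiment.yaml --variant proposed2
raddecomp decompose --config experiment.yaml
raddecomp evaluate --config experiment.yaml
raddecomp all      --config experiment.yaml        # everything
```

Stages stamp their outputs with config hashes: re-running an unchanged
config is a no-op, and a changed config refuses to overwrite silently.
Training variants: `conventional1` (plain CycleGAN), `conventional2`
(+ l2 reconstruction loss), `proposed1` (+ hierarchical learning),
`proposed2` (hierarchical + reconstruction GC loss).

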