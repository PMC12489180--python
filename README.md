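# reconformer

Unsupervised transformer super-resolution reconstruction for
multi-orientation thick-slice 3-D MRI.

## The problem

Multi-slice MRI acquires stacks with high in-plane resolution and thick
slices: fast to scan and high-SNR, but anisotropic. Given two or three such
stacks in different slice-select orientations, super-resolution
reconstruction (SRR) estimates one isotropic high-resolution volume. Each
stack is modelled as

    y_i = D_i( b_i * (m_i o x) ) + e_i

where `x` is the high-resolution image, `m_i` a rigid head pose, `b_i` a
1-D Gaussian slice profile whose FWHM equals the slice thickness, `D_i`
frequency-domain decimation along the slice axis by the integer factor
(thickness / in-plane spacing), and `e_i` Gaussian noise.

Two reconstruction routes are provided:

- **TV baseline** — minimize `sum_i ||y_i - A_i x||^2 + lambda TV(x)` by
  monotone accelerated gradient descent.
- **Transformer (the method)** — a patient-specific deep-image-prior loop:
  a volumetric vision transformer `T_theta` (patch tokenization, multi-head
  self-attention blocks, multi-scale deconvolutional decoder with skip
  connections, sigmoid-bounded output) takes the TV-combined stacks as
  input, and Adam minimizes the l2 data-consistency loss
  `sum_i ||y_i - A_i T_theta(u)||^2` over the network weights — no training
  labels and no external data. The reconstruction is the trained network's
  output, `x = T_theta(u)`.

The package also ships mutual-information rigid registration (Powell +
B-spline, via SimpleITK), a quality-metric suite (SSIM, NMI, JSD,
Canny/Prewitt edge-strength sharpness, SNR, CNR, plus a simple tissue
segmenter), and a seeded brain-like phantom simulator so everything is
testable offline. For who: researchers working on MRI super-resolution or
inverse problems who need a transparent, fully reproducible desk-scale
reference implementation.

## Worked example

Simulate a study from a 64^3 brain-like phantom (0.5 mm isotropic ground
truth, two orthogonal stacks with 2 mm slices = factor 4, noise at 10% of
each stack's max), then reconstruct both ways and compare:

```python
from reconformer import (PhantomSpec, TVConfig, make_phantom, simulate_study,
                         ssim, snr, cnr)
from reconformer.metrics import TissueMasks
from reconformer.network import dip_train, reduced_preset
from reconformer.tv import tv_reconstruct

phantom, labels = make_phantom(PhantomSpec(shape=(64, 64, 64),
                                           spacing=(0.5,) * 3, seed=1))
study = simulate_study(phantom, labels, thicknesses=[2.0],
                       planes=["axial", "coronal"], sigma_fraction=0.1, seed=1)
stacks = [r.volume for r in study.stacks]
geoms = [r.geometry for r in study.stacks]
masks = TissueMasks.from_labels(labels)

tv_vol, _ = tv_reconstruct(stacks, geoms, None, TVConfig(lambda_tv=1e-2))
rc_vol, trace = dip_train(stacks, geoms, None, reduced_preset(seed=1))

for name, v in [("TV", tv_vol), ("transformer", rc_vol)]:
    print(f"{name}: SSIM={ssim(v, phantom):.4f} "
          f"SNR={snr(v, masks):.3f} CNR={cnr(v, masks):.3f}")
```

Output (about 2 minutes on one CPU core):

```
TV: SSIM=0.4842 SNR=3.286 CNR=1.979
transformer: SSIM=0.5454 SNR=4.377 CNR=2.689
```

SSIM is structural agreement with the ground truth (1 = identical); SNR is
the count-weighted GM+WM mean over the background noise standard
deviation; CNR is the GM–WM contrast over the same noise. The transformer
reconstruction scores higher on all three: sharper tissue interfaces and
less residual noise than the TV solution under identical inputs.

The same pipeline is scriptable from the shell:

```bash
reconformer simulate --out sim --shape 64 --thickness 2.0 \
    --plane axial --plane coronal --seed 1
reconformer reconstruct-tv sim/stack_*.nii.gz --out tv
reconformer reconstruct sim/stack_*.nii.gz --out rc --preset reduced --seed 1
reconformer evaluate rc/recon_transformer.nii.gz \
    --reference sim/ground_truth.nii.gz --labels sim/labels.nii.gz --out report
```

Other subcommands: `register` (MI rigid group registration),
`sweep-patch-size` (re-run the reconstruction at patch sizes 8/16/32 and
tabulate NMI/JSD/sharpness/SNR), `run` (whole pipeline from one YAML
config).

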