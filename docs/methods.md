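# Methods

## Problem

Two-dimensional multi-slice MRI trades through-plane resolution for scan
time and SNR: stacks are acquired with high in-plane resolution (here
0.5 mm) and thick slices (1–3 mm). Given two or three such stacks acquired
in different slice-select orientations, super-resolution reconstruction
(SRR) estimates a single isotropic high-resolution (HR) volume. This
package implements an unsupervised, per-subject transformer reconstruction
with an explicit forward acquisition model, a total-variation (TV)
baseline, a quality-metric suite, and a procedural phantom simulator, so
the whole method is testable without any external data.

## Forward acquisition model

Each low-resolution stack is modelled as

    y_i = D_i( b_i * (m_i o x) ) + e_i

with `m_i` a 6-DOF rigid head pose, `b_i` a 1-D Gaussian slice profile
along the slice-select axis whose FWHM equals the slice thickness
(`sigma_mm = thickness / (2 sqrt(2 ln 2))`), `D_i` frequency-domain
decimation by the integer factor `thickness / in-plane spacing`, and `e_i`
i.i.d. Gaussian noise with standard deviation a stated fraction (default
10%) of the stack's maximum intensity. Operations are composed in exactly
that order.

Numerical choices:

- The slice kernel lives on the HR lattice, truncated at ±4 sigma (odd
  length) and renormalized to unit sum; boundary handling for the spatial
  blur is reflective.
- Decimation keeps the central `1/f` frequency band; at an even band width
  the positive Nyquist bin is kept, the real part is taken, and the scale
  is fixed so constants are preserved exactly. Axis extents not divisible
  by the factor are symmetrically zero-padded first.
- With noise off the whole map is linear. The per-axis blur and decimation
  stages are materialized as small 1-D operator matrices (built by applying
  the same public routines to identity inputs) and a rigid transform as a
  sparse trilinear interpolation matrix, so the operator's adjoint is exact
  to machine precision. Both reconstruction methods use these operators and
  their adjoints; the simulator uses the identical code path, so a perfect
  reconstruction of noiseless data attains zero data-consistency loss by
  construction.

## Registration

Stacks are aligned by rigid registration with mutual information as the
similarity criterion, third-order B-spline interpolation and Powell's
derivative-free optimizer, coarse-to-fine (shrink factors 4, 2, 1). The
implementation wraps SimpleITK's registration framework with full-volume
metric sampling, which makes runs deterministic. Group alignment uses a
star topology: the first stack defines the frame. Simulated pipelines can
bypass registration and pass ground-truth poses, isolating reconstruction
behaviour from registration error. On the structured phantom, poses up to
5 mm / 5 degrees are recovered to well within 0.5 mm / 0.5 degrees.

## TV baseline

The baseline minimizes `sum_i ||y_i - A_i x||^2 + lambda * TV_eps(x)` with
smoothed isotropic TV (`eps = 1e-3`) on forward differences. The solver is
monotone Nesterov-accelerated gradient descent with backtracking: an
accelerated step is accepted only when it decreases the objective,
otherwise the iteration falls back to a plain backtracked step, so the
objective trace is non-increasing by construction. Plain gradient descent
was tried first and could not reach oracle-level accuracy on the
blur-dominated normal equations within a sane iteration budget; the
monotone accelerated variant converges to the dense least-squares solution
within 1e-3 relative error on toy problems. Initialization is the
adjoint-based back-projection average `sum A_i^T y_i / sum A_i^T A_i 1`.
Defaults: `lambda = 1e-2` on unit-normalized intensities, 200 iterations,
relative-change tolerance 1e-6. At 10%-of-max noise this weight leaves
visible residual noise in the reconstruction; that is the classical
character of the baseline this package compares against, and the weight is
a config parameter.

## Transformer reconstruction

The network input is the TV combination of the stacks resampled on the HR
lattice and min–max normalized to [0, 1]. The input-combination schedule
deliberately uses a stronger TV weight (default `3e-2`, 200 iterations)
than the comparison baseline: the network refines toward data consistency
from its input, so residual noise baked into the input cannot be removed
by training, while structure lost to smoothing can be recovered from the
data term.

Architecture (all sizes config-driven):

- Tokenization into cubic patches (default 16^3 voxels at full scale, 8^3
  in the reduced preset) via a linear projection to the embedding width
  (768 / 96), plus a learnable additive position embedding at the token
  grid.
- A stack of pre-norm transformer blocks (12 blocks, 12 heads, MLP 3072 at
  full scale; 4 blocks, 6 heads, MLP 192 reduced), providing the
  long-range spatial dependency modelling that distinguishes the method
  from CNN-based unsupervised SRR.
- A multi-scale decoder: the deepest hidden state is reshaped to a
  volumetric feature map and repeatedly upsampled 2x by learned
  pixel-shuffle (linear channel expansion + voxel rearrangement, the exact
  equivalent of a stride-2 transposed convolution); selected transformer
  depths (skip taps 3/6/9/12 full, 1–4 reduced) feed each stage through
  projections. Decoder stages are linear — the nonlinearity lives in the
  transformer blocks; saturating activations inside the decoder were found
  to die early in training and silence the correction path entirely.
- A finest-scale skip feeds the raw input volume through a per-voxel
  projection into the last stage.
- A zero-initialized 1x1x1 convolution head produces a residual correction
  that is added, in logit space, to the (clipped) input image, and a
  sigmoid bounds the output to (0, 1). Training therefore starts exactly
  at the TV-combined input; without this residual anchoring, whole-volume
  training from random initialization does not reach a usable image within
  a desk-scale iteration budget.

Training is deep-image-prior style: Adam minimizes the l2 data-consistency
loss of the network output pushed through the exact forward operators; no
labels, no external data, and randomness only in the parameter
initialization, so runs are bitwise reproducible for a fixed seed. The
full-scale schedule is 4000 iterations at learning rate 0.01. The reduced
preset runs 300 iterations at 3e-4: at the smaller width the larger rate
saturates the sigmoid head, and the fixed, deliberately short schedule is
the implicit regularizer — data consistency keeps improving monotonically
with iterations while reconstruction quality eventually degrades as the
residual capacity starts fitting measurement noise, the classical deep-
image-prior trade-off. Early stopping is not applied; the iteration count
is part of the configuration.

The output is denormalized with the input's recorded intensity range.
Volumes are edge-padded to patch-size multiples for the network and
cropped back before the loss.

## Quality metrics

- SSIM: scikit-image's implementation (Gaussian window sigma 1.5,
  K1 = 0.01, K2 = 0.03, population covariances, dynamic range from the
  reference); unequal lattices are resampled to the reference first.
- NMI `(H(a)+H(b))/H(a,b)` and MI in bits from dense joint histograms
  (256 and 32 bins by default; configurable).
- JSD between marginal intensity histograms over the shared range, in the
  standard bounded convention `JSD = KL(p||m)/2 + KL(q||m)/2`, `m=(p+q)/2`,
  in bits, so identical histograms give 0 and disjoint ones give 1.
- Sharpness: average edge strength computed slice-wise in 2-D — Canny edge
  mask (high threshold = Otsu of the Prewitt gradient magnitudes, low =
  0.4x high) selecting pixels of the squared Prewitt gradient magnitude,
  accumulated over slices; a magnitude (non-squared) variant is a config
  switch, and relative comparisons are unaffected by that monotone choice.
  Reported sharpness is normalized by a reference image's AES.
- SNR `s / sigma` with `s` the voxel-count-weighted GM+WM mean and `sigma`
  the background standard deviation; CNR `|s_GM - s_WM| / sigma`.
- `segment_simple` provides the tissue masks when none are supplied: Otsu
  background split, largest-component head mask, 3-class k-means on
  intensities mapped to CSF/GM/WM by mean rank under the stated contrast
  (T2: WM < GM < CSF). It exists to feed SNR/CNR, not for morphometry; on
  the phantom it recovers each tissue at Dice >= 0.9.

## Phantom simulator

The generator emulates the study conditions end to end: a brain-like HR
label image (nested ellipsoidal head / CSF rim / cortical GM band / WM
core, two ventricles, deep GM nuclei, seeded smooth lobular boundary
perturbations) with piecewise-constant tissue intensities exactly
consistent with the emitted masks (T2-like by default: CSF 1.0, GM 0.55,
WM 0.30, background 0); stacks degraded through the forward model for
every (thickness, plane) pair; per-stack noise at 10% of that stack's own
maximum; per-stack seeds derived from one master seed so a study
regenerates bit-exactly from its manifest. The canned recipes mirror the
published protocols: simulation — thicknesses {1, 1.5, 2, 2.5, 3} mm in 3
orthogonal planes at 10% noise; clinical — two stacks (axial + coronal),
0.5 mm in-plane, 2 mm slices (factor 4).

What the phantom does not emulate: cortical folding, partial-volume
mixtures, bias fields, Rician noise statistics, and motion within a stack.
Passing tests therefore demonstrate the correctness of the operators and
the relative behaviour of the reconstruction methods under the stated
conditions, not clinical image quality.

## Problem sizes

The default test bench uses 32^3–64^3 phantoms at 0.5–1 mm spacing, two
orthogonal factor-4 stacks, 10% noise, and the reduced network preset with
300 iterations; these sizes are the package's reference desk-scale
conditions and run on a single CPU core. The full-scale preset matches the
published configuration and is intended for GPU-class hardware.

## Known limitations

- At desk scale the transformer's refinement margin over its own input is
  small, and quality is non-monotone in iterations (the DIP trade-off);
  the fixed 300-iteration schedule was chosen once for the reduced preset
  and is the lever a user should tune first at other scales.
- The set-valued network input described by the method (all stacks at
  once) is realized, as in the original pipeline, by the TV combination;
  a true multi-volume input head is not implemented.
- Rigid poses are per stack; within-stack (slice-level) motion is out of
  scope.
- The frequency decimation assumes integer thickness/in-plane ratios;
  non-integer ratios are rejected rather than rounded.
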