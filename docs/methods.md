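# Methods

`perfsyn` implements a complete, self-contained pipeline for studying
end-to-end synthesis of DSC-MRI perfusion parameter maps with conditional
GANs: a digital perfusion phantom with known per-voxel hemodynamics, the
classical deconvolution engine that produces the training targets, slice-wise
preprocessing, two generator architectures with a PatchGAN discriminator,
the adversarial + L1 training objective, and the four-metric evaluation
with paired significance testing.  Because clinical DSC datasets of this
kind cannot be shared, every stage is exercised on simulated data whose
ground truth is known by construction.

## Phantom forward model

Each brain voxel follows standard indicator-dilution theory.  The arterial
input function (AIF) is a gamma-variate bolus

    C_a(t) = A * ((t - t0)/(alpha*beta))^alpha * exp(alpha * (1 - (t - t0)/(alpha*beta)))

normalized so its peak value is `A` (default 5 a.u.), with onset `t0` placed
at the end of the prebolus window (8 frames x TR).  Defaults `alpha = 3`,
`beta = 1.5 s` give a bolus with ~4.5 s rise time, a typical clinical shape.
Tissue concentration is the causal discrete convolution

    C(t) = CBF' * (C_a (*) R)(t - delay),    rectangle rule, scaled by TR,

with `CBF'` the relative flow in 1/s, an exponential (default) or boxcar
residue function `R`, and the arrival delay rounded to whole frames.  Signal
conversion is the monoexponential T2* model `S = S0 exp(-k TE C)` with
`S0 = 100`, `TE = 36 ms`, `k = 40 /(mM s)` chosen so that a gray-matter
voxel shows a 25-35 % peak signal drop, a realistic DSC contrast-to-noise
regime; additive Gaussian noise (default SD 1, i.e. 1 % of baseline) is
applied on the signal.  Acquisition defaults mirror an acute-stroke
protocol: TR = 2.22 s, 60 frames (protocol range 50-75), 8 prebolus frames,
21 x 128 x 128 grid; a small preset (4 x 32 x 32, 32 frames) keeps
end-to-end runs fast.

**Quadrature choice.**  At TR = 2.22 s the left-rectangle sum of
`exp(-t/MTT)` overestimates MTT by ~30 %, which would break the central
volume theorem in the discrete model.  The exponential residue therefore
uses the decay constant `tau = -TR / ln(1 - TR/MTT)`, which makes the
discrete rectangle-rule area of `R` equal MTT exactly while keeping
`R(0) = 1` and monotone decay; `tau -> MTT` as the grid is refined.  With
this convention, area conservation (area under C / area under C_a = relative
CBV) holds to machine precision rather than "within discretization error".

**Tissue and lesion geometry.**  The brain is a stack of shrinking ellipses
(gray matter CBF 60 ml/100g/min, MTT 4 s; a white-matter core at
25 ml/100g/min, MTT 4.8 s; both modulated by a smooth ~10 % random field so
maps are not piecewise constant).  CBV is defined as CBF x MTT, so the
central volume theorem holds exactly in the truth maps.  An ellipsoidal
lesion multiplies CBF by 0.35 and MTT by 2.0 and adds 6 s arrival delay by
default; the cohort generator draws per-patient lesion geometry and severity,
and in the "delay-rich" mode also draws background arrival lags of 0-2
frames and lesion delays of 2-8 s, emulating the acute-occlusion regime in
which timing maps carry most of the between-patient variation.

What the phantom does *not* model: contrast recirculation and leakage,
partial-volume effects in the AIF, dispersion of the bolus on its way to the
tissue, Rician magnitude noise (Gaussian is the default; the noise model is
switchable), and motion artifacts.  Tests passing on phantoms therefore
demonstrate correctness of the computational pipeline, not clinical-grade
robustness.

## Classical map engine

Concentration is recovered as `C = -ln(S/S0) / (k TE)` with `S0` the
prebolus mean; voxels with a non-positive baseline are masked out, the
signal is floored at machine-epsilon x S0 before the log, and negative
concentrations produced by noise are kept so that integral statistics remain
unbiased.  The five maps:

* **CBV** — area under `C` over area under `C_a`.  Areas use the rectangle
  rule, matching the forward-model quadrature; this also makes CBV exactly
  invariant to a permutation of the frames (trapezoid endpoint weights would
  not be).
* **CBF, Tmax** — block-circulant SVD deconvolution: the AIF convolution
  matrix is built at padded length `L = 2T`, inverted through its SVD with
  singular values below `f * s_max` zeroed (default `f = 0.10` for noisy
  data; 0 recovers the exact inverse on noiseless input), giving
  `k(t) = CBF' R(t - delay)`.  CBF is the height `max k` and Tmax the lag
  `argmax k` (earliest frame on ties) — the delay-insensitive readings the
  circulant formulation is designed for.  The first `T` lags of the padded
  solution are kept.
* **MTT** — CBV/CBF wherever CBF > 0; voxels without recoverable flow are
  flagged invalid and excluded from the mask rather than raising.
* **TTP** — `argmax` of the raw tissue curve (no deconvolution), earliest
  frame on ties, with a low-contrast flag for flat curves.

On noiseless phantoms the whole chain is exact to ~1e-13 relative error
because deconvolution inverts the very quadrature the phantom used; the
acceptance thresholds (5 % median error, one frame of timing) leave room for
regularized, noisy regimes.

## Preprocessing

Time series are padded to 80 frames by repeating the final frame (pure
baseline prolongation; longer series are refused, never truncated).  All
values are mapped affinely to [-1, 1] using global min/max statistics fitted
on the **training split only** and reused for validation/test — out-of-range
test values pass through unless clipping is requested — and volumes are cut
into axial slices, dropping slices whose brain mask is empty.  Splits are by
patient (default 70/10/20; 203 patients reproduce a 142/20/41 partition)
with a seeded shuffle, so no patient contributes slices to two splits.

## Architectures

Both generators output one map slice through a tanh; all convolutions use
kernel 4, stride 2, LeakyReLU slope 0.2 on the way down, ReLU on the way up.

* **pix2pix**: the 80 frames enter a six-level 2D U-Net as input channels.
  Channel ladder 64, 128, 256, 512, 512, 512 (scaled by `base_channels/64`);
  batch normalization everywhere except the outermost layer and the
  bottleneck; skip connections mirror encoder levels into the decoder.  A
  128 x 128 slice reaches a 2 x 2 bottleneck.
* **temp-pix2pix**: the sequence keeps a time axis, `(1, h, w, 80)`, and six
  3D convolutions — kernel (3, 3, 4), stride (1, 1, 2), padding (1, 1, 1),
  channel plan 8, 16, 32, 64, 64, 64 (configurable) — collapse time
  80 -> 40 -> 20 -> 10 -> 5 -> 2 -> 1 while preserving the spatial grid; the
  squeezed feature image then feeds the same U-Net (early fusion).  The
  spatial 3x3 extent of the temporal kernels keeps local context without
  touching spatial resolution; the 3D path is order-sensitive by
  construction, which is the point of the variant.
* **Discriminator**: PatchGAN conditioned on the source frames stacked as
  channels next to the (real or generated) map slice — 81 input channels for
  both variants — three stride-2 conv + batch-norm + LeakyReLU blocks, then a
  final strided convolution to one channel and a sigmoid, yielding a patch
  probability grid (2 x 2 for 32 x 32 inputs, 8 x 8 for 128 x 128).

Weights are initialized normal(0, 0.02) (gamma of batch norm at
normal(1, 0.02)).  Small-image presets shrink `n_levels` so the bottleneck
stays at least 1 x 1 (32 x 32 uses five levels).

## Training

Discriminator loss `-E log D(x,y) - E log(1 - D(x,G(x)))`; generator loss is
the non-saturating `-E log D(x,G(x))` plus the L1 reconstruction term, both
weighted 1.  Probabilities are clamped to [1e-7, 1 - 1e-7], which puts exact
analytic anchors on the losses (`2 ln 2` and `ln 2` at an indifferent
discriminator).  Adam with lr 1e-4 and betas (0.5, 0.999) for both networks,
batch size 4, one D step per G step, constant learning rate, dropout 0 (the
implicit GAN noise source is off, so an eval-mode generator is bit-exactly
deterministic).  Inference follows the pix2pix convention for batch
normalization: generated slices are normalized with the statistics of the
test batch, at batch size 1, rather than the training running averages —
running averages accumulated at batch size 4 track the feature
distributions too loosely and were observed to corrupt a subset of
generated slices.  Fine-tuning loads every pretrained weight, resets optimizer
state and trains further on the new domain.  All randomness flows from one
root seed through named substreams (phantom, split, init, shuffle), so runs
are reproducible end to end and stages can be re-run independently.

The network stack (strided 2D/3D convolutions, transposed convolutions,
batch normalization, Adam, reverse-mode autodiff) is implemented directly on
numpy inside `perfsyn.nn`; gradients of every operator are verified against
central finite differences, and the 2D convolution against an independent
correlation oracle.

## Evaluation

MAE, NRMSE (`RMSE / sqrt(mean(y^2))`), SSIM and PSNR per test slice in
normalized space.  SSIM defaults to the single-window (global) form of the
luminance/contrast/structure product with `k1 = 0.01`, `k2 = 0.03`, `L = 2`;
a sliding-window variant (8 x 8 uniform window) is available.  PSNR is
`10 log10(MAX_I^2 / MSE)` with `MAX_I = 2`; a printed-form variant
`10 log10(MAX_I / MSE)` is exposed as an explicit option because that
squared-vs-unsquared choice changes values by ~3 dB and should never be
silent.  Identical images yield an infinite-PSNR sentinel that aggregation
excludes with a count.  Models are compared per slice with the two-sided
paired Wilcoxon signed-rank test (zeros dropped, ties mid-ranked, alpha
0.05; fewer than 5 nonzero differences yields a flagged no-result instead of
a p-value).

## Problem sizes used by the test suite and acceptance script

The suite runs entirely on the small preset: 4 x 32 x 32 phantoms (64
noiseless frames for recovery checks, 32 noisy frames for training data),
five-level U-Nets with `base_channels = 16` and temporal channels
(4, 8, 16, 16, 16, 16), ~200 training slices for the smoke training and
smaller cohorts for the directional comparison.  These sizes are the
package's CI-scale study conditions; full-scale runs (128 x 128, 100
epochs, full channel ladders) use the same code paths through the default
configurations.

The architectural comparison between the two generator variants is scored
after enough epochs for both models to approach convergence at this scale;
comparing half-trained models would measure optimization speed (the deeper
temporal path starts slower) rather than what the architecture can express.

## Known limitations

* GAN quality at CI scale is far below what full-scale training reaches;
  the suite asserts directions and sanity bounds, not clinical-quality
  synthesis.
* The architectural comparison is informative only where the target map is
  hard at phantom scale.  Tmax targets carry deconvolution speckle and pure
  timing structure, and there the temporally aware generator wins by a wide
  margin; TTP comes from the raw tissue curve, is smooth, and both variants
  saturate near the SSIM ceiling, leaving differences inside the seed-noise
  band — the phantom's TTP maps are structurally simpler than clinical ones,
  so that comparison should not be over-read.
* The phantom's geometry is stylized (ellipses); networks trained on it will
  not transfer to real anatomy.
* Batch normalization uses per-batch statistics in training mode, so loss
  traces depend on batch composition; reproducibility is guaranteed only for
  a fixed seed and batch order.
* cSVD here uses a dense SVD of the 2T x 2T circulant matrix per AIF —
  adequate for these grid sizes; an FFT-diagonalized implementation would be
  the next step for throughput.
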