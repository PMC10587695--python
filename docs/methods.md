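# Methods

`polstain` models the full computational chain of "bright-field snapshot
Mueller-matrix microscopy": simulating and inverting a dual
division-of-focal-plane (DoFP) polarimetric microscope, encoding
polarimetric images for learning, translating them to bright-field stain
contrast with an unpaired cycle-consistent adversarial model, and scoring
the translations. This note records the models, the defaults and why, the
numerical choices, and what the synthetic phantom does and does not show.

## Polarimetric model

Light is described by Stokes vectors `S = (S0, S1, S2, S3)` and samples by
4x4 Mueller matrices acting as `S_out = M S_in`. Ideal elements (linear
polarizer, linear retarder, rotation) follow the textbook forms;
`S3 > 0` denotes right-circular light and axes are counterclockwise from
horizontal facing the source. The retarder sign convention is the one free
choice in the algebra; it is anchored so that the polarization state
generator (horizontal polarizer + quarter-wave plate) at fast-axis +15 deg
emits exactly the elliptical state `E1 = (1, 0.750, 0.433, 0.500)`, which
makes the convention externally testable. `E1`/`E2` constants are stored at
the printed 3-decimal precision rather than recomputed at full precision,
so exact comparisons against the tabulated values hold; their degree of
polarization is therefore 1 only to about 1e-5, and tolerances downstream
account for that.

### Instrument model and inversion

The polarization state analyzer is eight intensity channels: a bare DoFP
camera (linear micro-analyzers at 0/45/90/135 deg) and a second DoFP camera
behind a quarter-wave retarder. The retarder's fast axis is not dictated by
the physical design description; the default places it at 45 deg, which
makes `S3` observable with instrument-matrix condition number 2.0. The
configuration is swappable (`PsaConfig`), and removing the retarder
demonstrably drops the instrument rank to 3.

Stokes reconstruction solves the overdetermined 8x4 system `I = A S` with
the Moore-Penrose pseudoinverse — the natural least-squares reading of an
"instrument matrix inverse" for a non-square `A`. Mueller reconstruction
uses four illumination states from quarter-wave-plate presets
`(-45, 0, 30, 60)` deg, chosen so the 4x4 incident-state matrix has
condition number 3.6 (< 10, checked at construction); the exact presets of
the physical instrument are not published, so well-conditionedness was the
selection criterion, fixed before any downstream evaluation. Calibration
estimates `A` from >= 4 known states by least squares. Measurement noise
(gaussian or scaled-poisson) exists for robustness studies only; every
accuracy contract is stated noise-free.

## Encodings

Two translator inputs are supported, both mapped to `[-1, 1]`:

* **PCA of Mueller channels.** The 16 element images are strongly
  correlated; PCA is fitted dataset-level over pooled training pixels
  (mean-centered, not variance-scaled — the elements share units). The top
  1 (PCA1) or 3 (PCA3) scores are kept. Component signs are fixed by making
  the largest-magnitude loading entry positive (PCA signs are otherwise
  arbitrary and would break regression tests). The affine map to `[-1, 1]`
  uses the 1st/99th percentiles of the training scores — robust to score
  outliers — and the bounds are stored in the basis for reuse at test time;
  out-of-range test scores clip. A per-image PCA mode is deliberately not
  implemented: the dataset-level reading matches how the variance is pooled
  in training, and two modes would double every downstream contract.
* **S0-normalized Stokes.** `(S1/S0, S2/S0, S3/S0)`, already dimensionless
  and invariant to illumination intensity. Pixels with
  `S0 <= 1e-6 * max(S0)` are set to zero (division safety; the choice of
  floor only affects unilluminated pixels).

Bright-field RGB images map by `x/127.5 - 1` to match the generator's tanh
range. Patch extraction tiles row-major with flush-to-edge remainder
patches so every pixel is covered; stitching averages overlaps and is an
exact inverse when stride equals patch size.

## Translation model

Two generators (`G`: polarimetric -> bright-field, `F`: inverse) and two
70x70 PatchGAN discriminators are trained with

```
L = L_GAN(G, D_Y) + L_GAN(F, D_X) + lambda (E||F(G(x)) - x||_1 + E||G(F(y)) - y||_1)
```

The generator is the residual translation design: 7x7 stem at `base_width`
channels, two stride-2 downsampling convolutions, nine residual blocks at
quarter resolution, mirrored transposed-convolution upsampling back to
`base_width` at full resolution, and a 7x7 tanh projection. "Three steps"
of down/upsampling is read as stem + two strided convolutions — the only
reading consistent with a final full-resolution feature map of
`base_width` channels before the output projection; a strict
three-strided-convolution variant sits behind `strict_strided`. The
discriminator stacks 4x4 convolutions with widths (64, 128, 256, 512, 1)
and strides (2, 2, 2, 1, 1), leaky-ReLU 0.2, instance norm on the middle
layers; its receptive field is 70 px and a 256 px input yields a 30x30
prediction map. Convolutions feeding an instance norm carry no bias — the
normalization cancels a bias exactly, and a parameter with identically zero
gradient would be dead weight.

Because no GPU deep-learning stack is a dependency, the layers (conv,
transposed conv as the exact adjoint, instance norm, activations) and Adam
are implemented directly over NumPy with explicit backward passes,
verified against finite differences. Float32 im2col + BLAS matmul keeps
CPU training of the toy-scale models tractable.

Training choices the source description leaves open, fixed as the standard
choices of this model family: Adam with `lr0 = 2e-4`, betas (0.5, 0.999);
`lambda = 10`; a replay pool of 50 past fakes for discriminator updates;
optional identity loss off by default. Both adversarial-loss variants are
provided: `log` (the printed minimax form, discriminator outputs through a
sigmoid) and `least_squares` (labels 1/0 on the raw map); both must pass
the convergence checks. The learning-rate schedule is constant for the
first half of the epochs then linearly decays to zero (epoch 75 of 100
with 50 flat epochs gives exactly `0.5 lr0`). Batches cycle independently
shuffled permutations of the two domains — pairing is never used in
training. All randomness (init, shuffling, pool) flows from one
`TrainConfig.seed`, making loss histories bit-for-bit reproducible.

Transfer learning copies all four networks' weights from a donor and
resets optimizer state; architecture mismatches fail loudly with the
offending shapes.

## Evaluation metrics

* SSIM: 11x11 gaussian window (sigma 1.5), K1 = 0.01, K2 = 0.03, dynamic
  range 255, channel-averaged (computed via scikit-image with exactly these
  settings; cross-checked against a direct sliding-window implementation).
* RMSE on the [0, 1] intensity scale.
* JSD between 256-bin per-channel histograms, base-2 logarithm so the
  value is bounded by 1; `0 log 0 = 0`.
* EMD between the same histograms along the 0-255 gray axis (units: gray
  levels), via the 1-D cumulative-difference identity; cross-checked
  against an independent optimal-transport implementation.

Histogram binning, channel handling and scales are declared conventions —
the magnitudes they produce are consistent with how such scores are
typically reported, but none of them is uniquely recoverable from published
tables alone. `evaluate_pairs` supports paired ground-truth mode and
cycle-reconstruction mode (`x` vs `F(G(x))`) for unpaired settings.

## Synthetic phantom

The phantom emulates the statistical structure the method assumes, not
histology appearance: nuclei are random ellipses carrying absorption
(transmittance 0.55) and partial depolarization (`diag(1, p, p, p)` with
p = 0.6 — the simplest physical depolarizer, and the blend of a retarder
with an ideal depolarizer reduces to exactly this form); stromal fibers are
smooth random walks carrying linear retardance (0.5-1.5 rad at the core,
gaussian cross-profile) with slow axis along the local tangent; background
is a 0.96 isotropic transmittance. Bright-field styles composite per-class
optical densities through Beer-Lambert attenuation: H&E (blue-purple
nuclei, pink stroma), Ki-67 and TTF-1 (DAB-brown positivity-flagged nuclei
on blue counterstain, 30% positive by default). Palette extinctions are
documented constants, not fits to real stains. Two objective
magnifications are emulated by rendering the same geometry at two pixel
pitches. Stokes images in rendered datasets go through the full
simulate-intensities / reconstruct-Stokes chain, so dataset consistency
with the instrument model is by computation, not construction.

What passing on the phantom shows: the acquisition model inverts
correctly; encodings preserve the polarimetric contrast that localizes
nuclei (depolarization) and fibers (retardance); the unpaired objective
can recover a cross-modality mapping when such a mapping exists; transfer
between stain styles accelerates convergence. What it does not show:
performance on real tissue texture, stain variability, scanner color
profiles, registration error, or DoFP sensor artifacts — none of which the
phantom models.

## Problem sizes

Toy-scale defaults used by the test suite and examples, chosen as the
package's CPU-scale study conditions: 64 px scenes (8 nuclei, 3 fibers),
40-scene training sets, width-8 generator / (8, 16, 32, 64, 1)
discriminator, batch 2, 200 training iterations (10 epochs of 20
iterations), 3 seeds. Convergence is measured on the 10-iteration moving
average of the forward cycle loss. The architecture geometry checks
(receptive field, 30x30 map) always use the full-width specification.

## Known limitations

* CPU-only: full-scale (256 px, 100-epoch, thousands-of-patches) training
  is out of reach of the NumPy engine; the design scales the study down
  rather than changing the method.
* The printed-precision `E1`/`E2` constants propagate ~1e-5 DoP slack.
* The generator requires spatial sizes divisible by 4 (two stride-2
  stages).
* Histogram metrics on small toy images are noisier than at clinical
  image sizes; identities and invariances are exact, magnitudes are not
  comparable across scales.
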