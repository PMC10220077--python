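# Methods

## The physical model

A 2-D fast spin-echo (FSE) acquisition fills k-space one phase-encode (PE)
line at a time; each repetition (TR) acquires one echo train of `etl` lines
(default 13, as in a typical T2-weighted FSE head protocol with a 256 × 256
matrix). Rigid head motion *between* TRs leaves each echo train internally
consistent but inconsistent with its neighbours, and such line-wise
inconsistencies reconstruct as ghost replicas displaced along the PE axis.

The simulator models exactly that failure mode:

1. **Motion bank.** From one motion-free image, build every rigid in-plane
   transform on a fixed grid — integer translations up to ±10 px (step 1)
   along the vertical, horizontal and one diagonal direction, and rotations
   up to ±5° (step 0.5°) about the grid center ((H−1)/2, (W−1)/2). The
   identity is excluded, giving 20 transforms per translation direction plus
   20 rotations: 80 bank entries at the default grid.
2. **Echo-train schedule.** PE lines 0…n_pe−1 are partitioned into TR
   blocks of `etl` consecutive lines (linear view ordering; an interleaved
   ordering is available). 256 lines at etl 13 → 19 full blocks + one of 9.
3. **Motion timeline.** Independently per TR block, the subject is "still"
   with probability 1 − p_motion (default p_motion = 0.5) or has moved into
   one uniformly drawn bank pose. The mixing ratio is a free parameter of
   the simulation (real scans have no single canonical value); it is
   recorded in every manifest.
4. **Line substitution.** The corrupted k-space takes each block's lines
   verbatim from the chosen source's k-space (centered/fftshifted
   convention, unnormalized forward DFT); still blocks keep the original's
   lines bitwise. The corrupted image is the complex magnitude of the
   inverse transform — the standard MRI magnitude image.

Key correctness oracles (all in the test suite): an all-still timeline
reproduces the original to 1e−9; a timeline constant at bank entry *j*
reproduces exactly entry *j*'s image; wrap-around translation obeys the
Fourier shift theorem; and corrupting along one PE axis equals transposing
the corruption of the transposed image along the other axis.

## Synthetic phantoms

The generator composes concentric ellipses into a head-like slice at
T2-ish contrast: bright scalp/fat rim, mid-gray parenchyma, bright
CSF-filled ventricles and two bright anterior eyeballs on a dark (air)
background, with seed-controlled jitter of centers and intensities
(default ±5%) emulating subject/slice variability. Intensities default to
the range (0, 255), arbitrary units.

What the phantom does **not** emulate: anatomical texture (tissue is
piecewise constant), receive-coil bias fields, noise, partial-volume
edges, or any pathology. Tests passing on phantoms therefore demonstrate
the correctness of the simulation/training/evaluation machinery and the
qualitative behaviour of the models — not clinical performance on real
T2 images. Ventricles and eyeballs are rendered bright (T2-like CSF and
vitreous) because the visual assessment of correction quality focuses on
those structures.

## Dataset construction

Per PE direction, a pool of (corrupted, clean) pairs is simulated with one
derived seed per pair (all seeds flow from a single global seed through
stable per-stage salts). Splitting is by seeded shuffle then slicing, with
round-half-away-from-zero arithmetic: the training pool is round(0.9·n),
validation is round(0.1 · training pool), test is the remainder — at
n = 5500 exactly 4455/495/550. The "both directions" model trains on the
first half (after a seeded shuffle) of each direction's train+validation
pool: 2475 + 2475 = 4950, with validation re-carved per direction
(round(0.1·2475) = 248 each) so that every subset is exactly
direction-balanced; test sets stay direction-pure so consistent,
inconsistent and both-direction conditions remain expressible. Splits are
at the image level, not the subject level — a known limitation shared with
the study design this follows.

Model inputs are min-max normalized per image onto [0, 1]; outputs are
clipped to [0, 1] and rescaled onto [0, 255].

## Correction models

All three models map a normalized corrupted image to a restored image of
the same size and are trained with Adam, batch size 1.

- **Autoencoder** — 4 Conv(2×2)-ReLU-MaxPool(2×2) encoder stacks, first
  stack 32 channels, doubling per stack; the decoder mirrors with
  nearest-neighbour upsampling; sigmoid head. Trained with MSE.
- **U-Net** — depth 4, first layer 64 channels, 3×3 filters, two
  Conv-ReLU per level, concatenation skips at every resolution, sigmoid
  head. Trained with MSE.
- **Conditional GAN** — pix2pix-style: the generator is the U-Net above
  built from Convolution-BatchNorm-ReLU blocks with dropout (p = 0.5)
  active during training as the source of generator stochasticity; the
  discriminator is a PatchGAN over the (condition, candidate) channel
  pair — four stride-2 4×4 convolutions (64→128→256→512, BatchNorm except
  the first, LeakyReLU 0.2) and a 1-channel projection + sigmoid, yielding
  a patch decision map of side input/16. The generator objective is the
  adversarial term plus λ·L1 to the clean target with λ = 100. The
  discriminator maximizes E[log D(x,y)] + E[log(1 − D(x,G(x)))]; the
  generator trains on the non-saturating form −E[log D(x,G(x))] (the
  standard stable surrogate for the minimax objective) plus the L1 term.
  Updates alternate 1:1. Adam betas are (0.5, 0.999) for the GAN and
  (0.9, 0.999) for the reconstruction models.

The networks run on a small reverse-mode automatic-differentiation engine
written on numpy (`kmotion.nn`): im2col-based convolution with exact
backward, 2×2 max-pooling, nearest upsampling, batch norm with running
statistics, and Adam. Gradients of every spatial op are verified against
central finite differences in the test suite. Training is exactly
reproducible from the seed (pure numpy, no threading nondeterminism).

## Presets and numerical choices

Two named configurations:

- **paper** — 256×256 images, 5500 pairs per direction, 100 epochs,
  learning rate 2e-4, the channel widths above. This is the full-scale
  study configuration; it is documented, runnable (`--allow-large`), and
  deliberately never exercised by the test suite.
- **desk** — the reduced scale at which every test and the acceptance
  script run: 64×64 phantoms, 40 pairs per direction, 5 epochs, thinner
  networks (U-Net depth 3 / 16 first channels; autoencoder 3 stacks / 16
  channels; discriminator base width 8), learning rate 2e-3. The higher
  rate and the small discriminator are deliberate at this scale: with only
  ~10² gradient steps the models must move quickly, and a full-width
  discriminator overpowers a 16-channel generator.

Stability choices: discriminator probabilities are clamped to
[1e−7, 1 − 1e−7] before logs; an optional global gradient-norm ceiling
(desk: 1.0) guards the tiny-batch runs against the occasional exploding
step that can drive the sigmoid head into permanent saturation; training
aborts with a diagnostic on any non-finite loss.

## Image quality metrics

SSIM is computed from **global** image statistics (no sliding window), in
two selectable forms: the default transcribes the printed formula with
cross term 2σ_Xσ_Y (σ = population standard deviation) and constants
C1 = (0.01·2000)² = 400, C2 = (0.03·2000)² = 3600; the
`standard_covariance` mode replaces the cross term with 2·cov(X, Y), the
usual structural form. A 255-based constant set is available
(`SSIMConstants.from_dynamic_range(255)`). The two conventions are kept
side by side because the global formula with a σ-product cross term and a
2000-scale constant is unusual but internally consistent; no intent is
guessed beyond offering both.

PSNR is 10·log10(peak²/MSE). By its printed definition the peak is the
maximum absolute value of the first (corrected or corrupted) image, and
`psnr()` implements exactly that; identical images return +∞. The
evaluation harness, however, compares candidates that are all mapped onto
the same (0, 255) output scale, so `evaluate_condition` defaults to the
fixed dynamic-range peak of 255 — otherwise a restoration that improves
MSE can be penalized merely for not containing a single maximal pixel.
Both behaviours are one keyword apart.

Condition comparisons use a **paired** two-tailed t-test on per-image
values (the same test images underlie every condition), significance at
p < 0.005 with no multiple-comparison correction. Improvement rates are
100·(mean_corrected − mean_baseline)/mean_baseline against the
uncorrected ghosted baseline. Zero-variance difference vectors are
reported as degenerate rather than fed to the t distribution.

## What the desk-scale results do and do not show

Five epochs on 36 tiny synthetic pairs demonstrate that the pipeline
learns: reconstruction losses fall, and corrected test images beat the
ghosted baseline on mean global SSIM and PSNR for the U-Net and the CGAN
(the autoencoder typically improves SSIM but can lose PSNR — its
bottleneck blurs aggressively, the same qualitative behaviour the
full-scale study reports for it). Absolute values at desk scale are not
comparable to full-scale results on real T2 images, which require the
paper preset and acquired volunteer data.

## Known limitations

- In-plane rigid motion only; no through-plane, sub-pixel, or intra-readout
  (frequency-encode) motion, no spin-history or parallel-imaging effects.
- Image-level (not subject-level) splits.
- The per-TR motion model draws poses independently per block; real motion
  is temporally correlated (a run-length variant is noted but not built).
- Global-statistics SSIM is far less discriminative than windowed SSIM;
  values cluster near 1 even for visibly ghosted images. It is kept because
  it is the evaluation definition this package implements; windowed SSIM is
  deliberately out of scope.
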