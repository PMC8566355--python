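# Methods

## The artifact model

Wrap-around (aliasing) occurs when anatomy extends beyond the encoded
field of view: the out-of-FOV signal folds back onto the opposite side of
the reconstructed image. `mrwrap.simulator` models this purely in the
image domain. Given an artifact-free image **I** ∈ ℝ^{M×N} with
nonnegative intensities and an exact-zero background, the simulation has
two parameters: the shift distance *d* ∈ [1, N] (how many columns fold
back — the size of the corrupted area) and the layer intensity *r* > 0
(how strongly the folded signal contaminates it).

1. **Artifact layer** Î: for a right-side wrap, the rightmost *d*
   columns of Î receive the leftmost *d* columns of **I**, scaled by *r*;
   all other entries are exactly zero. A `side="left"` switch mirrors
   this; vertical wrap is out of scope.
2. **Support patterns** F = [I > 0], F̂ = [Î > 0]. Strict positivity is
   deliberate: it is why generated and stored images must keep an exact
   zero background (the I/O layer never injects an epsilon).
3. **Overlay** I_r = (I + Î) ⊙ F. Folded signal landing on blank
   background carries no diagnostic harm and is discarded by the F mask.
4. **Wrapped-area map** V = (F + F̂) ⊙ F ∈ {0, 1, 2}: 0 background,
   1 clean anatomy, 2 corrupted anatomy. `artifact_mask = (V == 2)` is
   the training target for mask estimation.
5. **Brightness correction**: with I1 = Σ I over V=1 and I2 = Σ I over
   V=2, the wrapped region of I_r is rescaled to avoid contrast
   distortion from the additive overlay.

Indexing: the defining equations are 1-based with wrap condition
"d + n̂ ≤ N"; internally everything is 0-based (layer columns < N−d are
zero). The test-suite oracle is written per-pixel from the 1-based form
to guard the translation.

### The brightness-correction ambiguity (a deliberate design decision)

The correction's published form multiplies the wrapped region by the raw
ratio I2/I1, while its stated goal is to *maintain* the clean image's
unwrapped:wrapped brightness ratio. These are not the same thing: the
raw ratio is typically 0.02–0.35 for realistic geometries, so the
published form darkens the wrapped band by up to 50×, and — because the
factor approaches 1 as *d* grows — distortion is *not* monotone in the
shift distance (measured per-phantom PSNR across the level presets is
U-shaped). The package exposes three modes on
`apply_brightness_correction` / `simulate`:

* `"as_printed"` (default): multiply by I2/I1, the literal published
  definition. Artifacts are strong and easily learnable at every level;
  severity is not monotone in PSNR.
* `"preserve_ratio"`: multiply by I2 / Σ_{V=2} I_r, which restores the
  wrapped area's total brightness to its artifact-free value and hence
  preserves I1:I2 exactly. This mode degrades smoothly (I_s → I as
  r → 0⁺; PSNR nonincreasing in r at fixed d; monotone across the level
  presets) but on near-piecewise-constant phantoms the ghost becomes
  very subtle at minor levels.
* `"inverted"`: multiply by I1/I2, for experimentation.

The default follows the published formula; the smooth-degradation
properties are asserted in the tests under `"preserve_ratio"`, and the
monotone-degradation acceptance check against the default pipeline is
knowingly left failing rather than papered over.

### Distortion-level presets

Severity grades 1–5 (minor, mild, moderate, severe, non-diagnostic) map
to (d/N, r) presets: 1→(0.15, 0.3), 2→(0.22, 0.5), 3→(0.30, 0.7),
4→(0.38, 0.9), 5→(0.45, 1.1). The clinically used values were chosen by
a radiologist per image and never published; these defaults are
monotone stand-ins, fully configurable, and carry no claim of clinical
equivalence.

## The phantom generator

`mrwrap.phantom` emulates a T1-weighted brain slice: a centered head
ellipse (default 0.9 of the frame width, 0.9 of its height) holding
`n_ellipses` (default 6) internal elliptical structures with intensities
drawn from `intensity_range` (default (0.2, 1.0]) over a mid-range base
tissue value, plus foreground-only Gaussian noise (σ = 0.02) clamped back
into the range so support never changes. Background is exactly zero.

The head-width default matters: a wrap of *d* columns corrupts anatomy
only where *d* exceeds the full background margin on both sides
(wrapped-band width = d − 2·margin for a centered object), so a head
narrower than ~0.7 of the frame would make the minor presets
artifact-free. 0.9 mirrors a brain that nearly fills the clinical FOV.

What the phantoms do **not** emulate: gyral/sulcal texture, tissue-class
noise statistics, bias fields, partial-volume edges. Consequences are
visible in the results: ghosts over near-constant tissue are carried
almost entirely by the brightness change (which is why the
ratio-preserving correction nearly cancels minor-level artifacts here,
and why passing benchmarks on phantoms say nothing quantitative about
clinical images).

## DUARN

Two U-nets. Each has a 3×3 stem; four encoder stages (2×2 stride-2
convolution, feature normalization, ReLU); four decoder stages (2×2
transposed convolution, normalization, ReLU, concatenation with the
matching-resolution skip, 3×3 fusing convolution, normalization, ReLU);
and a 1×1 head. Channel widths per scale are configurable: (64, 128,
256, 512) at full scale, (8, 16, 32, 64) as the CPU-scale default.
Inputs must be divisible by 16 (inference pads and crops automatically).

* **Phase 1 (artifact estimation)**: input the artifacted image, output
  per-pixel probability of lying in the wrapped area; trained with BCE
  against the simulated mask.
* **Phase 2 (deep elimination)**: input the artifacted image
  concatenated with the phase-1 *probability* map; the loss mask P1 is
  that map binarized at 0.5 (the probabilities-in, binary-for-loss split
  resolves an underdetermined point in the protocol). Output is the
  restored image, trained with

      L = a · mean(P1 ⊙ (I − Y)²) + b · BCE(I, Y),   a = 0.75, b = 0.25.

  The masked-MSE term is read as per-pixel squared error gated by P1 and
  averaged over all pixels — the only well-formed reading of a scalar
  loss "multiplied" by a mask — implementing a small weight for losses
  outside the artifact area; BCE (with the clean [0,1] intensities as
  soft targets) runs over all pixels and penalizes boundary
  misalignment. The endpoints a=0 / b=0 reproduce the BCE-only and
  MSE-only ablation variants.

Design choices that the architecture text leaves open, and why:

* **Identity-at-start restorer.** The phase-2 head is zero-initialized
  and its output is added to logit(input) before the sigmoid, so the
  untrained restorer is exactly the identity map. Off-artifact pixels
  already equal the target, so training only has to learn the in-mask
  correction; without this the network first wastes capacity
  reconstructing the whole image and reliably *degrades* minor-level
  inputs.
* **Instance normalization** rather than batch statistics. At the
  prescribed batch sizes (2 for phase 1, 1 for phase 2) batch statistics
  are noisy and systematically different between training and
  single-image inference; per-sample statistics are identical in both.
  Measured on the scaled benchmark, moving inference to per-image
  statistics improved held-out restoration by 6–11 dB at every level.
  (At batch size 1 the two coincide during training.)
* **Adam "momentum"** is read as β₁ (0.8 / 0.9 per phase), β₂ = 0.999.
* **Early stopping**: patience 10 on validation loss (10% of the
  training samples), min-delta 1e-5, best-weights restore; the
  configured learning rate is an initial rate, halved after every 3
  stale epochs.
* **Augmentation**: horizontal flip (image, target and mask together, so
  a right-side artifact becomes a consistent left-side one), rotations
  restricted to ±10° with nearest-neighbour mask co-transformation, and
  ±10% brightness gain re-clipped to [0, 1]; each applied with
  probability 0.5 per sample.

The networks are implemented in `mrwrap.nn`, a compact NumPy framework
with hand-derived gradients (im2col 3×3 convolutions, reshape/einsum
2×2 strided and transposed convolutions, instance norm, Adam), verified
against central finite differences to ~1e-8 relative error in the test
suite. Arithmetic is float32; training is deterministic for a fixed seed
on a fixed BLAS.

## Evaluation

PSNR = 10·log₁₀(MAX²/MSE) dB with MAX defaulting to 1.0 (the normalized
domain); identical images report +∞. SSIM uses the standard windowed
form: 11×11 Gaussian window (σ = 1.5), K₁ = 0.01, K₂ = 0.03, population
local variances, mean over the valid interior; it matches
scikit-image's implementation to < 1e-6 (asserted in the tests, where
scikit-image serves as the independent reference, not the
implementation). `evaluate_benchmark` aggregates artifacted-vs-clean and
restored-vs-clean PSNR/SSIM per distortion level and overall.

## The scaled benchmark and problem sizes

`mrwrap.benchmark.run_benchmark` is the package's end-to-end check,
sized for a single CPU core (a few minutes): 40 phantom sources × 5
levels = 200 samples at 64×64, split 80/20 by source (160 train / 40
held out), widths (8, 16, 32, 64). Because a desk-scale epoch budget
cannot emulate full-scale training to convergence at the published
rates, the benchmark uses compressed-schedule initial rates (1e-3 phase
1, 1e-4 phase 2) with plateau decay; epoch caps are 30 / 40. The
dataset-protocol checks separately reproduce the full corpus shape (140
sources × 5 levels = 700 samples; 80/20 split by source → 28 test images
per level).

## Known limitations

* Results on elliptical phantoms do not transfer quantitatively to
  clinical T1 images (no texture, no scanner noise model); the published
  per-level SSIM/PSNR table is not reproducible without the original
  private images and full-scale training.
* The mask estimator is trained only on artifacted samples, so on an
  artifact-free image it hallucinates a plausible band (~9% of pixels)
  and the restorer edits it (restored-vs-input ≈ 24 dB). Outside the
  estimated mask the pipeline is near-identity (> 30 dB). Screen inputs
  for artifact presence before restoring.
* Only horizontal, single-fold wrap is modeled: no vertical wrap, no
  multi-artifact composition, no k-space physics.
* BCE with non-binary targets (phase 2) is used as defined; it is a
  proper scoring rule for [0,1] intensities but its gradient weighting
  differs from MSE, and nothing here establishes it is optimal.
* The wrapped band inherits a single multiplicative correction per
  image; real aliasing can overlap with coil-profile shading that this
  model ignores.
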