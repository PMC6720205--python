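# Methods

## Problem and scope

Real time-lapse images of cleavage-stage human embryos are scarce and
ethically restricted, which limits the training of image-analysis models
for embryology. `embryogan` implements a pipeline that (a) trains a
generative adversarial network (GAN) to synthesize grayscale one-, two-
and four-cell embryo-like frames, and (b) quantifies how close a
generated set is to a real set using first-order (histogram),
second-order (co-occurrence texture) and human-judgment statistics.
Because clinical embryo image sets cannot be redistributed, the package
ships a parametric phantom generator that emulates the statistical and
visual structure of such data; every component is testable against it.

## Phantom data

A phantom frame is a piecewise-constant drawing plus noise: a
mid-gray culture-well interior bounded by a bright ring, a darker region
outside the well, and 1/2/4 translucent cell discs whose interiors sit
slightly below the background level and whose membranes (rims) are
darker still. On top of the drawing sit a mild additive illumination
ramp in a random direction, Gaussian sensor noise, and a small fraction
of salt-and-pepper pixels. Defaults: 600×600 px frames, well radius
0.88 of the half-width, cell radii 0.18–0.30 of the well radius, rim
contrast 45 intensity units, noise σ = 6, salt-and-pepper fraction
0.002, illumination ramp 4 % of full scale peak-to-peak. Levels were
chosen once to make a frame that is "almost the same gray" overall, as
embryo microscopy frames are, with cells visible mainly through their
darker membranes. Cells may overlap (cell division produces overlapping
blastomeres in real data); `allow_overlap=False` places them disjointly
for geometry-based tests.

Each frame is a pure function of `(config, seed)` and bit-identical
across runs. Dataset seeds are split as `SeedSequence(base_seed,
spawn_key=(class, index))`, so any subset is reproducible without
generating the rest. The generator also emits labeled ground-truth cell
masks and the analytic geometry (centres, radii, painted levels), which
the tests use as an oracle: mask pixel counts match πr² to within a
one-pixel perimeter band, and the noise-free frame mean matches the
area-weighted mean of the painted layers to within boundary
rasterization.

What the phantom does *not* model: real optics (defocus, halos),
fragmentation, 3- and 5-cell or blastocyst stages, and biological
texture inside the cytoplasm. Passing evaluation tests on phantoms
therefore demonstrates that the pipeline's statistics behave correctly,
not that the GAN reaches clinical realism.

## Networks

Both networks are dense (fully connected), implemented in NumPy with
hand-written analytic gradients.

* Discriminator (6 layers): flatten → dense → LeakyReLU(α = 0.2) →
  dense → LeakyReLU(0.2) → dense(1) with a sigmoid head. Default widths
  512, 256.
* Generator (11 layers): 100-value standard-normal latent →
  [dense → LeakyReLU(0.2) → batch-norm] ×3 → dense(side²) with a tanh
  head → reshape. Default widths 256, 512, 1024. The tanh head pairs
  with mapping 8-bit frames affinely to [−1, 1]; a sigmoid/[0, 1] mode
  is selectable.

Batch normalization standardizes each hidden activation with the batch
mean and biased variance in training mode and keeps running averages
with momentum 0.8 (`running ← 0.8·running + 0.2·batch`) for inference.
Learned scale/shift start at identity. Weights are initialized
N(0, 0.02²); widths are configurable because desk-scale runs use
smaller stacks than the full 200×200 configuration.

Training uses binary cross-entropy with probabilities clipped at 1e−7,
and a from-scratch Adam optimizer: exponential moving averages of the
gradient and its square, bias-corrected by 1/(1−β₁ᵗ) and 1/(1−β₂ᵗ),
step θ ← θ − a·m̂/(√v̂+ε). Defaults a = 2e−5, β₁ = 0.7 (the recipe's
stated values), β₂ = 0.999, ε = 1e−8 (conventional). The same settings
drive both networks. Correctness is pinned by three independent
oracles: a finite-difference gradient check of BCE∘discriminator and of
the full generator chain (1e−4 relative), a textbook-transcription Adam
trajectory (1e−6 over 100 steps), and the closed-form first-step
magnitude ≈ a.

## Training loop

Per iteration: sample a real batch (uniform with replacement) and an
equal-sized generated batch; one combined discriminator Adam step
toward labels real = 1 / fake = 0; then one generator Adam step through
the updated discriminator. No label smoothing, no schedules. The
default generator objective is the non-saturating surrogate
(BCE of D(G(z)) against 1); the saturating `log(1−D(G(z)))` form is a
config flag. Losses are recorded every iteration; checkpoints
(parameters, batch-norm running statistics, Adam state, loss history,
a 4×4 sample grid) are written every `checkpoint_every` iterations in a
versioned `.npz` container.

All randomness at iteration t comes from streams keyed by `(seed, t)`,
which makes runs bit-reproducible and checkpoint resumption exact: a
run of i₁ iterations, saved and continued for i₂ more, reproduces the
(i₁+i₂)-iteration history bit for bit on a single thread.

Mode collapse is monitored by the mean pairwise L2 distance between
samples, with frames scaled to [0, 1] and distances divided by
√(H·W) so the score lies in [0, 1] and equals 0 only for identical
samples (i.i.d. uniform-noise frames score ≈ √(1/6) ≈ 0.41).

## Evaluation

Histograms. Each image contributes its own probability-normalized
256-bin histogram; a set is summarized by the mean histogram. Two sets
are compared with Pearson correlation over bins, the Chi-square
statistic Σ(H₁−H₂)²/H₁ (bins with H₁ = 0 are skipped — the convention
of the statistic's common implementation), the intersection Σmin(H₁,H₂)
(1 for identical probability histograms; `rescale_pair` provides a
sum-2-over-the-pair compatibility normalization), and the Bhattacharyya
distance √(1−Σ√(H₁H₂)/√(H̄₁H̄₂N²)), which reduces to
√(1−Bhattacharyya coefficient) for probability histograms and lies in
[0, 1].

Texture. Images are quantized to 64 gray levels and the symmetric,
normalized gray-level co-occurrence matrix (GLCM) is accumulated at
distance 1 over angles {0°, 45°, 90°, 135°} and averaged (the classic
rotation-invariant protocol); all settings are arguments. From the
GLCM the 14 Haralick statistics are computed with natural logarithms
and 0·log 0 = 0: energy (angular second moment), contrast, correlation,
variance, homogeneity (inverse difference moment), sum average, sum
variance (moment about the sum average — the standard correction of the
original formula's misprint), sum entropy, entropy, difference
variance, difference entropy, the two information measures of
correlation, and the maximal correlation coefficient (square root of
the second-largest eigenvalue of the Q matrix, restricted to levels
with nonzero marginals). Degenerate inputs (single nonzero GLCM cell)
give entropy 0 and NaN for the correlation-type features, reported
rather than silently replaced.

Feature sets are compared per feature with a two-sample Welch t-test
(two-sided; pooled-variance mode available) at α = 0.01. Features that
are the same constant in both groups are reported as t = 0, p = 1.
Globally, PCA is fit separately on each 14-column feature matrix; the
explained-variance ratio of PC1 and the absolute Pearson correlation
between the two PC1 loading vectors are reported (loading vectors are
used because per-image score vectors from different sets have no
pairing; the absolute value removes the eigenvector sign ambiguity).

Expert judgments. For visual-Turing-test tallies the package computes
per-class true recognition rate TRR = 100·accepted/generated and the
pooled misclassification rate 100·Σ(generated−accepted)/Σgenerated,
with half-up decimal rounding for reported percentages, plus a
majority-vote reduction from long-format per-judge CSVs.

A median filter (odd window, edge-duplicating reflected padding)
is provided for salt-and-pepper cleanup of generated frames.

## Numerical and design choices

* 600→200 downscaling is an exact 3×3 block mean (integer-factor block
  averaging generally), with bilinear interpolation only for
  non-integer ratios — deterministic and brute-force checkable.
* Histogram bin count 256 (native 8-bit), GLCM levels 64, both
  configurable.
* One combined discriminator update on the concatenated real+fake batch
  rather than two half-updates, for determinism simplicity.
* Layer widths, latent distribution (standard normal), output
  activation (tanh), β₂ and ε are not dictated by the training recipe;
  the canonical dense-GAN choices above are the defaults and all are
  overridable.

## Desk-scale problem sizes

The test suite and the acceptance script exercise the full pipeline at
reduced size, chosen as the package's own verification scale: phantom
counts and rotation-augmentation arithmetic run on 16 px thumbnails
(the counting logic is size-independent); the adversarial behavior
check trains on 120 one-cell 64×64 phantoms for 2,000 iterations with
batch 32 and widths 128/256/512 (G) and 256/128 (D). At that scale the
run completes in minutes on one CPU and already shows the qualitative
signatures of successful adversarial coupling: finite losses, a
positive diversity score, held-out discriminator accuracy between the
coin-flip floor and perfect separation, and a generated-set histogram
far closer to the real set than to uniform noise.

## Known limitations

* Dense (not convolutional) networks limit achievable visual fidelity;
  the architecture is intentionally the simple reference configuration.
* The phantom's realism gap (see above) means evaluation numbers on
  phantoms do not transfer to clinical data.
* Exact bit-reproducibility of training is guaranteed only
  single-threaded; multi-threaded BLAS may reorder reductions.
* The unconditional generator does not take a class label; per-class
  models are obtained by training on per-class subsets.
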