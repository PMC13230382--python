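# Methods

This note records the models, numerical choices and limitations of the
`spsct` toolkit in enough detail to reproduce or audit any stage.

## Synthetic chest phantoms

Each phantom is a 2-D HU image built from analytic shapes with a
per-phantom `numpy.random.Generator`: an air background (−1000 HU), a
soft-tissue body ellipse (+40 HU) with a thin +700 HU bony rim, two −800 HU
lung ellipses, 3–8 contrast-opacified vessel cross-sections (+300 HU,
radius ≈ 3–6 % of the image side, placed by rejection sampling against the
lung's Euclidean distance transform so each disk clears the lung boundary),
and — in PE-positive cases — 1–3 soft-tissue embolus disks (radius 2–6 px)
strictly inside vessels, modelling partial filling defects. Masks are
recorded exactly as drawn; the class invariants (embolus ⊆ vessel,
`pe_present` ⇔ non-empty embolus mask, HU ∈ [−1024, 3071]) are enforced at
construction.

What the generator emulates: the tissue-contrast structure that drives
lung-window and soft-tissue-window rendering, partial-volume behaviour of
small vessels, and a cohort with controlled PE prevalence (default 0.5,
the composition of a balanced reader set). What it does not emulate:
anatomical texture, noise from photon statistics, 3-D/helical geometry,
motion, or contrast-timing variability. Passing tests therefore
demonstrate correctness of the pipeline's operators and the direction of
its effects, not clinical performance on patient data.

Cohorts draw distinct member seeds without replacement from the cohort
generator and shuffle the PE labels, so exactly `round(n·prevalence)`
cases are positive and the whole cohort is reproducible from one integer.

## Projector

Parallel-beam geometry, angles uniform on [0, π), detector of unit-pitch
bins centred on the image centre (N−1)/2, default bin count = image side.
Line integrals are computed by sampling each ray at half-pixel steps with
bilinear interpolation; the backprojector scatters with identical weights,
making the pair (A, Aᵀ) an exact transpose up to float64 rounding — a
property the algebraic reconstructions rely on, and which the test suite
checks to 10⁻⁶ relative (measured ≈ 10⁻¹⁵). The inner loops are compiled
with numba; a vectorized NumPy implementation of the same arithmetic
remains in the module as a fallback and as a cross-check target.

HU → attenuation uses μ = μ_water(1 + HU/1000) with μ_water = 0.0192 per
pixel unit, so air maps to exactly zero; reconstructions are converted
back to HU through the inverse before windowing.

Sparse acquisitions keep every (full/target)-th view starting at view 0,
preserving the full-view count as provenance. Subsampling commutes:
`sub(sub(S, 512), 128) = sub(S, 128)`.

## Reconstruction

*FBP.* Rows are ramp-filtered in the frequency domain using the
band-limited spatial-kernel construction of the Ram-Lak filter (avoids the
DC bias of a naive |ω|), zero-padded to the next power of two ≥ 2·bins;
optional cosine/Hann apodization. Pixel-driven backprojection with linear
interpolation, scaled by π/(2·n_views). On a 128×128 disk phantom with
2048 views the mean reconstructed attenuation inside the disk is within
0.1 % of truth (acceptance bound: 5 %).

*SIRT.* `x ← x + λ·C·Aᵀ·R·(b − A·x)` from a zero start, with R and C the
inverse row/column sums of the system matrix (computed by projecting a
unit image and backprojecting a unit sinogram); entries with vanishing
sums are zeroed so empty rays drop out. λ = 1 and 100 iterations by
default, the protocol's settings; λ is a relaxation factor in this update
even where the protocol calls it a regularization parameter. The residual
2-norm is recorded per iteration; non-finite iterates raise an error
naming the iteration.

*OS-SART.* The same normalized update restricted to consecutive angle
blocks (default 8 views), swept in sequential order, 50 iterations; each
block uses its own column-sum normalizer (SART normalization). With one
block per sweep the update sequence equals SIRT's exactly, which the tests
assert to 10⁻¹².

No positivity constraint is applied in either method.

## Dual-frame U-Net

Architecture as in the module docstring: depth 4, two 3×3 convolutions +
ReLU per block, 2×2 max pooling/unpooling, channel widths doubling from
`base_channels` (64 at full scale, 16 in the desk-scale configuration),
skip-and-concatenate from each encoder block output to the matching
decoder block input, and the dual-frame skip-and-subtraction bypass: the
features directly after each pooling are subtracted from the decoder
features directly before the matched unpooling. Unpooling re-uses the
switch indices of its paired pooling layer — i.e. it is the pooling
operator's adjoint, which the dual-frame construction requires.
Convolutions are zero-padded ("same") so all blocks preserve shape, and a
1×1 convolution forms the residual output.

Design choices where the design was open:

- **Residual head initialized to zero.** The final 1×1 convolution starts
  at zero weights, so the untrained network is exactly the identity
  correction and training can only improve on the sparse input. With the
  short desk-scale schedule this removes the transient in which a randomly
  initialized head injects noise into the corrected image.
- **Residual target is the difference of windowed images**
  (`windowed(full) − windowed(sparse)`), so input + target reconstructs
  the windowed full-view image exactly — an identity the tests assert.
- **Optimizer** is Adam (β₁ = 0.9, β₂ = 0.999) with the stated schedule:
  lr₀ = 10⁻³ multiplied by e^(−0.1) after every epoch.
- **Model selection**: the weights of the epoch with minimal validation
  loss are returned, with the full loss history retained.
- **Determinism**: all tensor work is NumPy float32 with a seeded
  Generator for initialization and batch shuffling; there are no
  nondeterministic kernels, so identical seeds give identical weights.

Training is implemented with explicit backpropagation (im2col/GEMM
convolutions in NHWC layout); gradients are verified against float64
central differences in the test suite. The loss surface of a
max-unpooling network has genuine discontinuities where pooling switches
flip; the gradient check therefore jitters biases off the tie points of
the zero initialization.

## Image-quality metrics

SSIM uses the Gaussian-windowed formulation: 11×11 window, σ = 1.5,
K₁ = 0.01, K₂ = 0.03, weighted population moments per window, map averaged
after cropping the 5-pixel half-window border. The implementation matches
a direct per-window evaluation to 10⁻⁸ and scikit-image's
`structural_similarity` (gaussian_weights, sample covariance off) to
10⁻⁷. PSNR is 10·log₁₀(range²/MSE) with an infinite-value sentinel for
identical images. Both are computed on lung-windowed images with
data_range 1, matching the (0,1) normalization of the pipeline. CIs over
per-image values default to the Student-t interval (deterministic); a
seeded 10 000-draw percentile bootstrap is available.

## Diagnostic statistics

- **Dice**: 2|A∩B|/(|A|+|B|); two empty masks score 1 (agreement on
  absence), exactly one empty scores 0. The degenerate convention only
  affects synthetic fixtures.
- **Case classification**: quality 0 ("not diagnostic") forces FN/FP by
  truth; evaluable positives are TP iff reader∩gold is non-empty
  (Dice > 0) — marking additional healthy vessels does not revoke a TP —
  else FN; evaluable negatives are TN iff no segmentation was drawn.
- **Wilcoxon signed-rank**: zero differences dropped; for n ≤ 25 the
  two-sided p comes from the exact sign-flip distribution of W⁺, built by
  polynomial convolution over doubled midranks (exact under ties); above
  25, the normal approximation with the standard tie correction and no
  continuity correction. The switch point is where exhaustive enumeration
  stops being worthwhile; both branches are cross-checked against
  enumeration and scipy.
- **DeLong**: AUC as the Mann-Whitney statistic with ties at ½; variance
  from the structural components V₁₀, V₀₁ (sample covariances); Wald 95%
  CI truncated to [0, 1]; the paired test uses the 2×2 component
  covariance. Degenerate zero-variance comparisons return z = 0, p = 1
  for identical scores. Type-I error of the paired test is verified by
  simulation (2 000 seeded null replicates at n = 200; rejection rate
  must fall in [0.03, 0.07] at α = 0.05).
- **Dose**: effective dose = DLP × 0.014 (chest conversion factor); dose
  fraction = views/2048 under the linear dose-views assumption.

## Automated reader (synthetic fixture)

The pipeline scores reconstructions with a deterministic stand-in reader:
candidate emboli are connected clusters (≥ 2 px) of vessel-interior pixels
(vessel mask eroded by 1 px, discounting partial-volume edges) whose
reconstructed HU falls below 120 — between the reconstructed contrast pool
and reconstructed thrombus at desk scale; ordinal quality/confidence/
artifact ratings are binned from the image's SSIM against the full-view
reference (thresholds 0.30/0.45/0.60/0.75/0.85). It exercises the scoring
and classification logic only; it does not model human perception, and its
threshold is tied to the phantom's tissue values.

## Experiment orchestration and problem sizes

`run_experiment` derives all randomness from one master seed via named
`SeedSequence` substreams (cohort, training, reader), splits the cohort at
the phantom level (no phantom in two splits), trains one network per view
subset, and evaluates the test split once, after model selection. The
default configuration mirrors the full study design (512×512, 2048 views,
six subsets, 50 epochs, base 64 channels); the desk-scale configuration
used by the test suite and the acceptance script — 64×64 phantoms,
200/40/20 split, base 16 channels, 10 epochs, the 32-view subset — was
chosen so a complete run finishes in minutes on a single CPU while
preserving every qualitative effect: streak formation, monotone
degradation, iterative smoothing, and residual-learning recovery.
SIRT/OS-SART comparisons are computed on the test split only.

## Known limitations

- Phantoms are piecewise-constant; SSIM values are higher across the
  board than on textured patient data, so only orderings and differences
  are meaningful, not absolute levels.
- At 64×64, a 32-view acquisition is much closer to angular Nyquist than
  at 512×512, so the sparse-view degradation is milder than at full
  scale; directions are preserved, magnitudes are not.
- The projector models no detector noise or photon statistics — sparse
  sampling is the only corruption, by design.
- The automated PE-detection network of the original study (exam-level
  detection from a trained CNN ensemble) is out of scope; the DeLong
  machinery accepts any user-supplied scores instead.
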