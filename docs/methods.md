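# Methods

This note documents the models, parameter choices and numerical decisions
behind `her2pss`, and what the synthetic-data experiments do and do not
establish.

## Scoring model

HER2 IHC scoring maps membrane-staining intensity and completeness in
tumor cells to an ordinal category 0 < 1+ < 2+ < 3+ (ASCO/CAP). The
package frames this as 4-class image classification with three
distinctive ingredients:

1. **Pyramid-Sampling Sets.** One classifier input is a channel stack of
   square patches from multiple scales of the same core: full-resolution
   patches carry membrane morphology, downsampled patches carry tissue
   architecture, and a whole-core thumbnail carries global context.
   Patch positions are drawn uniformly at random *with replacement* over
   all valid top-left coordinates (replacement keeps the sampler
   well-defined when few positions exist, e.g. a core barely larger than
   the patch). No tissue-content filter is applied: the method is
   deliberately ROI-free, so patches may land on background.
2. **Class-weighted cross-entropy.** Clinical datasets are imbalanced
   across scores. Weights `w_c = M/(C·n_c)` (M = total training cores,
   C = 4) make balanced data yield unit weights and keep the loss scale
   comparable across datasets; the identity `Σ_c w_c n_c = M` holds for
   any counts and is asserted in tests.
3. **Replicate/top-k/max inference.** The PSS sampler is stochastic, so a
   single forward pass sees only part of the core. The protocol scores
   `N` independent PSSs, ranks them by confidence, and takes the maximum
   class among the top `k`. The max (rather than a vote or mean) encodes
   the clinical convention that the strongest expression present drives
   the score, and is what makes the protocol sensitive to small
   high-expressing regions.

### Confidence

The replicate confidence is the top-two softmax margin `p(1) − p(2)`:
zero for an uninformative (uniform) output, approaching one for a
near-one-hot output. The maximum probability is available as an
alternative (`confidence_method="max_prob"`); the margin is the default
because it directly measures *preference between* categories rather than
absolute mass on one. Ties in confidence are broken by the lower replicate
seed, making KCS membership deterministic.

## Backbones

The backbone contract is input `(patch_size, patch_size, D_in)` → softmax
4-vector, with `D_in = 3 ×` patch count. Two backbones:

* **Small convnet (default, trainable here).** Four conv(3×3)–ReLU–
  maxpool(2×2) blocks, global average pooling, linear 4-way head;
  implemented in numpy (explicit im2col backprop) because no
  deep-learning framework is assumed in the runtime environment. Batch
  normalization is intentionally omitted: at this depth it is not needed
  for convergence, and its absence keeps the hand-written backward pass
  simple and exactly reproducible. Verified against central-difference
  directional derivatives in the test suite.
* **DenseNet-201 (documented reference).** The full-scale layout — 7×7
  initial convolution over all `D_in` stacked channels, dense blocks of
  6/12/48/32 layers, 1×1-conv + 2×2-average-pool transitions, softmax
  head — is recorded as a frozen spec (`densenet201_reference_spec`).
  Training it requires GPU-scale resources and is out of scope; every
  other module is backbone-agnostic by construction.

## Training parameters

| parameter | default | note |
|---|---|---|
| optimizer | AdamW (decoupled weight decay 1e-4; biases not decayed) | |
| learning rate | 1e-5 | full-scale protocol default; the small numpy backbone is trained at 3e-3 in tests (documented in the train config) |
| batch size | 12 | |
| LR schedule | halve after 5 epochs without validation-loss improvement, floor 1e-7 | the plateau rule is a concrete choice for the loosely specified "reduce on plateau" |
| augmentation | one of the 8 dihedral transforms, per patch | per-patch (not per-PSS) maximizes orientation diversity; each patch is an independent spatial sample, so coherence across the stack carries no information |
| PSS resampling | fresh PSS per core per epoch | stochastic sampling doubles as regularization |
| epoch selection | parameters of the best validation-loss epoch | validation PSSs use fixed seeds so the criterion is comparable across epochs |
| log clamp | 1e-12 | numerical guard in the loss; warned, never silent |

Training is fully deterministic given the config seed (one CPU, fixed
BLAS): all epoch shuffles, PSS seeds and augmentations derive from it.

## Synthetic IHC generator

The generator emulates exactly the features the scoring protocol relies
on, and nothing more:

* a circular tissue core (counterstain-toned disk on a near-white
  bright-field background) populated with cell-like objects: a
  hematoxylin-blue nucleus disk plus a DAB-brown membrane ring;
* class-conditional staining: ring blend intensity and angular
  completeness both increase with HER2 class (defaults 0.05/0.10,
  0.30/0.40, 0.60/0.75, 0.95/1.00 for 0/1+/2+/3+), making the mean
  membrane DAB signal strictly monotone in class;
* heterogeneity as **one contiguous angular sector** of specified area
  fraction expressing one class lower — contiguous rather than
  salt-and-pepper, so a random patch sampler can genuinely miss it;
* fixed cell scale (default radius 9 px) independent of core diameter,
  as under a fixed objective; density defaults to 12 cells /10⁴ px²
  (cell area fraction ≈ 0.3, modest ring overlap).

Closed-form expectations of the generator's own stain statistics (mixture
of background, nucleus and ring area fractions; overlap ignored) are
exported so tests compare rendered images against an analytic oracle; the
observed overlap bias is below the 5e-3 test tolerance, an order of
magnitude under the per-class signal spacing.

It does **not** model optics, scanner noise, stain variation, nuclear
pleomorphism or tissue texture. A green parameter-recovery test therefore
establishes that the pipeline is wired correctly and that multi-scale
sampling plus max-aggregation behave as designed — not that the small
backbone would score real tissue. The desk-scale defaults (256-px cores,
64-px patches, an 8+2+1 pyramid, 51→11 patches) exist solely to keep a
full train/predict cycle in CPU-minutes; full-scale values remain plain
configuration.

## Core detection

TMA dearraying runs in two stages: (1) proposals from a circular Hough
transform on a Canny edge map of the ×4-downsampled grayscale slide, with
accumulator threshold 0.15 and greedy Euclidean non-maximum suppression at
the requested minimum separation; (2) full-resolution refinement — within
a window around each proposal, tissue is segmented by thresholding
against the background level estimated from the window border, holes are
filled, and 2–3 centroid/equivalent-radius iterations give subpixel
center and radius (the coarse Hough grid alone quantizes both by the
downsampling factor). Out-of-bounds crop regions are filled with white,
the bright-field background, never reflected. The full-scale detector
this reconstructs was described only as Hough-based, so this module is a
faithful generic reconstruction, not a parameter-level replica.

## Consensus labeling

A core's label requires agreement of at least two raters. Two policies
were genuinely open and are fixed as follows: a **nondiagnostic flag
excludes only as a majority** (nondiagnostic quality is a property of the
core, not a per-rater veto — a lone flag does not override remaining
consensus); and an **adjudicator must match one of the tied or candidate
scores** (an adjudicator introducing a third score cannot create
two-rater agreement, so such cores are excluded as discordant).
Train/validation/test splits are assigned per *patient* (deterministic
shuffle, cumulative core-count cuts) so no patient spans two splits.

## Monte Carlo simulation

Subsets of size `N` are drawn from each core's replicate pool **without
replacement** (the pool members are themselves independent replicates;
replacement would double-count). Subsets are resampled independently per
core in every repetition. Replays never re-run the network: a per-core
confidence ranking is precomputed, and selecting the `k` smallest ranks
within a subset is exactly the KCS rule restricted to that subset (a test
verifies the replay against exhaustive subset enumeration on a toy pool).
Desk-scale profile: pool 30, 1,000 repetitions; full-scale (pool 300,
10,000 repetitions, `N` to 200, `k` to 100) is configuration only.

## Evaluation choices

* **Adjacent-pair accuracy**: restricted to cores whose true label is in
  the pair; any prediction outside the pair counts as an error (the most
  conservative reading of "differentiating between" two scores).
* **ROC/AUC**: positive-group score is the summed probability over the
  positive classes of the grouping; explicit threshold sweep over unique
  scores; trapezoidal AUC. Cross-checked against the midrank
  Mann–Whitney U statistic to 1e-12, including ties.
* **Averaged top-k probabilities** for ROC reuse the same KCS selection;
  the mean of simplex points is already on the simplex, so the final
  renormalization is a numerical no-op (asserted in tests).
* Degenerate denominators (specificity with no true negatives, empty
  pair subsets) yield NaN with a warning, never a silent zero.

## Known limitations

* The numpy backbone is desk-scale; no pretrained weights, no GPU path,
  no color normalization (the method assumes a single-scanner color
  distribution; cross-scanner transfer would need additional adaptation).
* The synthetic world is separable by design at the defaults; boundary
  classes (0 vs 1+) are the first to blur when staining tables are made
  less separable, mirroring the clinically hardest distinction.
* Core detection assumes roughly circular, well-separated cores on a
  bright background; folded or torn tissue is out of scope.
* Bit-exact reproducibility is guaranteed within one BLAS configuration;
  different threading backends may perturb training trajectories at the
  float32 rounding level.
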