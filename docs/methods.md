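# Methods

This note documents the models and procedures `cardiopcso` implements, the
choices made where the design was genuinely open, and what the synthetic
test beds do and do not establish.

## Predator Crow Search Optimization (PCSO)

PCSO is a bounded continuous minimizer hybridizing two population
metaheuristics.

**Predator phase dynamics.** A population of τ "prey" positions moves
relative to a *raiding elite* — the best position found so far — through
three phases keyed to the iteration fraction Q/Qmax (the velocity ratio
between raider and prey):

* **Phase 1** (Q < Qmax/3, exploration): Brownian steps
  `step = Y_A ⊗ (elite − Y_A ⊗ prey)`, `prey ← prey + C·U ⊗ step`, with
  `Y_A` i.i.d. standard normal and `U` uniform(0,1).
* **Phase 2** (middle third): the first ⌈τ/2⌉ agents take Lévy steps
  against the elite (development); the rest take Brownian steps scaled by
  the decay `M(Q) = (1 − Q/Qmax)^(2Q/Qmax)` (discovery).
* **Phase 3** (final third, exploitation): all agents take M-scaled Lévy
  steps `Y_R ⊗ (Y_R ⊗ elite − prey)`.

Lévy steps use Mantegna's algorithm with tail exponent 1.5, giving the
occasional long jump that escapes local basins; `M` anneals from 1 to 0,
shrinking late-stage moves into a local search around the elite.

**Raid jump.** Each prey also proposes a masked long leap
`prey + M·(Smin + U ⊗ (Smax − Smin)) ⊗ H` with `H` an elementwise
Bernoulli(0.2) mask: a jump towards a random box point on a random 20 % of
dimensions. The parenthesization (a random point *inside* the box) is the
reading that keeps jumps in bounds before clipping.

**Crow search.** A parallel population of crows each follows the memorized
personal best of a uniformly chosen *other* agent:
`crow ← crow + rand·FL·(mem_j − crow)` with flight length FL = 2. Memory is
the per-agent best accepted position — the record of "where food was".

**Hybridization and acceptance.** Each iteration, the raid-jump candidate
(from the phase-stepped prey) and the crow candidate blend 50/50 into one
hybrid proposal per agent, which is evaluated and accepted only if it
improves that agent's fitness. Greedy acceptance makes the best-fitness
history non-increasing by construction; the elite is the argmin over all
evaluations. Crows fly to their proposed positions regardless of
acceptance, so crow exploration continues even through rejected hybrids.
One objective evaluation per agent per iteration plus the initial sweep:
τ·(Qmax + 1) evaluations total.

Defaults (C = 0.5, FL = 2.0, mask probability 0.2, Lévy exponent 1.5) are
the conventional values of the parent algorithm families and are all
exposed in `PCSOConfig`. Bound handling is clipping. Termination is the
fixed iteration budget, with an optional stagnation-window early stop that
is off by default. Calibration (in the test suite): on the 5-D sphere with
τ = 20, Qmax = 200, the median final best over 20 seeds is below 1e-2,
orders of magnitude below an equal-budget uniform random search.

## Information-gain feature selection (IGFS)

A feature's score is `IG(X, Y) = H(Y) − H(Y|X)` in bits, with
`H(Y|X) = Σ_v P(X=v)·H(Y|X=v)`. Numeric features are discretized first —
equal-width with 10 bins by default (deterministic and friendly to the
schema's declared ranges; equal-frequency is available). Features are
ranked descending with stable ties by original order; the selection
threshold is the mean IG by default, with fixed-value and top-k rules as
alternatives. Fitted bin edges are reusable on held-out data (out-of-range
values clip into the end bins), so selection never sees test rows.

## The tabular classifier and its training

The classifier is a dense network, input → 128 → 64 → 32 → 1, ReLU hidden
units and a sigmoid output, with per-hidden-layer batch normalization and a
positive-class weight in the binary cross-entropy. It is implemented
directly in NumPy; the flattened parameter vector (weights, biases, BN
scale/shift) is the PCSO search point.

Population search has no minibatch updates, so batch-norm moments are
computed once from the training split and frozen before each fitness
evaluation — fitness is then a deterministic function of the weight
vector. The fitness itself is the weighted BCE on an internal stratified
validation split (20 %), which guards the search against memorizing the
training split. The search box is [−3, 3] per weight, sized for z-scored
inputs. An optional Adam refinement of the best weights (learning rate
1e-3, 20 epochs, batch 32, dropout active) exists but is off by default;
BN moments are treated as per-epoch constants there, making normalization
a fixed affine map inside each epoch.

Calibration: on linearly separable 2-feature data (n = 400, margin 1) the
full 128/64/32 network trained with τ = 30, Qmax = 150 reaches held-out
accuracy ≥ 0.9 (typically 1.0); with shuffled training labels, held-out
accuracy stays at chance.

## Explanation layer

The interpretability method is deliberately minimal and model-agnostic:

* **Global:** permutation importance — the mean increase in validation
  loss when one feature column is independently shuffled, with its s.d.
  over repeats — reported beside the IG ranking for cross-reference.
* **Local:** central finite-difference sensitivity ∂p/∂x_j per sample.

Importance is computed on *held-out* data. On training rows, permuting
even an uninformative feature that the overfit network happens to use
systematically raises the loss, biasing its importance away from zero;
out-of-sample, that memorization component vanishes and pure-noise
features sit within sampling noise of zero.

## Preprocessing

Gaussian denoising (separable convolution, reflect boundary so borders do
not darken; σ = 0 is the identity); z-score standardization using the
*population* s.d. (deterministic idempotence; `ddof=1` switches
conventions) with fitted statistics reapplied to held-out rows — never
refitted; |z|-threshold outlier flagging with correction by the same
mean/mode imputation used for missing values; SMOTE oversampling
(interpolation towards one of k = 5 nearest minority neighbours until the
minority/majority ratio reaches the target — synthetic rows are convex
combinations, so they stay inside the minority bounding box); paired
image/mask augmentation (90° rotations, flips, linear contrast on the
image only); and a stratified train/test split using largest-remainder
allocation so split sizes are exact.

SMOTE and the class-weighted loss are independent switches; nothing in the
design requires choosing one.

## U-Net segmentation

The network has five encoder and five decoder blocks. Each block is
conv3×3 → BN → ReLU → conv3×3 → BN → ReLU → dropout(0.1); encoder blocks
end in 2×2 max pooling (stride 2) and double the channels 8 → 16 → 32 →
64 → 128; decoder blocks start from a 2×2 transposed convolution, halve
the channels and concatenate the mirrored encoder activation. Kernels are
He-Normal initialized; a final 1×1 convolution yields per-pixel scores for
background / cavity / myocardium (a binary whole-heart mode is the
n_classes = 2 case). All layers are NumPy (im2col convolutions with
explicit backward passes), trained with Adam (learning rate 1e-3) on soft
multi-class Dice loss over the foreground classes, batch size 4 by
default — with ~50 training images, small batches give enough update steps
in a 20-epoch budget.

Same-padding is the default and preserves the input size, which is
required to be divisible by 2^(depth−1). The single-convolution size
arithmetic for valid padding (256 → 254 with a 3×3 kernel) is available in
`conv_output_size`; a full valid-padding U-Net additionally needs cropped
skip connections and specially matched input sizes, and the network raises
an informative error rather than silently mis-handling it.

**ROI cropping ("perfect ROI").** The input is cropped to the bounding box
of the *reference* mask expanded by a margin, optionally grown to the
divisibility requirement, with an exact paste-back inverse. Because the
box derives from ground truth, this is an upper-bound evaluation protocol:
it removes localization error and isolates segmentation quality.

Calibration: depth-5/base-8 U-Net, 20 epochs on 50 noisy 64×64 phantoms,
reaches mean held-out Dice ≥ 0.9 (typically ≥ 0.99).

## Metrics

Accuracy, precision, recall (= TPR), FPR from the confusion counts; F1 is
the harmonic mean 2PR/(P+R) by default. A halved variant
((1/2)·PR/(P+R)) is provided as `variant="printed"` for comparison with
sources that print that form — note it cannot exceed 0.5 and is below both
precision and recall by construction, so it is not the reported default.
Degenerate denominators yield 0 with a logged warning. The ROC curve
sweeps the unique scores with ties grouped, anchored at (0,0) and (1,1);
AUC is trapezoidal and equals the Mann–Whitney concordance probability
(verified to 1e-10 in the tests). IoU = Dice/(2 − Dice) per class, with
empty/empty defined as 1.

## Cross-validation harness and pipeline

Stratified k-fold (k = 5 default) assigns per-class members round-robin
after a seeded shuffle keyed to sample ids, handing remainders to the
currently smallest folds — every sample validates exactly once and fold
sizes differ by at most one. Everything fitted — imputation, z-score
statistics, feature scores, classifier weights — uses only the training
folds.

The end-to-end pipeline (simulate/load → clean → IGFS → SMOTE →
PCSO-train → metrics → explain) logs every stage and writes a manifest
(config echo, seeds, library versions) sufficient to reproduce a run
bit-for-bit. Two pipeline-level choices differ from the bare classifier
defaults, both from the harness calibration runs:

* the pipeline's default weight box is [−1, 1] — with batch-norm layers
  absorbing scale, the narrower box conditions the population search
  better than [−3, 3] and measurably improves fold accuracy;
* when SMOTE has rebalanced the training prior, predicted probabilities
  are Bayes-corrected back to the original prevalence before the 0.5
  threshold (training under an artificial 50/50 prior otherwise
  systematically over-calls the minority class on imbalanced test data).

Calibration: on strong-signal synthetic data (n = 1000, three planted
effects of 2.0), mean 5-fold accuracy ≥ 0.85 with the default budget
(τ = 20, Qmax = 60 per fold).

## Synthetic data

**Tabular generator.** Mirrors the 15-feature MACCE schema: numeric
marginals uniform within the declared clinical ranges (the simplest
distribution consistent with range-only information), categorical codes
uniform. The label is Bernoulli under a logistic model on the standardized
informative columns with user-set coefficients; the intercept is solved on
the realized sample so class-1 prevalence matches the requested imbalance
(default 0.3, which exercises the SMOTE path). Known ground truth makes
feature-recovery and dose-response tests exact. The generator mirrors the
schema's marginals only — not any real joint distribution, feature
correlations, or non-logistic label structure — so passing tests
demonstrate correct machinery, not clinical performance.

**Phantom generator.** Concentric disc (cavity, brightest) inside an
annulus (myocardium, mid-grey) on a dark background — the minimal geometry
with the topology of a short-axis left-ventricle slice — at randomized
centre and radii, with Gaussian intensity noise (σ = 0.05 by default ≈
13 % of the cavity/myocardium contrast). Phantoms have exact masks and
analytic areas. They lack cine-MRI appearance: no texture, bias fields,
papillary muscles, through-plane effects, or anatomical variability; Dice
values here are an upper bound of sorts on what the same network could do
on real data, and the scaled-down problem (tens of 64×64 images, 20
epochs) is chosen to keep the full suite runnable on one CPU in minutes.

## Numerical choices

* Entropies in bits (log₂); 0·log 0 := 0; IG clipped at 0 for rounding
  negatives below 1e-12.
* BCE probabilities clipped to [1e-7, 1 − 1e-7]; BN ε = 1e-5.
* Dice/IoU on empty/empty masks defined as 1; soft-Dice gradient derived
  analytically and verified against finite differences.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give bitwise-identical
  results, including full optimizer and training runs.

## Known limitations

* PCSO searches the full ~11 k-dimensional weight vector; it reliably
  solves well-conditioned problems at this scale but is not competitive
  with gradient training on hard decision boundaries — the optional Adam
  refinement exists for that.
* The valid-padding U-Net mode is size arithmetic only (see above).
* The explanation layer is permutation importance + finite differences;
  it does not attempt Shapley-style attribution.
* Headline clinical figures reported for this family of methods on
  permission-gated datasets are not reproducible from synthetic phantoms
  and are not targeted by this package's tests.
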