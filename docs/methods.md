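# Methods

## Problem

Estimation of model accuracy (EMA) asks: given a protein target sequence and a
pool of candidate 3D structural models ("decoys") but *no* experimental
structure, predict each model's quality so the best model can be selected. The
quality measure used throughout is GDT-TS normalised to [0, 1]. The pipeline
implemented here follows the CASP-style EMA designs that pair distance-map
features with deep learning: features are derived from the agreement between a distance map predicted from the
sequence (PDM) and the distance map computed from a model's coordinates (MDM),
optionally combined with external per-model quality scores and a pairwise
consensus score, and a deep-learning ensemble regresses those features onto
GDT-TS.

## Distance-map features

All map comparisons use Cβ atoms (Cα for glycine), the convention of the
distance predictors whose output a PDM emulates; GDT-TS and lDDT use Cα. For a
model with missing residues the MDM carries an observation mask; masked entries
never enter any feature.

Direct map agreement:

- `dist_pearson` / `correlation_feature` — Pearson correlation of aligned
  upper-triangle entries with sequence separation ≥ 6 observed in both maps.
  The two names are kept because different predictor presets refer to the same
  quantity under both; they are computed identically here. Fewer than 3 pairs
  or zero variance yields the sentinel 0 with a logged warning.
- `dist_rmse` — RMSE over the same aligned entries, clipped to the 16 Å cap
  (sentinel: the cap itself when no pairs align).
- `dist_recall`, `dist_recall_long` — fraction of the PDM's sub-8 Å pairs
  (separation ≥ 6, or ≥ 24 for the long-range variant) realised below 8 Å in
  the MDM. Pairs touching missing model residues leave both numerator and
  denominator.
- `dist_precl2`, `dist_precl2_long` — precision of the top ⌈L/2⌉ candidate
  pairs ranked by ascending predicted distance (ties broken lexicographically
  on (i, j) for determinism); candidates must be observed in both maps.
- `contact_short/medium/long` — fraction of listed predicted contacts of each
  CASP separation class (short 6–11, medium 12–23, long ≥ 24; |i−j| < 6
  ignored everywhere) realised below 8 Å in the MDM. The contact threshold is
  8 Å with strict inequality.

Image similarity. Both maps are rendered to 8-bit images with intensity
`round(255·(1 − min(d, 16)/16))` — short (contact-bearing) distances bright,
everything beyond 16 Å black — then resized bilinearly to a common 128×128
grid so the features are comparable across target lengths:

- `dist_ssim` — mean structural similarity (11×11 Gaussian window, σ = 1.5,
  K1 = 0.01, K2 = 0.03, dynamic range 255), mapped to [0, 1] via (SSIM+1)/2.
- `dist_psnr` — peak signal-to-noise ratio in dB, capped at 100 dB (identical
  images), reported as PSNR/100.
- `dist_phash` — 64-bit DCT perceptual hash (resize to 32×32, 2-D DCT, 8×8
  low-frequency block with the DC term dropped and the next coefficient
  appended, thresholded at the median); feature = 1 − Hamming/64.
- `dist_orb_num` — up to 500 ORB keypoints per image, brute-force Hamming
  matching with Lowe's ratio test at 0.75 (distance-0 best matches always
  accepted); feature = matches/500.
- `dist_gist` — GIST-style descriptor: mean Gabor magnitude (4 scales × 8
  orientations) on a 4×4 grid → 512 dimensions; feature = (cosine+1)/2.

Every similarity feature lies in [0, 1]; degenerate inputs map to documented
sentinels (never NaN) so training is total over any generated dataset.

## Reference scores

**GDT-TS** is estimated with an LGA-like deterministic heuristic rather than
the LGA program: superpositions are seeded from every sliding window of
lengths 3/5/7 along the residues shared by model and reference; each seed is
refined by re-superposing (Kabsch) on the residues currently within the
threshold until a fixed point (≤ 10 iterations), for each threshold in
{1, 2, 4, 8} Å. For very short shared chains (≤ 12 residues) all residue
triples (and quadruples at ≤ 9) are added as seeds, which brings the
heuristic within 0.05 of an exhaustive subset-superposition oracle while
never exceeding it. The score is the mean over thresholds of the largest
fitting fraction; the denominator is always the full target length, so
missing residues in partial models count as failures (CASP convention).

**lDDT** is the Cα variant: reference pairs are native Cα pairs within a 15 Å
inclusion radius (|i−j| ≥ 1); the score is the mean over {0.5, 1, 2, 4} Å of
the fraction of reference pairs whose model distance differs by less than the
threshold, with pairs touching missing model residues counted as unpreserved.
The all-atom original is out of scope; the Cα form preserves the score's
superposition-free structure.

**Pairwise consensus** stands in for the multi-model feature class (the
original predictors consumed APOLLO/Pcons/ModFOLDClust2 scores): a model's
score is its mean symmetrised pairwise GDT-TS against the other pool members.
For pools above 30 models a fixed-seed (1729) random reference subset of 30
keeps the cost bounded on CASP-sized (150-model) pools.

**Partial models and domains.** A predicted score is multiplied by
n_present/L. Targets with declared domain boundaries are scored per domain
slice (model, PDM and contact list restricted and renumbered) and the domain
scores averaged.

**Evaluation** follows the CASP EMA convention: per-target ranking loss
(true GDT-TS of the pool's best model minus true GDT-TS of the model the
predictor ranks first; predicted ties break lexicographically on model id)
and per-target Pearson correlation, averaged overall and within the four
difficulty categories (TBM-easy, TBM-hard, FM/TBM, FM).

## Predictor

The regressor is a five-dense-layer network (256/128/64/32/1 units), ReLU
hidden activations, a logistic output unit so predictions live in [0, 1], a
batch-normalization layer between the second and third dense layers, and
dropout (rate 0.2) after the first and third. Loss is mean-squared error,
optimised with Adam (learning rate 1e-3, batch 64) and early stopping
(patience 10) on the validation fold. Widths, optimiser, loss and patience
are this package's choices; layer count and batch-norm/dropout placement
follow the published architecture. The network is implemented directly on
numpy — the datasets are small and the architecture is explicit this way —
and its backpropagation is verified against finite differences in the test
suite.

Training splits targets (not decoys) into K folds of near-equal size, so no
target's decoys straddle a member's train/validation boundary. Member k
trains on folds ≠ k and validates on fold k. Prediction is either the mean
of the K member outputs or, with two-stage stacking, the output of a stage-2
network whose input is the original features concatenated with the K stage-1
outputs (input width n_features + K). The stage-2 network trains on the same
structural models under the same fold partition, with fold 0 as its
early-stopping validation split — a choice this package makes where the
original description is silent. Features are z-scored with statistics of the
full training table, persisted with the model; constant columns get unit
scale (they standardise to zero).

Presets map six predictor configurations to their feature subsets:
`construct`, `cluster`, `ai`, `hybrid` (multi-model; include the consensus
feature), `deep` and `dist` (single-model). `ai` uses K = 5, the others
K = 10; `construct`, `hybrid`, `deep` and `dist` use two-stage stacking,
`ai` and `cluster` ensemble averaging. External-tool score columns are
optional inputs: when absent, a preset degrades to its computable
distance/contact/consensus subset with a logged notice, so the pipeline runs
without any third-party binaries.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
exercised:

- **Native**: a compact self-avoiding Cα random walk — consecutive spacing
  3.8 Å, non-adjacent pairs ≥ 4.0 Å (rejection sampling, ≤ 10⁴ retries per
  step), with a bias (0.9) toward the running centroid so long-range contacts
  exist. Cβ sits 1.5 Å off Cα along a deterministic local-frame bisector.
- **Decoys**: native coordinates plus a chain-correlated Gaussian
  displacement field (iid noise smoothed by a 5-residue moving average, then
  rescaled to per-atom sd σ). Smoothing is essential: iid noise destroys
  local geometry unrealistically fast and makes GDT-TS collapse; the
  correlated field yields the graded quality spectrum over
  σ ∈ {0.5, 1, 2, 4, 8} Å that the tests rely on. σ = 0 reproduces the
  native; a configurable fraction of decoys loses a terminal segment to
  exercise the partial-model path.
- **PDM**: native Cβ map plus symmetric Gaussian noise (sd τ), clamped ≥ 0
  with zero diagonal. Contact lists are thresholded from the PDM at 8 Å with
  logistic-of-margin probabilities. τ encodes target difficulty: the default
  benchmark alternates τ = 0.5 (labelled TBM-easy) and τ = 3 (labelled FM),
  purely so category-wise evaluation is exercisable.
- **External scores**: ρ·standardised(truth) + √(1−ρ²)·noise, min-max
  rescaled to [0, 1]; ρ = 0.6 by default, a mid-informative surrogate for
  third-party single-model scores.

What these pools do *not* emulate: real protein stereochemistry, secondary
structure, method-correlated decoy error (all decoys here share one error
model), or realistic distance-predictor error structure (real predicted maps
have contact-dependent, non-Gaussian error). Passing the end-to-end checks
therefore demonstrates that the pipeline is implemented coherently —
features track true quality, training recovers the mapping, ranking works —
not that any blind-assessment benchmark numbers are reproduced; those
require real CASP data and the original third-party feature programs.

## Problem sizes and numerical choices

The end-to-end benchmark used by the acceptance checks generates 10 targets
of length 60 with 100 decoys each (σ grid above, τ ∈ {0.5, 3}), trains the
two-stage `deep` preset (surrogate externals at ρ = 0.6) on 8 targets for up
to 60 epochs and evaluates on the 2 held-out targets — sizes chosen so the
whole experiment runs in minutes on one CPU while leaving clear headroom
above the pass thresholds (mean per-target Pearson ≥ 0.8, mean ranking loss
≤ 0.05). Tie-breaks are lexicographic everywhere a ranking or sort occurs;
all randomness flows from explicit integer seeds through
`numpy.random.default_rng`, and retraining with the same seed reproduces
predictions bit-for-bit.

## Known limitations

- The GDT-TS heuristic is a lower bound on the exhaustive optimum; its
  agreement is verified only at small sizes where enumeration is feasible.
- lDDT is Cα-only, so side-chain packing errors are invisible to it.
- The consensus feature subsamples references on large pools; scores on
  pools > 30 are estimates of the full pairwise mean.
- Secondary-structure, solvent-accessibility and energy features of the
  original predictors enter only as optional external columns; nothing in
  this package computes them.
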