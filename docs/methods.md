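# Methods

This note records the models, defaults and numerical choices behind `molrl`,
and what its synthetic test bed does and does not demonstrate.

## Generator: SMILES language model

SMILES strings are tokenized with a minimal scheme: the two-character
organic-subset halogens `Cl`/`Br` and any bracketed atom `[...]` are single
tokens; every other character is its own token.  This is the smallest rule
set for which detokenization reproduces the input exactly.  The vocabulary
is built from the training corpus plus reserved `PAD`/`START`/`END` markers
(PAD fixed at index 0); its size is data-driven and recorded in run
manifests rather than hard-coded.

The policy network is a stack of recurrent layers (LSTM by default, GRU
selectable; the RL machinery is cell-agnostic) over one-hot token inputs,
followed by a dense softmax head.  Library defaults are 2 × 256 units,
dropout 0.3 between recurrent layers, batch 16, 25 epochs, Adam at 1e-3
with the gradient norm clipped at 3, 65 tokens maximum, sampling
temperature 0.9.  The dropout rate is our choice (only the presence of
dropout is canonical); masks are sampled per batch and held fixed across
time steps.

Pre-training is teacher forcing: each step conditions on the ground-truth
prefix and the loss is the mean per-token categorical negative
log-likelihood.  Sampling is autoregressive; logits are divided by the
temperature before the softmax, and the draw uses the Gumbel-max trick so
the whole batch advances in one vectorized step under a single seeded RNG.
Sequences that reach the token budget without emitting `END` are kept and
flagged unterminated; they usually parse as invalid and earn zero reward.

All network code is NumPy in float64 with hand-written backpropagation
through time.  One loss covers both training modes: a coefficient-weighted
cross-entropy whose per-step coefficients are 1/#tokens for supervised
training and R_i·γ^j·mask_ij/n for the REINFORCE surrogate.  Exactness of
the gradient is enforced by a central-finite-difference test (relative
error < 1e-3 at h = 1e-4 on a 5-token-vocabulary, 8-unit policy).

## Reinforcement learning

Fine-tuning clones the pre-trained generator; the clone (*biased*) is
updated, the original (*unbiased*) is frozen.  Per episode a batch of 10
molecules is sampled.  Policy selection happens **per token**: each active
molecule draws u ~ U(0,1) and the biased policy acts iff u > threshold,
where the threshold is 0.01 / 0.05 / 0.10 for an increasing / decreasing /
undefined reward trend.  The trend is the sign of the linear-regression
slope over the last 10 episode means, with |slope| < 1e-3 classified as
undefined.  Both policies consume every realized token so their hidden
states agree on the prefix; only tokens the biased policy emitted receive
gradient.

The molecule-level reward is terminal, broadcast to all of its token
positions through the γ^j weighting (γ defaults to 1.0).  Affinity rewards
use raw = exp(pIC50/4 − 1) min–max normalized over pIC50 ∈ [3, 11] and
clamped to [0, 1]; the range is a config spanning common potency practice.
The BBB reward is the classifier probability itself.  Scalarization is
either the linear weighted sum or the Chebyshev rule: compute weighted
distances w_j·(1 − r_j) to the utopian point (1, 1) and return the reward
of the farthest objective, ties resolved toward affinity — deterministic
and always equal to one of the two input rewards.  Surrogate-loss
log-probabilities are those of the tempered distribution actually sampled
from, so sampling and learning see one consistent policy.  During RL,
gradients are clamped elementwise to [−3, 3] (pre-training clips the global
norm instead, matching how each phase is usually stabilized).

The diversity memory holds the last 30 generated fingerprints (FIFO).  If a
batch's mean Tanimoto distance to the memory falls below τ = 0.75 the whole
batch's rewards are multiplied by 0.7, once (never compounded within a
batch); the memory is then updated.  Capacity, τ and the factor are package
choices surfaced as config.  Diversity fingerprints default to radius 2 /
2048 bits, matching the QSAR descriptor; the radius is a config
knob because circular-fingerprint naming conventions are ambiguous about
odd diameters.

A weight sweep runs one fine-tuning per affinity weight; each run is
summarized by the mean terminal reward vector over its final 20 episodes
(invalid molecules counting (0,0)), and dominance flags are set by a
non-dominated filter (a point is dominated if another is at least as good
on both objectives and strictly better on one).

## Predictors

**Affinity.**  A multilayer perceptron (default 64×64, L2 penalty 1e-2)
over features derived solely from the SMILES string: counts of every
training-corpus token, the same counts normalized by the number of atom
tokens, token length and atom count, with an out-of-vocabulary bucket.
Features are standardized; targets are standardized too (zero-variance
labels fall back to no rescaling), which together with the L2 penalty keeps
the net close to smooth fits instead of interpolating noise.  The reference
design used an embedding + GRU regressor; with no deep-learning framework
in the dependency set, the token-feature MLP is this package's
sequence-descriptor regressor, and it recovers the synthetic affinity rule
to Q² > 0.99.

**Permeability.**  An MLP classifier (default 256×128×64) over 2048-bit
radius-2 Morgan fingerprints; the reference design's 4000–250-unit stack is
reachable through the config but oversized for desk-scale data.

Both models train epoch-wise (minibatch 32) with early stopping: a 15%
validation split is held out **before** any oversampling, validation loss
is monitored with patience 10, and the best weights are restored.

**Oversampling.**  SMOTE and ADASYN are implemented directly (the usual
library is not a dependency): synthetics are convex combinations
x + λ(x_nn − x), λ ~ U(0,1), of a minority point and one of its k = 5
minority-class nearest neighbours (Euclidean on the raw bit vectors), left
real-valued so the convexity property is exact; originals are preserved
verbatim and synthetics appended.  ADASYN allocates synthetics per minority
point proportionally to r_i = (#majority among its k nearest
neighbours)/k, largest-remainder rounding to hit the exact total.
Oversampling is applied to training folds only — synthetics can never reach
a validation or test fold.

**Evaluation protocol.**  A 15% external test set is split off first, then
5-fold cross-validation over the remainder; reports carry per-fold metrics,
their mean ± sd, and external-test metrics.  Metrics: MSE, Q² (coefficient
of determination) and Lin's concordance correlation for regression; ACC,
rank-based AUC, sensitivity, specificity and Matthews correlation at
threshold 0.5 for classification.  Degenerate single-class inputs yield
NaN with a warning rather than an arbitrary number.  An optional
grid-search driver cross-validates a user-supplied hyper-parameter grid.

## Generated-set evaluation

A generator report over n samples contains: % valid (RDKit sanitization),
% unique among valid (on canonical SMILES, so rewritings count once),
internal diversity δ(valid, valid) and external diversity against a
reference corpus (mean pairwise Tanimoto distance; at most 1,000 molecules
enter the pairwise computation, seeded subsample), % desirable (predicted
pIC50 > 6.5 **and** P(BBB+) > 0.5 — the permeability half of the rule is
this package's completion of a one-sided definition), and histograms of
pIC50, P(BBB+), QED, SAS, logP and MW.  Drug-likeness windows are closed at
their printed bounds: MW < 500 g/mol, logP ∈ [1, 4], QED ≥ cut (default
0.5), SAS ≤ 6 (above 6 counts as hard to synthesize).  Every report field
is recomputable from the persisted per-molecule records.

## Synthetic test bed

`fixtures` generates all offline inputs.  The corpus enumerates rule-based
templates — alkanes and substituted chains, mono-/di-/1,3,5-trisubstituted
benzenes, pyridines, pyrroles, furans, thiophenes, imidazoles and saturated
rings decorated from a 25-fragment substituent set (~5,300 unique valid
molecules ≤ 24 heavy atoms); requests beyond capacity raise.  Two pure
deterministic oracles stand in for trained predictors in tests:
pseudo-pIC50 = 3 + 8·(aromatic heavy atoms / heavy atoms) ∈ [3, 11], and
pseudo-permeability = 1/(1 + exp((MW − 350)/50)).  They deliberately
compete: rings raise the pseudo-affinity while their mass lowers the
pseudo-permeability.  A binary permeability label (BBB+ iff MW < 200 g/mol)
splits the corpus roughly 74/26 — the non-permeable minority mirroring real
BBB collections; the cut sits below the oracle midpoint because template
molecules are small.  The imbalanced fingerprint dataset labels molecules
by overlap ≥ 4 bits with a fixed seeded 64-bit mask drawn from a
bit-frequency window chosen so both classes are populated.

What this test bed does **not** emulate: the breadth of drug-like chemical
space (no fused rings, stereocenters, charged species or macrocycles),
assay noise in labels, and activity cliffs.  Passing tests therefore
demonstrate that the machinery — likelihood training, exact policy
gradients, oversampling geometry, scalarization algebra, exploration
control — behaves as specified, not that the pipeline discovers real
AA2AR antagonists; headline numbers from full-scale corpora are out of
scope here.

## Desk-scale study conditions

Tests and the acceptance script run one fixed configuration: a
3,000-molecule corpus; a 2 × 64-unit LSTM generator (the library default of
256 units is unchanged) trained 25 epochs with batch 16, lr 1e-3, norm clip
3; 500-sample evaluation batches; 200 RL episodes of batch 10 at Chebyshev
(0.5, 0.5); QSAR training on 2,000 (affinity) and 3,000 (BBB) molecules.
The smaller recurrent width is the package's desk-scale choice so the whole
pipeline remains a few minutes of single-CPU work.

## Known limitations

- At toy scale the fine-tuned policy collapses toward a handful of
  optimal molecules (internal diversity drops sharply); the diversity
  memory fires repeatedly and slows, but does not prevent, collapse on a
  reward landscape this simple.  Real-scale corpora give the penalty far
  more room to act.
- REINFORCE uses no baseline or critic; gradient variance is tamed only by
  clipping and small learning rates, which is faithful to the original
  formulation but slower than modern variants.
- The affinity model sees token composition, not token order beyond
  counts; properties requiring sequence context would need richer
  features or a recurrent regressor.
- Predictor probabilities are used as rewards without calibration;
  desirability fractions inherit any miscalibration.
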