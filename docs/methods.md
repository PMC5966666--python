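# Methods

## Model

A deep belief network for binary disease prediction over the canonical
13-attribute heart-disease schema. Each layer is a restricted
Boltzmann machine (RBM): a bipartite energy model over visible units
`v` and binary hidden units `h`,

    E(v, h) = −aᵀv − bᵀh − vᵀW h,
    P(v, h) = exp(−E(v, h)) / Z,

with conditional activations factorizing over units because there are
no within-layer connections. Visible units accept real values in
[0, 1], treated as activation probabilities: the normalized clinical
features are continuous, and the conditionals are applied to them
directly. The stack is topped by one logistic output unit giving the
disease probability.

For tiny models (≤ 20 total units) the package tabulates the Boltzmann
distribution exactly (`cardiodbn.exact`); these enumeration routines
are test oracles for the conditionals, the partition function and the
log-likelihood gradient, never part of the training path.

## Training

**Pretraining.** Each RBM is trained by CD-1: hidden probabilities
from the data (positive phase), one binary hidden sample driving one
visible reconstruction, hidden probabilities of the reconstruction
(negative phase). Updates use probabilities in the gradient statistics
and a sampled binary state only for the Gibbs step. Defaults: learning
rate 1, at most 10 epochs per RBM, mini-batches of 100 (shrunk to the
data size when larger; remainder batches kept). Within the fixed
epoch budget the epoch snapshot with the lowest full-data
reconstruction error is kept.

Weights initialize from a zero-mean Gaussian with SD 0.1, biases zero.
The scale matters: at this training budget (a few dozen CD updates on
a few hundred rows) a much smaller initialization leaves the model
near the symmetric saddle where every hidden unit sits at 0.5 — the
layer learns almost nothing, stacked activations collapse toward
constants, and depth selection degenerates into an artifact of that
collapse. SD 0.1 escapes the saddle within budget while remaining
small enough not to saturate units at the start.

**Depth growth.** Layer t+1 trains on the mean-field hidden
probabilities of layer t (probabilities, not samples, so stacking is
deterministic given the seed). The reconstruction error

    R = Σ_ij |p_ij − x_ij| / (n·m)

(mean absolute one-step mean-field reconstruction error, in [0, 1] for
unit-interval data) is the growth statistic: a candidate layer is kept
while `R(k−1) − R(k) > ε`, default ε = 0.03, validated band
[0.01, 0.05]; the failing candidate is discarded and growth stops
(a `keep_stopping_layer` flag retains it instead, for the alternative
reading of the rule). A hard cap (default depth 8 counting the visible
layer) bounds growth regardless. Per-layer widths are searched over
`⌈√(m·n)⌉ + k, k ∈ [1, 5]` with one fixed seed per candidate so the
comparison differs only in width; ties break toward the smaller count.
Note the rule compares errors measured on *different* inputs (each
layer reconstructs its own input); it is a heuristic, not a monotone
statistic of one quantity, and its main failure mode — spurious extra
layers when activations become easy to reconstruct — is inherited by
design.

The claim that reconstruction error couples to the network energy is
not a theorem; the package tests only its empirical surrogate (positive
rank correlation between R and the mean data energy across training
epochs).

**Fine-tuning.** The pretrained weights initialize a feed-forward
sigmoid network; full-batch gradient descent on the mean cross-entropy
backpropagates through the logistic head and every layer (weights and
hidden biases; visible biases are unused by the forward pass).
Defaults: rate 2.0, up to 1000 epochs, early stopping on a 15%
validation holdout of the training rows (best-validation-loss
snapshot, checked every 20 epochs, holdout seeded → deterministic).
These defaults were chosen because small-rate short-budget descent
underfits the deeper stacks this method sometimes grows (gradients
attenuate roughly 40-fold per layer through small-weight sigmoid
layers), while longer unregularized training overfits tables of a few
hundred rows; validation early stopping handles both regimes. Weight
decay was tried and rejected (it re-collapses deep stacks by shrinking
exactly the small weights the gradient must grow); momentum brought no
improvement over plain descent.

## Preprocessing

Continuous attributes (age, trestbps, chol, thalach, oldpeak) are
scaled by robust min-max: the scaling extremes are the means of the k
largest/smallest *training* values (k = ⌈2% of n⌉ by default, k = 1 —
plain min-max — for age), which damps isolated recording outliers such
as a single cholesterol of 564. Out-of-range held-out values are
clamped to [0, 1], keeping the RBM input contract. Categorical
attributes map through ordered code tables and divide by the maximum
code. The shipped table includes the public files' alias spellings
(thallium 3/6/7 → 0/1/2, Cleveland integral floats), and a Statlog
variant remaps that file's shifted chest-pain (1–4) and slope (1–3)
codes; Statlog's 1/2 labels are remapped to 0/1 by the reader. The
graded diagnosis 0–4 is binarized (0 vs ≥ 1): the output head is a
single probability, and the public evaluation convention for these
files is presence/absence. Missing `?` values are imputed with the
training-split mode (categorical) or median (continuous). All
fitting — scaling, imputation — uses the training partition only.

## Synthetic generator

Records are sampled from a latent binary hierarchy: a disease bit at
the root; factor levels of width `factors_per_level`, doubling per
level and capped at 13, each factor copying its (contiguously grouped)
parent with flip probability `0.1 · noise_sd`; the 13 attributes
emitted from contiguous blocks of the deepest level. Continuous
attributes are factor-shifted Gaussians with clinically plausible
means and SDs (e.g. cholesterol 225 vs 268 ± 35 mg/dl, peak heart rate
158 vs 131 ± 15 bpm); categorical attributes are factor-tilted
multinomials over the canonical code sets. `noise_sd` jointly scales
continuous jitter, categorical confusion and factor flips, so
`noise_sd = 0` makes every attribute a deterministic function of the
label; `label_flip_prob` (default 0.05) adds irreducible label noise.
Defaults: n = 300, latent depth 2, noise 1.0.

What this emulates: multi-scale correlation among attributes whose
depth is controlled by construction, which is exactly what the depth
rule is supposed to detect — deeper hierarchies should select deeper
networks. What it does not emulate: real clinical marginals and
missingness patterns, attribute-specific measurement error, or
dependence structures not expressible as a binary factor tree. Passing
tests therefore demonstrate that the machinery behaves as designed
under a controlled hierarchy, not that the headline accuracies carry
over to any particular clinical cohort.

Paired structure-recovery experiments (latent depth 2 vs 4) use
n = 500 per data set: at n = 300 the layer-wise error estimates are
noisy enough that the paired depth comparison is unreliable, while
n = 500 gives a stable signal. The end-to-end accuracy protocol keeps
the n = 300 fixture.

## Evaluation protocol

One run: stratified 70/30 split, preprocessing fitted on the training
partition, growth, fine-tuning, accuracy on the held-out partition.
The repeated protocol reruns everything with fresh split and
initialization seeds drawn from one master seed and reports per-run
accuracies, their mean, and their *population* variance (÷ n). The
depth sweep forces fixed depths with the ε rule disabled; its runtime
column is informational only.

## Numerical and degenerate-input choices

Sigmoid via `scipy.special.expit` (stable for large |x|); partition
sums via `logsumexp`. Degenerate scaling ranges (all values identical)
and short columns raise errors naming the attribute. Width-search ties
break toward fewer units. The enumeration oracle refuses models above
20 total units. Seeds derived from master seeds stay below 2³¹.

## Known limitations

* The depth rule compares reconstruction errors across different
  representations; occasional spurious deep growth persists (visible
  as rare deeper-than-modal runs in the repeated protocol).
* CD-1 at this epoch budget underfits each layer; reconstruction
  errors are far from their attainable minima, and all depth/width
  decisions are made in that underfit regime.
* Accuracy on the synthetic fixture sits close to a logistic-regression
  baseline; the value of depth here is in structure detection and
  stability, not large accuracy gains on 13 features.
* No multiclass severity output (labels binarized), no persistent CD,
  momentum or weight decay in pretraining, and no bidirectional
  associative-memory inference at the top layer.
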