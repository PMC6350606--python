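# Methods

## The model

The classifier is a three-layer feed-forward network `[M; Q; L]` with
the unipolar sigmoid `f(x) = 1/(1+e^-x)` on both the hidden and output
layers and **no bias terms**: the hidden net input is
`net_j = Σ_i w_ij x_i` and the output net input `net_k = Σ_j w_jk O_j`.
For sex classification `M = 6` (the six midsagittal measurements CSA,
CSC, ASA, ASC, OSA, OSC), `L = 2` (a female and a male output neuron),
and `Q ∈ {6, 12}` for the two architectures under study. Targets are
one-hot: female `(1, 0)`, male `(0, 1)`; scalar label coding is
female = 1, male = 0. Predicted class is the larger output neuron, with
exact ties resolved to male (fixed, documented, and measure-zero for
trained networks).

Training is per-sample (online) gradient descent on the squared error
`E = ½ Σ_k (d_k − y_k)²`. The applied change of each weight at step
`n + 1` is

```
Δw(n+1) = α Δw(n) + η·s_i·g − η λ w
```

where `g` is the error-gradient term — `(d_k − O_k) O_k (1 − O_k) O_j`
for hidden→output weights and its backpropagated counterpart
`O_j (1 − O_j) O_i Σ_k (d_k − O_k) O_k (1 − O_k) w_jk` for
input→hidden weights — `α ∈ [0, 1)` the momentum coefficient,
`η > 0` the learning rate, and `λ ≥ 0` the L2 coefficient whose
`−η λ w` term is the exact gradient of adding `(λ/2)‖w‖²` to the
objective (weight decay over all weights). `s_i` is an optional
per-sample factor (see boosting). Momentum memory stores the applied
deltas verbatim, which gives three exact algebraic identities used as
tests: `α = λ = 0` reduces to the bare rule; a zero-gradient step
scales the previous delta by exactly `α`; zero gradient with `α = 0`
multiplies weights by `(1 − ηλ)`.

Each epoch visits the training rows in a freshly shuffled, seeded
order. The epoch MSE is the mean over samples of the summed squared
output error, `MSE = (1/n) Σ_i Σ_k (d_ik − y_ik)²`, computed after the
epoch's updates; training stops at the epoch budget or when the epoch
MSE reaches `mse_goal`. The reported MSE uses this one definition for
both training and testing splits.

### Defaults and units

| parameter | default | rationale |
|---|---|---|
| `layer_sizes` | (6, 12, 2) | the wider of the two studied architectures |
| `eta` | 0.5 | centre of the studied {0.1, 0.5, 0.9} grid |
| `alpha` | 0.9 | strongest studied momentum |
| `lambda_reg` | 2⁻²⁵ | a small decay whose per-update shrinkage `ηλ ≈ 1.5e-8` is numerically meaningful over 10⁵ epochs without dominating the gradient; any value ≥ 0, including large ones, is settable |
| `max_epochs` | 100 000 | full-study budget; tests and examples use 200–2 000 |
| `init_scale` | 0.5 | weights start uniform on [−0.5, 0.5], seeded |

Hyperparameters interact: on well-separated classes every grid cell
trains to 100%; on strongly overlapping classes the aggressive corner
(η = 0.5–0.9 with α = 0.9, effective step η/(1−α) = 5–9) can drive the
output units into saturation, where `O_k(1−O_k) ≈ 0` kills the gradient
and the network locks onto the majority class. That behaviour is a
property of the update rule, not a defect of the implementation, and is
the reason the operating point is chosen by the grid experiment.

### Numerical notes

- The inner per-sample loop is compiled (numba). The public
  single-update function is plain numpy with identical operation order;
  the two paths agree to ~1e−12 relative (BLAS vs sequential dot
  summation), verified by test.
- A uniform sample-weight vector scaled by `N` can land at `1 ± 1 ulp`;
  scales within 1e−9 of 1 are snapped to exactly 1.0 so a uniform
  distribution is bit-identical to unweighted training.
- Divergence (non-finite weights or epoch MSE) raises an error naming
  the learning rate rather than returning garbage.
- Model and ensemble files are versioned JSON; Python's shortest
  round-trip float repr makes reloads exact.

## AdaBoost integration

`T` networks (default 4) are trained sequentially. Round `t` holds a
distribution `D_t` over training rows (uniform `1/N` initially), trains
a network with per-row gradient scale `s_i = N·D_t(i)` — deterministic
reweighting rather than resampling, chosen because it exactly recovers
unweighted training at uniform weights — and with seed
`master_seed + t` so rounds differ even under near-identical
distributions. Its weighted error is `ε_t = Σ_i D_t(i)·ε_i` with `ε_i`
the 0/1 misclassification indicator; its vote weight
`W_t = ½ ln((1−ε_t)/ε_t)`; the next distribution is
`D_{t+1}(i) ∝ D_t(i)·β^(1−ε_i)` with `β = ε_t/(1−ε_t)` — the classical
two-class AdaBoost update (correct rows shrink). `ε_t` is clamped to
`[1e−10, 1−1e−10]` before the log-odds so a perfect round keeps a
finite (large) vote and an unchanged distribution.

A round with `ε_t ≥ 0.5` is no better than chance: it aborts and
truncates the ensemble at `t − 1` learners; if the first round aborts
there is no usable learner and the run errors. Prediction sums
`H(x) = Σ_t W_t h_t(x)` over the two output neurons (`h_t` the raw
output vector) and takes the argmax with the male tie-break; for
ensemble MSE the score is divided by `Σ_t W_t` to return it to the
(0, 1) output scale.

## Baselines

**Fisher discriminant.** Projection
`w = S_w⁻¹ (m_F − m_M)` with `S_w` the pooled (unbiased) within-class
covariance; decision threshold at the midpoint of the projected class
means (equal priors — the classical anthropometric convention; a
prior-weighted threshold `midpoint − ln(n_F/n_M)` is available by
option). A singular `S_w` is ridge-stabilized by `ε·trace/p` on the
diagonal. The univariate rows of the comparison table are the same fit
on one variable, i.e. a cut on that measurement.

**Logistic regression.** Newton/IRLS on the Bernoulli likelihood with
logit link, female = 1, intercept included; converged when the largest
coefficient step is ≤ 1e−8 (cap 100 iterations). Quasi-separation is
flagged (any |coefficient| > 30) rather than errored, since separable
training data make the MLE diverge along a ridge while the decision
rule stays well-defined.

Both are deliberately written on the raw linear algebra; scikit-learn
and statsmodels serve as independent cross-checks in the test suite,
alongside a brute-force Fisher-criterion angular grid search and a
zooming likelihood grid search.

**Comparison table.** Per method: male accuracy, female accuracy, and
their unweighted mean on one shared test split.

## Synthetic data

The generator draws each class from a six-dimensional normal with a
shared within-class covariance — the classical dimorphism model and
exactly the regime where LDA attains the Bayes rate `Φ(Δ/2)`
(`Δ` the Mahalanobis distance between class means), which the tests use
as an analytic oracle. Defaults: 153 females and 114 males (the study's
class sizes); female means (358, 178, 124, 110, 112, 94) mm with SDs
(12, 7, 6, 5, 6, 5) — order-of-magnitude plausible for adult cranial
sagittal arcs/chords, not calibrated to any real sample (none is
published); correlation 0.7 between each arc and its own chord, 0.3
elsewhere (positive-definiteness is validated at construction). Male
means sit `effect_scale` SDs above female means per variable;
`effect_scale = 2` (default) gives `Δ ≈ 2.9`, Bayes accuracy ≈ 92%,
the range real craniometric studies report; `effect_scale = 6` gives
`Δ ≈ 8.6`, an essentially separable problem; `effect_scale = 0` gives
identical classes for null calibration. Non-positive draws are redrawn
(measurements are lengths), preserving near-normal shape; rows are
shuffled; everything is deterministic under the spec seed. An optional
per-class covariance override supports robustness experiments.

What the generator does *not* emulate: measurement error structure,
age/population covariates, departures from normality, and
arc-geometry constraints beyond positivity (arcs exceeding their chords
holds at the means but is not enforced row-wise). Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical model, not field performance on real skulls.

## Experimental protocol

`prepare_split` applies the study protocol: stratified 70/30 split
(per-class training count = `round(class_size × 0.7)`; 153/114 →
107 + 80 = 187 train, 80 test), then min-max normalization to [0, 1]
**fitted on training rows only** (test rows may fall outside; z-score
is a config option). Stratification and training-only fitting are the
package's choices where the protocol was ambiguous; both are the
leakage-safe readings. Unstratified splitting rounds the total count
instead.

`run_grid` sweeps η, α ∈ {0.1, 0.5, 0.9} with the boosted network,
re-splitting afresh each repeat by default (a shared-split mode
exists); per-(cell, repeat) seeds derive from the master seed via a
64-bit LCG mix reduced below 2³¹, so reports are bit-reproducible.
Failed repeats (divergence, unusable ensemble) are recorded with their
cause and excluded from means — never silently dropped. Summaries
report both per-cell means and maxima; `compare_architectures` runs
(6, 6, 2) and (6, 12, 2) on identical splits and verdicts each cell.

## Problem sizes

Tests and the acceptance script run the pipeline at desk scale, chosen
to make the statistical assertions sharp rather than to mimic the full
study: gradient checks on 6-4-2 networks; recovery and null calibration
on 500 + 500 rows × 2 000 epochs × 4 boosting rounds over 5–10 seeds
(pooled binomial band at α = 0.01 for the null; seeds whose first
boosting round is chance-level produce no ensemble and contribute
nothing — benign, since with balanced classes any classifier's expected
test accuracy is exactly 50%); LDA-vs-Bayes at 10 000 rows; the grid at
3 repeats × 1 000 epochs on the 267-row default dataset. The
100 000-epoch budget remains the library default for full runs.

## Known limitations

- No bias terms, matching the model equations; class boundaries through
  strongly off-centre data can therefore require more hidden units or
  epochs than a biased network would.
- Only the `[6; Q; 2]` single-hidden-layer sigmoid family; no adaptive
  learning rates, alternative activations, or deeper stacks.
- Binary AdaBoost only; no multiclass variants or non-network base
  learners.
- The comparison table evaluates a single split; it inherits that
  split's sampling noise.
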