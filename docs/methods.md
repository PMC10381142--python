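# Methods

## Problem setting

`hvat` predicts a binary patient outcome (case = 1, control = 0) from two data
modalities at once: a longitudinal stream of dated clinical events — diagnoses,
medications, note titles, and measurements carrying numerical values — and a
small non-longitudinal vector of demographics.  The model is a hybrid of a
transformer encoder over *clinical tokens* (the Value-Aware Transformer, VAT)
and a residual feed-forward network over the static vector, fused by summation
and read out through a single sigmoid node trained with binary cross-entropy.

## Input representation

Each patient has an observation window ending at an *index date*.  The window
is divided into equal intervals of length `L` days; intervals are numbered
1, 2, 3, … backward from the index date (*temporal indices*).  Backward
numbering aligns patients at the clinically meaningful end of their histories,
so "two intervals before the index date" means the same thing for everyone.
An event dated `g` days before the index date falls in interval
`floor(g / L) + 1`; an event on the index date itself falls in interval 1, and
index 0 is reserved for the summary token.  Both this convention and a ceiling
convention reproduce the canonical month-scale examples; `floor + 1` was chosen
because it handles day-zero events without a special case.

Within one interval, repeated occurrences of a concept collapse to a single
token `(t, C, v)`.  Unvalued concepts take `v = 0`; valued concepts aggregate
their raw values with a per-concept rule (mean for BMI-like quantities, max
for fitness-like quantities where the best performance in a period is the
informative summary).  A special token `(0, S, 0)` is prepended to every
sequence; the transformer output at its position is the fixed-width summary of
the whole sequence used for classification.  Patients with no in-window events
keep just the special token — prediction then rests on the static branch.

Values are z-scored per concept with training-subset population mean/SD before
embedding ("concept-wise normalization"); a constant concept gets SD 1.  The
age entry of the 7-dim static vector
`[age, sex, Race_Black, Race_Other, Race_Unknown, Eth_Hispanic, Eth_Unknown]`
is likewise z-scored on the training subset for optimization stability; dummy
entries pass through untouched.

## Token embedding

A token embeds as `E(t, C, v) = TE(t) + CE(C) + v·VE(C)` with `d = 32`:

* `TE` is a fixed interleaved sinusoid, `TE(t) = [sin(tω₁), cos(tω₁), …]`
  with `ω_k = 10000^(−2k/d)`, `k = 1…d/2`.  This one-based exponent is the
  convention implemented here; a switch (`te_convention="classic"`) provides
  the original transformer's zero-based variant for comparison experiments.
  `TE` is never updated during learning.
* `CE` and `VE` are learned per-concept tables.  `VE(C)` is a direction along
  which the normalized value moves the token — multiplying a learned basis
  vector by the value is what makes the branch value-aware, treating valued
  concepts as continuous predictors rather than binned categories.

Embedding rows are initialized standard-normal — the customary initialization
for lookup tables (and the default of the deep-learning library the
architecture was prototyped in), which also keeps the learned tables on the
same scale as the fixed temporal encoding (per-dimension RMS 1/√2).  Fan-in
He scaling is reserved for the linear layers it was derived for; applying it
to the tables (std √(2/d) ≈ 0.25 at d = 32) makes concept identity a small
perturbation on the shared temporal signal and measurably slows learning.

## Network

The VAT branch runs `N = 2` standard post-norm transformer encoder blocks
(multi-head self-attention with 2 heads, position-wise feed-forward of inner
width 4d with ReLU, residual connections, layer norm, dropout 0.1).  Padded
positions are excluded from attention with an exact mask (masked keys get
probability exactly 0), so padding provably cannot change any real patient's
output.  The static branch projects the 7-vector to width d and applies one
residual hidden block (linear → ReLU → dropout → linear).  The branch outputs
are summed, passed through another residual hidden block of the same shape,
and mapped to a probability by one sigmoid unit.  The exact depth/width of
the feed-forward blocks is not pinned by the architecture's description;
the defaults here (hidden width 32, inner transformer width 128) are
configurable.

Ablations reuse the same forward path: `without_ffnn` zeroes the static
branch's contribution and `without_vat` the transformer's — equivalent to
removing the branch, since the fusion is a sum.  The orderless deep baseline
(FFNN-NL) is the `without_vat` network with its input layer widened to all
predictors: whole-window presence indicators for unvalued concepts,
whole-window aggregates for valued ones, plus the 7 static variables, all
z-scored on the training subset.  A linear SVM on the same features
(scikit-learn `LinearSVC`) completes the five-way comparison.

The mini-batch loss is the *sum* (not mean) of per-patient binary
cross-entropies: batches hold a roughly constant number of tokens rather than
patients, and summing keeps the per-token gradient scale comparable across
batches.  The contract-level loss takes probabilities clamped to
`[1e-7, 1 − 1e-7]`; the training loop evaluates the same quantity from logits
(`softplus(x) − y·x`) so the gradient `p − y` stays exact under saturation.

## Numerical substrate

The network and its training run on a small reverse-mode automatic
differentiation engine over float64 numpy arrays written for this package
(broadcast-aware elementwise ops, batched matmul, layer norm, masked softmax,
dropout, embedding gather).  Every primitive is finite-difference tested, and
an end-to-end gradient check on a 3-patient batch is part of the test suite.

## Training protocol

Sequences are sorted by token count and packed greedily into mini-batches
whose token sums never exceed the budget (default 10 000); only a single
over-long sequence may form its own batch.  This operationalizes "similar
sequence lengths per batch, ~10 000 tokens per batch" while guaranteeing the
budget invariant.  Batch order is reshuffled every epoch.

Optimization is mini-batch SGD with Nesterov momentum (coefficient 0.9, the
conventional choice) and three parameter groups with separate learning rates:
5·10⁻⁴ for the static branch, 5·10⁻⁵ for the VAT branch (including both
embedding tables, which feed only that branch), and 1·10⁻⁴ for the fusion
block and output layer.  Linear weights are He fan-in initialized; biases
zero; layer-norm gains one.

After each epoch the validation AUC is computed with dropout disabled.
Training stops when AUC has not strictly improved for 10 consecutive epochs
(plus a `max_epochs = 200` safety cap), and the checkpoint with the highest
validation AUC is returned.  The operating threshold is chosen afterward on
*training* scores as the accuracy-maximizing cut (decision rule
`score ≥ threshold → case`; candidates are midpoints between adjacent
distinct scores plus sentinels; ties break toward the smallest threshold).
AUC is the Mann–Whitney statistic with average-rank tie handling — identical
to the trapezoidal ROC area but directly matching its brute-force all-pairs
oracle.

The orderless tabular models (FFNN-NL, SVM) have no meaningful sequence
lengths, so they train on fixed 64-patient batches; with the summed loss,
token-budget batches of short-sequence patients would hold several hundred
patients and make the effective step size unstable for the wide input layer.

## Feature ranking

Binary presence/absence concepts are ranked by a continuity-corrected log
prevalence ratio penalized by its standard error.  With `a` of `m` cases and
`b` of `n` controls showing the concept anywhere in their windows:

    LogPR = ln(((a+0.5)/(m+0.5)) / ((b+0.5)/(n+0.5)))
    SE    = sqrt(1/(a+0.5) − 1/(m+0.5) + 1/(b+0.5) − 1/(n+0.5))
    score = |LogPR| − z_{α/2}·SE          (α = 0.05, z from the normal quantile)

The score equals the confidence limit nearer zero (sign-adjusted), so a
positive score certifies a significantly nonzero LogPR at level 1−α.  Counts
are computed on the training subset only.  Ties in the top-k selection break
by |LogPR| then name — an arbitrary but deterministic rule.

## Synthetic cohort

The generator emulates a case-control EHR study: a 5-year window ending at a
common index date, visits from a Poisson process (10/patient/year), ~20
unvalued concept archetypes (medications/diagnoses/note titles), two valued
concepts (a fitness-like measure aggregated by mean, a BMI-like noise
concept), and demographics with a mild age–outcome association (cases ~1
year older on average) so the tabular-only ablation lands above chance but
far below the full model.  The static signal is kept deliberately weak: the
comparative design needs the longitudinal channels to dominate, and a strong
static plateau early in training would also interact badly with AUC-plateau
early stopping at this cohort scale.

Outcome signal is planted at three levels, each with an exact estimand:

* **Presence** — designated concepts are present with probability `q` in
  controls and `q·exp(effect)` in cases (planted at the patient level so the
  whole-window presence LogPR *is* the effect; default 0.7 on 3 concepts with
  q = 0.3).  Kept moderate on purpose: presence survives aggregation, so it
  sets the orderless baselines' performance, and the comparative design needs
  headroom above them.
* **Timing** — an "early marker" is equally prevalent in both groups (0.7),
  but in cases (probability 0.95) it occurs only in the older half of the
  window.  Only temporal indices carry its signal; any orderless view of the
  data is blind to it.
* **Values** — the fitness concept is measured in everyone (~8 times), but in
  cases its mean is shifted by ±1.5 SD with the sign flipping between the
  older and recent half of the window.  Whole-window mean aggregates
  therefore carry asymptotically no signal: this is the designed stressor
  separating a value-aware, time-resolved model from aggregated baselines.
  The timing and value channels are planted strongly — they are the signals
  the architecture exists to capture, and they must dominate the learning
  trajectory for plateau-based early stopping to see steady progress at this
  cohort scale.

What the generator does **not** emulate: real disease epidemiology or
demographics, coded-vocabulary scale (hundreds of medications), informative
visit processes, missingness mechanisms, or measurement error structure.
Passing the learnability suite shows the architecture can extract planted
presence/timing/value structure from realistic-shaped sequence data — not
that it attains any particular performance on real cohorts.

## Scaled-down study conditions

The learnability experiments run on 2000 patients (1000 cases / 1000
controls, split 80/10/10 stratified) — a size chosen so the full comparative
study trains in minutes on one CPU while keeping every structural property of
the design.  At this scale an epoch contains only ~8 token-budget batches, so
plateau detection needs the full patience window; the 200-epoch cap and the
prototype learning rates are kept as-is.

## Degenerate inputs and edge rules

* Unknown-concept event rows are dropped with a logged count; unparseable
  dates or missing values for valued concepts are hard errors naming the row.
* A valued concept absent from training data normalizes with (0, 1) and a
  warning; constant concepts use SD 1.
* Zero-event patients keep only the special token.
* Split rounding: validation/test take `floor(fraction·class size)` per
  class; the remainder goes to train.
* A single sequence longer than the token budget forms its own batch with a
  warning.
* AUC requires both classes; single-class input is an error, not a default.

## Known limitations

* No pre-training objectives, attention-based explanation, learning-rate
  schedules, warmup, weight decay, or gradient clipping — deliberately out of
  scope.
* The autodiff engine is single-threaded numpy; it is sized for the prototype
  architecture (d = 32, 2 blocks), not for large-scale training.
* The simulator plants signals independently per channel; correlated
  channels (e.g., presence and timing of the same concept) are not modeled.
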