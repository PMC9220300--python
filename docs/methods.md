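# Methods

This note documents the models, the numerical choices and the synthetic
study conditions behind `edafuse`, in the order the pipeline runs.

## Label model

The seven discrete emotions map onto the two axes of the circumplex model:
positive valence = {neutral, surprise, happy}, high arousal = {surprise,
fear, anger, happy}; the complements define the negative/low classes. The
mapping is total on the closed vocabulary, and aggregate group counts
conserve mass (positive+negative = high+low = total). For corpora with
continuous 1–9 self-assessment ratings, binarization uses the strict cut
`rating > 5` with ties assigned to the negative/low class; 5 is the scale
midpoint and no canonical cut exists, so the tie rule is documented rather
than load-bearing. Published summaries of the wristband corpus disagree
internally (a sequence total of 4,023 against per-expression counts summing
to 3,554); the package trusts the per-expression counts, which are the
numbers its group totals reproduce.

## Preprocessing

* **Normalization scope.** Min-max normalization is computed per
  participant over that participant's concatenated samples. Its purpose is
  removing between-participant level differences; per-trial scope would
  also erase within-participant tonic differences between trials, which
  carry valence information.
* **Median filter.** 11-point running median with replicate-edge padding
  (padding with zeros would fabricate boundary artifacts). The window must
  be odd and no longer than the signal.
* **Resampling.** Polyphase filtering at the rational rate ratio
  (`scipy.signal.resample_poly`, line padding); the embedded low-pass stage
  anti-aliases on downsampling. Duration is preserved to within one sample
  period.
* **Segmentation.** A trial is the `trial_s`-second window following the
  `pretrial_s`-second baseline; the baseline mean is subtracted ("baseline
  removed" is read as mean subtraction, the simplest faithful rule). An
  empty baseline means zero shift.
* **Order.** 4 Hz style: normalize, then median-filter (the order is
  configurable; on idempotent fixtures the two orders agree). 128 Hz style:
  resample, segment/debase, then normalize.

## Statistical features

Eleven time-domain statistics for the 4 Hz style: mean, kurtosis, skewness,
max, min, standard deviation, variance (population convention, recorded so
oracles match), plus the mean absolute and mean-of-negative first and
second differences. "Negative mean of the first-order differential" is read
as the mean over strictly negative differences — the recovery-slope
magnitude of SCR decay; a non-decreasing signal scores 0. Zero-variance
signals report skewness/kurtosis 0 with a warning rather than NaN.

SCR-event features (128 Hz style registry): peak count, mean trough-to-peak
amplitude, mean rise time, local-minimum count, and the first two moments.
A peak qualifies when its rise from the onset — found by walking back from
the local maximum while the signal strictly ascends, which lands on the
preceding local minimum or the edge of a flat baseline — exceeds the
amplitude threshold (default 0.01 in post-normalization units,
configurable). Trough-to-peak amplitude systematically underestimates
events riding a previous SCR's decay; this is the standard limitation of
non-decomposition EDA analysis and is visible in the recovery tests, which
therefore plant temporally separated events. The feature registry is purely
time-domain; no spectral features are included.

## Gender-age relation graph embedding

Entities: one per participant, one per distinct integer age (no binning by
default; the graph mirrors the printed triple form `(participant, AgeIs,
28)`), and the two gender tokens. Relations: `AgeIs`, `GenderIs`, and
optionally `HasLabel`. Scoring is the complex trilinear form with the
conjugated object embedding; the 4-term real expansion is the
implementation and the full complex product is the test oracle.

The conditional probability of a completion is a softmax over the candidate
set {true completion} ∪ sampled negatives. The candidate set includes the
true completion so probabilities are well defined and bounded by 1; the
notation that sums over negatives alone is read as shorthand. Negatives are
sampled uniformly without replacement from the entities that do not form an
observed positive (the filtered protocol), resampled every epoch.

Training: full-batch Adagrad (learning rate 1e-2) on the summed negative
log-likelihood over both directions plus λ·ΘᵀΘ with λ = 1e-3; embeddings
initialize from a zero-mean Gaussian with scale 1/√K. Gradients are
analytic (verified against finite differences at 1e-8). Divergence raises
with a suggestion to lower the learning rate. Defaults in the pipeline:
K = 16 and 300 epochs, which drive filtered MRR to 1.0 on rosters of the
sizes used here within a couple of seconds; the embedder accepts K = 50 for
larger vocabularies. Filtered ranking assigns tied scores the mean rank of
the tie block, so an untrained all-zero model scores the analytic
expectation (m+1)/2 per case rather than an optimistic rank.

Embeddings are trained once on the full gender/age graph and reused across
folds: the graph contains covariates only, never labels, so no fold
information leaks (verified by the null-calibration experiment). `HasLabel`
triples are off by default; when enabled they must be built from
training-fold subjects only and retrained per fold.

## Fusion and classifier

PCA (fitted with centering on training-fold subjects only) reduces the
real-part embedding matrix to the feature dimension d. Inside each fold the
statistical features are z-scored and the reduced embedding rows are
rescaled to `1 + 0.5·z`. The unit-centered scaling is a deliberate choice:
the fusion is multiplicative, and weights fluctuating around +1 let
training start near the identity regime `F ≈ S` instead of sign-scrambling
the features with zero-mean weights.

`F = S ⊗ (P ĝ)` with P initialized to the identity (the embedding passes
through unchanged at epoch 0) and learned jointly with the network by
backpropagation. Each trial inherits its subject's reduced embedding row;
embeddings are per-participant while S is per-trial.

The network is d → 64 → 128 → 64 → 2 with batch normalization, ReLU and
dropout 0.2 after each hidden layer and a softmax output. The training
criterion is MSE between the softmax outputs and one-hot targets (as
specified; cross-entropy is available behind `loss="ce"`), optimized by
Adam at learning rate 1e-3, full batch. Classes are weighted inversely to
their training-fold frequencies so the fitted model does not inherit fold
imbalance — without this, leave-one-subject-out accuracy acquires a small
negative bias under label-randomization nulls. The canonical epoch budget
is 700; the pipeline default is 150, which reaches the same ranking of
methods at desk scale in a fraction of the time. Dropout masks and
initialization derive from one seed; training is bit-reproducible, and
inference runs in evaluation mode (running batch-norm statistics, no
dropout), so repeated predictions are identical.

## Evaluation

One fold per subject; metrics (recall, precision, accuracy, F1 for the
positive/high class) are computed per fold from the fold confusion matrix
and averaged, with the accuracy standard deviation across folds; pooled-
confusion aggregation is available. Zero-denominator ratios report 0 with a
warning. The Friedman statistic uses within-group mean ranks with the
standard tie correction (identical columns yield statistic 0, p = 1), and
the Nemenyi critical distance is `q_α √(k(k+1)/6N)` with q_α computed
exactly from the studentized-range distribution at infinite degrees of
freedom divided by √2 (k = 5, α = 0.05 gives 2.728, matching the published
table); "critical value 0.05" is read as the significance level, not q
itself.

## Synthetic study conditions

The generator emulates a wristband-style corpus: 40 subjects (gender
balanced ±1, ages uniform on 18–39), 8 trials × 60 s at 4 Hz. A trial is
tonic level (subject draw N(2, 0.5²) μS, +0.5 for positive valence, slow
sinusoidal drift of amplitude 0.1) plus Poisson SCR events (rate 5/min for
high arousal vs 3.5/min for low; each event rises linearly over 1–3 s to an
amplitude drawn from N(0.6, 0.2²) clipped at 0.05 and decays exponentially
with τ = 4 s) plus N(0, 0.02²) sensor noise, clipped at zero conductance.
Labels are drawn per trial with log-odds `covariate_effect · (2·gender ±
age_centered)`, gender coded +1 for F, age scaled to [−1, 1]; the default
covariate effect is 0.7. The rates were chosen so that the signal channel
alone supports roughly 0.6 LOSO accuracy — clearly above chance, clearly
below the ceiling — leaving the covariates a decisive complementary share,
which is the regime the fusion architecture targets. An optional minimum
inter-event gap (default off, preserving exact Poisson counts) spaces
events for detector-validation tests.

What the generator does **not** model: physiological sudomotor dynamics
(compound/superposed SCR shapes beyond linear-rise/exponential-decay),
motion artifacts, stimulus-locked response latencies, or any dependence of
signal morphology on gender/age beyond the label pathway. Passing tests
therefore demonstrate that the pipeline recovers the covariate structure it
declares, not that comparable gains will appear on any particular real
corpus.

## Problem sizes and experiments

The multi-seed improvement experiment uses 10 seeds × 40 subjects with LOSO
(so 800 classifier fits per full run) at 150 MLP epochs and K = 16 /
300-epoch embeddings — about seven minutes on one CPU; the seed-wise sign
test requires at least 9 wins in 10 for significance at 0.05. The null
calibration replaces the task labels with independent fair coin flips under
`covariate_effect = 0` (randomization rather than a global permutation:
permuting a fixed label pool induces the well-known negative finite-pool
coupling bias of cross-validation, which would contaminate a leakage check;
under randomization the binomial reference around 1/2 is exact) and uses
10 seeds × 24 subjects.

## Known limitations

* The multiplicative fusion is sensitive to the embedding-row
  representation; zero-mean weights at initialization measurably hurt
  training (hence the unit-centered scaling above).
* Trough-to-peak SCR amplitudes are biased low for overlapping events; a
  deconvolution-based decomposition is out of scope.
* Single-seed LOSO differences between SF and SF-GARG fluctuate by several
  points at 40 subjects; only the multi-seed comparison is stable.
* The Friedman/Nemenyi machinery assumes independent result groups; LOSO
  folds share training data, so its p-values are approximate in this
  setting, as in the literature it follows.
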