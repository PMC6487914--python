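# Methods

## Model and assumptions

The unit of analysis is a subject with a binary label (case = 1) and a
feature vector per contributed source. Missingness is *source-wise*: a
source's entire block is present or absent, never individual cells. The
framework makes three structural assumptions:

1. the complete-data subjects (domain `2^S − 1`) are a fair test set for
   models trained on incomplete-data subjects — i.e. completeness is not so
   strongly informative about the label that train and test distributions
   diverge;
2. a per-source model trained on all contributors of that source is a valid
   estimate of that source's class signal (no imputation is attempted —
   with whole modalities absent there is nothing defensible to impute
   from);
3. disease signal may be heterogeneous across sources within a subject, so
   pooling base responses across sources (rather than fusing per-source
   ensemble outputs) preserves the evidence a single strong modality
   carries.

Tie handling is asymmetric by construction: both fusion rules return the
positive class when the vote or mean probability lands exactly on the
boundary (`Σ R_i = B/2`, mean = 0.5). This biases exact ties toward the
case class and is deliberate and documented rather than incidental.

When a source lacks some classifier kind, the pooled denominator is the
actual number of responses available and the threshold is half of it; pools
are allowed to be ragged.

## Evaluation protocol

Training pools are balanced to equal class counts by random undersampling
of the majority class (oversampling available behind a flag), then split by
repeated stratified k-fold CV (default 10 folds × 10 repeats; repeat `r`
derives its seed as `base + r` and redraws the balancing resample, so
discarded majority subjects rotate). Normalization to zero mean/unit
variance is fit on the training rows of each fold only; validation rows are
transformed with the training parameters (leakage-safe). Constant training
columns get their sd guarded to 1 and are flagged; after centering they are
identically zero and can never enter a LASSO support. Accuracy is reported
everywhere; F1 (positive class = cases, defined as 0 when there are no true
or predicted positives) is added on the imbalanced test set. The decision
threshold is 0.5 throughout.

The L1-logistic base learner picks its penalty by inner stratified 5-fold
CV accuracy over a 10-point log grid running from the full-shrinkage point
down four decades; a fully shrunk model predicts the training prevalence.
The random forest default is 500 trees with `√p` features per split (100
trees in the simulation studies below); its hyperparameters are ordinary
defaults, not tuned.

## Penalized least-squares solvers

Both selection objectives regress the 0/1 label directly; the squared-error
fit is purely a selection device, and classification accuracy is always
computed by a separate unpenalized logistic model on the selected support
(a logistic-loss selection variant is available via the L1-logistic
learner). The solvers are cyclic (block) coordinate descent:

* LASSO: exact coordinate minimization by soft-thresholding; the objective
  is non-increasing by construction. Convergence: relative objective change
  below 1e−8 (tests use down to 1e−14), max 10,000 sweeps; non-convergence
  is logged and the best iterate returned with its KKT residual
  (`|X_j'r| ≤ λ` on the zero set, `= λ·sign(β_j)` elsewhere).
* SG-LASSO: per group, the zero test
  `‖soft(X_g'r, λ₁)‖₂ ≤ λ₂√p_g` either zeroes the block exactly or the
  block is updated by proximal-gradient steps (step size `1/‖X_g‖₂²`,
  ≤ 50 inner iterations — each step decreases the objective, so truncation
  is safe). Zero groups are KKT-checked at the end.

Coefficients below 1e−12 in magnitude are cleared to exact zero after
convergence (float dust at the shrinkage boundary). Correctness is pinned
by the orthonormal closed form (soft-thresholding of `X'y`), the λ=0 least-
squares limit, an independent reference implementation (scikit-learn's
coordinate descent, with the `alpha = λ/n` scaling conversion), a smoothed-
objective quasi-Newton oracle (objective gap < 1e−6 on 20 random
instances), and the analytic reductions SG(λ₁, 0) ≡ LASSO(λ₁) and
singleton-group SG(0, λ₂) ≡ LASSO(λ₂).

## CDL and IDL pipelines

CDL standardizes the complete-data matrix and fits LASSO or SG-LASSO over a
penalty grid (default 8 points per axis, log-spaced over two decades down
from the full-shrinkage point; λ₂ axis additionally includes 0). The grid
point is chosen by the cross-validated accuracy of the downstream logistic
model on the candidate support, with ties broken toward the sparser
support; grid solutions are warm-started along the path. Because small
complete sets make a single CV estimate noisy, the grid score averages 3
repeats of balanced stratified 5-fold CV (each repeat redraws the balancing
resample). Feature selection itself is done once on the full complete set;
only the accuracy estimate is fold-honest — the same compromise a two-step
select-then-validate protocol always makes, and it applies identically to
both pipelines being compared.

IDL stage 1 runs per-source LASSO on all incomplete-data contributors of
the source (test subjects excluded), with λ chosen by standard pathwise
5-fold CV on squared prediction error — the conventional rule for a pure
LASSO path, used here because a downstream-accuracy criterion proved
degenerate (accuracy plateaus let noise collapse the support to ~1
feature). Nonzero weights concatenate into `β_ISL`; stage 2 restricts the
complete-data matrix to those columns and runs the same SG-LASSO grid
procedure as CDL. A source whose stage-1 support is empty contributes no
columns (logged). Ranking returns the top-k features by |β|, ties broken by
(source order, column order).

## Synthetic cohort generator

The generator emulates the target regime at the feature-table level:
4 sources with feature counts tapping 97 / walking 180 / voice 326 /
memory 3 (defaults), ~1,513 subjects, case prevalence 0.65, and presence
drawn from a mixture — with probability 0.08 a subject is a "completer"
contributing everything; otherwise sources are independent coins with
probabilities (0.959, 0.777, 0.452, 0.028). The mixture is what reproduces
*both* the ~8.8% complete-data fraction and the tapping > voice > walking >
memory pool ordering; independent coins alone cannot (their product gives
~4.4% complete), i.e. presence is positively correlated across sources, as
engagement-driven missingness plausibly is. Subjects drawing zero sources
are redrawn; the real mechanism is unknown and is almost certainly not
MCAR, so a label-dependent (MAR) shift is available as a stress-test
option, clearly beyond the emulated regime.

Features are Gaussian with within-source equicorrelation 0.2 and no
between-source correlation. A case expresses each source independently
with probability `heterogeneity` (default 0.6) and shifts that source's
informative features by `effect_size` (default 0.35 sd) only where
expressed; controls are pure noise. Memory carries a single low-value
informative feature by default, mirroring its small, weakly informative
real-world block. What the generator does *not* emulate: raw sensor
waveforms, non-Gaussian feature marginals, between-source correlation of
the signal, informative missingness, and repeated instances per subject —
so passing tests demonstrate the bookkeeping, solvers and fusion logic, not
real-data effect sizes.

## Simulation study conditions

The method-comparison study (`heterogeneous_config`) is a scaled-down
regime chosen once, after a pilot calibration, as the study conditions for
all seeded comparisons: 600 subjects, 55 features
(tapping 12 / walking 16 / voice 24 / memory 3, of which 4/4/5/1
informative), heterogeneity 0.5, effect size 1.5 (an expressed source
carries an aggregate shift of ≈3 sd, i.e. a clearly detectable symptom,
isolating fusion behavior from base-classifier power), completer fraction
0.08 with contribution probabilities (0.85, 0.70, 0.50, 0.15) — ~88% of
subjects incomplete and ~70 complete-data test subjects per replicate. The
test suite runs 50 replicates of this regime; the acceptance script runs
30. Bootstrap defaults follow `n_boot = 10,000`, but the seeded checks run
1,000–2,000 replicates (the CLT calibration they verify is
size-independent). These sizes are the package's own study design for a
single-workstation run.

## Known limitations

* The squared-error selection objectives treat the binary label as numeric;
  this matches the two-step select-then-classify usage but the λ path is
  not a likelihood path.
* With `n < p` complete sets the LASSO solution need not be unique; support
  comparisons across solvers are therefore made on objective values, not
  coefficients, except on orthogonal designs.
* The combined-vs-individual comparison selects the best individual source
  *post hoc* on the test set, which inflates the individual baseline on
  small test sets (winner's curse over 8 models); the reported margins are
  conservative in that respect.
* Generator missingness is MCAR-given-engagement; informative missingness
  would bias the complete-data test set and is not modeled by default.
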