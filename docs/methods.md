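# Methods

## Model

`priodyn` models paired multivariate time series — neural activity
`y_k ∈ R^{n_y}` and behavior `z_k ∈ R^{n_z}` — with a latent dynamical system
written in *predictor form*:

    x_{k+1} = A'(x_k) + K(y_k)
    y_k     = C_y(x_k) + e_k
    z_k     = C_z(x_k) + ε_k

The state update consumes the observed neural sample directly through the
neural-input map `K`, so filtering is a causal forward pass: no inference
problem is solved at test time, and `x_k` is a deterministic function of
`y_1..y_{k-1}`.  The residual processes `e_k`, `ε_k` collect whatever is
unpredictable from past neural activity.

The state is split into two blocks.  Section 1 (`x^(1)`, dimension `n_1`)
carries the behaviorally relevant neural dynamics; section 2 (`x^(2)`,
dimension `n_2 = n_x − n_1`) carries the remaining neural dynamics.  The
section-1 recursion never reads section-2 states, so `x^(1)` can be computed
alone; section 2 additionally receives the updated section-1 state through its
input map, which adds no new dynamics to `x^(2)` (the coupling bypasses the
recursion).

Each of the four parameter maps (`A'`, `K`, `C_y`, `C_z`) is independently
linear (a plain matrix) or a feed-forward ReLU network with 1–2 hidden layers
of 64 or 128 units; the recursion may instead be an LSTM cell.  When a
parameter is nonlinear, the same network shape is used in both sections.  Two
structural rules are applied automatically:

- when *both* `A'` and `K` of a section are nonlinear, the additive update is
  replaced by a single combined network `x' = A''([x; u])`, which contains the
  additive form as a special case;
- with LSTM recursion, the hidden and cell vectors jointly form the internal
  recurrent state, the declared state dimension counts hidden units, and
  readouts see only the hidden part.  This keeps the state-update interface
  identical across all recursion types (the alternative — exposing hidden and
  cell to the readouts — would double the effective readout dimension and
  break the `n_1`/`n_2` bookkeeping).

Categorical behavior is supported by widening `C_z` to `n_z × n_c` logits and
applying a softmax per behavior dimension; the behavior loss becomes the
categorical cross-entropy.  Behavior observed only intermittently is handled
by evaluating the behavior loss only at observed time steps.

## Four-step prioritized optimization

1. **Step 1** trains the section-1 recursion, neural input and behavior
   readout end-to-end to minimize the behavior prediction loss.  The first
   `n_1` latent dimensions are therefore spent on behaviorally relevant
   dynamics before anything else is learned.
2. **Step 2** freezes the section-1 states and fits the section-1 neural
   readout to them.
3. **Step 3** trains section 2 (recursion, input, neural readout) to predict
   the neural residual left by section 1; its input is `[y_k, x^(1)_{k+1}]`.
4. **Step 4** fits a joint behavior readout from both state blocks.  It runs
   when `n_1 = 0` (the unsupervised special case, where behavior can only be
   read out this way) or on request; when `0 < n_1 < n_x` it is skipped and
   behavior is predicted from `x^(1)` alone.

No step is ever revisited; each is independent of the later ones.  After the
steps complete, the residual covariances `Σ_e`, `Σ_ε` are estimated as sample
covariances of the one-step-ahead residuals on the training data (needed only
for simulating from a fitted model).

Losses are negative log-likelihoods: sum of squared errors for continuous
(isotropic-Gaussian) series, categorical cross-entropy (with probabilities
floored at 1e-7) for discrete behavior.

### Optimization details

No automatic-differentiation framework is used: each parameter map implements
its own vector-Jacobian product, and gradients flow through the unrolled
recursion by backpropagation-through-time.  All vjps are verified against
central finite differences in the test suite.  Everything is computed in
float64; this costs nothing with numpy and makes serialization round-trips and
oracle comparisons bit-stable.

- Continuous recordings are cut into fixed-length sequences (default 128
  steps) with the state reset to zero at sequence starts; minibatches of
  sequences (default 8) are optimized with Adam (default step size 3e-3).
  Learning rate and batch size are conventions, not derived quantities; the
  defaults were chosen on simulated linear systems for reliable convergence.
- Early stopping: training stops when the epoch objective has not improved
  for `patience` (default 3) consecutive epochs, and the best-epoch weights
  are restored.  Restoring the best epoch is a package choice; with the
  strict no-improvement rule it makes the stopped model no worse than any
  seen during training.
- Gradients are clipped to a global norm of 10 before each update.  Without
  clipping, candidates with a nonlinear recursion occasionally diverge early
  in training; clipping leaves converged solutions unchanged.
- Linear static readouts (steps 2 and 4 with a linear map and Gaussian loss)
  are solved exactly by least squares — the unique minimizer of the same
  objective — rather than iterated.  Nonlinear readouts use Adam with the
  same early-stopping rule as the recurrent steps.
- Inputs: neural activity and continuous behavior are z-scored per channel
  with training-set statistics (behavior statistics from observed samples
  only), and predictions are mapped back to original units.  Unscaled
  multimodal inputs destabilize gradient training; the scaling is inverted
  exactly, so reported metrics are in original units.
- One master seed fans out to weight initialization, batch order and
  noise draws; repeated fits with the same seed are bit-identical.
- Masked behavior samples contribute exactly zero loss and zero gradient, so
  corrupting them cannot change any learned weight (asserted in tests).
- Initial states are zero; learning them is supported but off by default (on
  long continuous recordings their influence is negligible).
- An L2 regularization hook exists in the configuration but defaults to zero
  and is not used by any analysis here.

## Evaluation

*Decoding* is the mean Pearson correlation (CC), across behavior dimensions,
between behavior and its one-step-ahead prediction from past neural activity
alone; *neural self-prediction* is the same for the neural channels.  Folds
are contiguous segments (remainder samples to the earliest folds) so test
segments are never interleaved with training data.  A constant predicted
dimension scores CC 0 (it carries no signal); a constant *actual* dimension is
excluded with a warning.  Categorical behavior is scored by one-vs-rest ROC
AUC, macro-averaged over classes (the aggregation is a package choice).

State-dimension sweeps fit powers of 2 from 1 to 128, with
`n_1 = min(16, n_x)` by default.  Two selection rules operate on training-data
curves only: the smallest dimension at the training decoding peak, or the
larger of that and the smallest dimension at the training self-prediction
peak.

The *performance frontier* compares models on both metrics jointly: model A is
on the frontier if, against every other model, it is significantly better in
decoding, or significantly better in self-prediction, or not significantly
different in both.  Significance requires a one-sided Wilcoxon signed-rank
P ≤ 0.05 over paired session-folds *and* at least a 1% relative difference of
the means (the relative difference is taken against the comparison model's
mean).  When every pairwise difference is significant the rule reduces to
strict Pareto dominance.

Forecasting feeds the model's one-step neural prediction back as the
observation; m − 1 feedback iterations give the m-step-ahead prediction.  The
model-free baseline holds the last observed value for all horizons (the
"smoothness-only" predictor; the exact formula is an interpretation and is
labeled as such).

For 2-D latent visualizations, states are z-scored (pooled over conditions),
rotated so the first condition's mean trajectory starts at polar angle 0, and
reflected if that trajectory's signed area is clockwise; one transform applies
to all conditions.  Note the rotation preserves the zero mean and the total
(not per-axis) variance.

## Flexible-nonlinearity search

The candidate grid contains 90 architectures: each of the four parameters
linear or nonlinear with a shared feed-forward shape (15 nonempty subsets × 4
shapes + 1 fully linear = 61), plus the LSTM-recursion family over the
remaining three parameters (7 × 4 + 1 = 29).  Each candidate is scored by
twofold inner cross-validation (contiguous halves) within the training data;
the held-out fold of the outer split is never touched.  Selection is either
decoding-focused (maximize self-prediction among candidates within 1 s.e.m.
of the best decoding) or self-prediction-focused (the mirror).  With two inner
folds the s.e.m. is the sample standard deviation over folds divided by √2,
which equals half the absolute fold difference.  Ties on the maximized metric
break toward parsimony: fewer nonlinear parameters, then fewer hidden units,
then fewer layers.

## Synthetic ground truths

The simulation module defines the validation worlds; it emulates no real
dataset.

**Random linear models** (stochastic form): state dimension 16 of which 4
drive behavior, neural and behavior dimensions uniform in 5..10, transition
eigenvalues drawn as conjugate pairs uniformly in the unit disk (realized as
2×2 rotation-scaling blocks, so the behavior-driving states are dynamically
decoupled from the rest), Gaussian readout matrices, state and neural noise
covariances random positive-definite (trace-normalized) scaled log-uniformly
by 0.003–0.3 and 0.01–100.  Behavior noise is produced by an independent
4-state linear model, and the behavior readout rows are rescaled so each
behavior dimension's signal/noise standard-deviation ratio hits a log-uniform
target in 0.5–50.  The scaling uses the analytic stationary covariances
(discrete Lyapunov equations), so the targets are exact in expectation.

**The ideal predictor** of a linear model is its steady-state Kalman one-step
predictor (gain from the discrete algebraic Riccati equation).  Its decoding
and self-prediction CC on generated data are the ceilings against which
fitted models are compared; the behavior-noise sub-model is unobservable from
neural data, so no decoder can beat `C_z x̂`.

**Sine-injected nonlinear models** (predictor form, scalar observations):
a random stable scalar-observation model with one state (or two, only the
first driving behavior) has exactly one parameter replaced by
`linear + a·sin(·)` applied to the parameter's input (for the recursion,
elementwise on the state; for multivariate inputs the sine reads the first
coordinate, the one whose scale is calibrated).  The state is rescaled by a
similarity transform until its empirical 95% interval spans 2π within 10%,
so the sine's input visits roughly one period.  For the neural-input
parameter the sine's input is y, which is invariant to state rescaling, so
there the sine argument is scaled directly to map y's 95% interval onto one
period — without this the injected "nonlinearity" can be indistinguishable
from linear whenever y happens to span a small fraction of a period.  The
sine amplitude is set so its
output range is 0.25 of the linear term's output range within 20%; the two
conditions are alternated on freshly generated data for at most 20 iterations,
and unstable draws are resampled (at most 50 times).  Behavior noise is set to
a signal/noise std ratio of 5 — large enough that decoding differences between
candidate models are measurable, small enough that the sine's effect is not
drowned.  Neural noise variance is drawn log-uniformly in 0.25–4.

**Localization experiment**: for each simulated model, six candidates are
fitted — fully linear, nonlinearity in exactly one of the four parameters
(one hidden layer of 64 units), and fully nonlinear — under contiguous
five-fold cross-validation, and the frontier rule is applied with folds as
paired samples.  Five folds are the minimum at which a one-sided signed-rank
test can reach P ≤ 0.05 (1/32 with five concordant folds), which is why the
per-model protocol uses five folds rather than the two used elsewhere for
simulated data.  `n_1` is set to the number of behavior-driving ground-truth
states, so the two-state protocol exercises both RNN sections.  A candidate
whose training diverges is refitted once with a three-times-smaller step size
and a fresh initialization.

### What the synthetic worlds do and do not show

The generators produce stationary Gaussian(-driven) series with exact
model-class match (up to the injected sine).  Passing the recovery and
localization suites therefore shows that the estimator and the
hypothesis-testing machinery are correct, not that real cortical recordings
satisfy the model's assumptions: real data are nonstationary, non-Gaussian,
have trial structure and unmodeled latent inputs, and their true dimension is
unknown.  Conclusions about where nonlinearity lives in real data must come
from applying the fitted-model comparisons to those data, not from these
simulations.

## Feature extraction

Three neural feature paths share one 50-ms time base, with windows aligned
causally (the feature at step k uses data ending at k·50 ms) so one-step-ahead
prediction never peeks forward:

- spikes: 10-ms binned counts, Gaussian-smoothed (σ = 50 ms, kernel truncated
  at ±4σ, unit sum) and downsampled by 5;
- raw LFP (local motor potential): high-pass 0.5 Hz, low-pass 10 Hz
  (zero-phase forward–backward Butterworth — noncausal within the
  preprocessing stage only), downsampled to 20 Hz;
- band log-powers: Welch spectra in sliding 300-ms windows at 50-ms steps
  with eight half-overlapping subwindows, log mean power in eight standard
  bands (delta 0.1–4, theta 4–8, alpha 8–12, low beta 12–24, mid-beta 24–34,
  high beta 34–55, low gamma 65–95, high gamma 130–170 Hz).  With 300-ms
  windows the spectral resolution is coarse (~15 Hz); the spectrum is
  evaluated on a ~1-Hz zero-padded grid and bands with no native bin fall
  back to the nearest bin.

## Problem sizes used by the shipped validation runs

The test suite and `scripts/acceptance.py` run the protocols at desk scale,
chosen once as the package's own validation sizes: linear recovery uses 10
random models with 10^4 training and 10^4 test samples, trained for 800 epochs
(no early stop, batch 16, sequence length 64); localization uses 3 models per
origin (2 in the acceptance script), series of 2,000 samples, 150 epochs.
Margins in the recovery tests (CC within 0.05 of the Kalman ceiling) are
implementation tolerances for these sizes, not universal constants; both gaps
shrink with longer training data.

## Known limitations

- Training objectives are nonconvex; convergence to the global optimum is not
  guaranteed, and the recovery margins above absorb the residual optimization
  gap at these problem sizes.
- The numpy trainer is single-threaded per fit; the architecture search is
  embarrassingly parallel across candidates but is run serially here.
- Forecast feedback uses the model's own neural prediction as a point
  estimate; no uncertainty is propagated.
- Bidirectional (noncausal) filtering is out of scope.
- The categorical path models behavior classes only; count-valued (Poisson)
  neural observations are not implemented.
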