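# Methods

## The model family

All estimators in this package share one statistical backbone: the Cox
proportional-hazards model. A subject with covariates `x` has hazard

    lambda(t | x) = lambda_0(t) * exp(h(x))

where `h(x)` is the log relative hazard and `lambda_0` an unspecified
baseline. The estimators differ only in how `h` is parameterized:

* **CoxPHSurvival** — `h(x) = beta . x`, fitted by Newton–Raphson
  maximization of the partial likelihood with the Efron correction for tied
  event times. Standard errors come from the inverse observed information.
  The convergence flag is set when `max|score| < tol * max(1, |loglik|)`;
  the tolerance is relative because the score precision attainable in
  floating point scales with the log-likelihood magnitude.
* **DeepSurvMLP** — `h` is a two-hidden-layer perceptron (widths 32/64/128,
  GELU activations, linear scalar head) trained by minimizing the negative
  log partial likelihood.
* **ResNet2DSurvival / ResNet3DSurvival** — `h` is a residual network over
  a coronal maximum-intensity projection (2-D) or the full PET volume
  (3-D). The 2-D family is the canonical 18/34/50-layer topology with a
  single-channel stem. The 3-D family (depths 10/18/34, basic blocks,
  channel widths 64→512) uses 3×3×3 kernels with batch normalization and
  ReLU after every convolution, stride-2 convolutions for downsampling, and
  adaptive average pooling before the scalar head. Its stem is a 3×3×3
  stride-2 convolution followed by a 2×2×2 stride-2 max pool — the /4 stem
  of the standard residual family expressed with the 3×3×3 kernel, which
  also keeps desk-scale CPU training tractable.
* **MultimodalSurvival** — joint fusion: the 3-D ResNet's pooled
  512-feature vector is concatenated with the MLP's last hidden activation
  (e.g. 64), a single linear head maps the fused vector to `h`, and the
  whole graph trains end-to-end from scratch. Warm-starting from trained
  unimodal weights is possible by loading their state dicts, but from-scratch
  joint training is the default (the simplest construction consistent with
  joint fusion).

### Training loss

The neural models minimize the event-normalized negative log partial
likelihood with Breslow handling of ties,

    L = -(1/d) * sum_{i: E_i = 1} [ h_i - log sum_{j: T_j >= T_i} exp(h_j) ]
        + l2_weight * ||theta||^2,

with `d` the number of events in the batch. Risk sets are computed *within
each minibatch* (established practice for image-based Cox training, where
the full-cohort risk set is infeasible at batch size 6); with the clinical
batch size of 125 this is near-full-batch. Each batch is sorted by time and
must contain at least one event; event-free batches are resampled from the
training pool. Dividing by the event count makes the `l2_weight` scale
batch-size-invariant; the default is 1e-4. The tabular Cox fitter uses the
Efron tie correction instead (standard for tabular data); the two tie
conventions are deliberate, matching each estimator's lineage.

Log-sum-exp terms are computed with max-subtraction. Risk scores are clipped
to ±50 before exponentiation in the Breslow estimator.

### From risk scores to survival times

After training, the Breslow estimator of the cumulative baseline hazard is
fitted **on the training data only**, using the final model's risk scores:

    H_0(t) = sum_{t_k <= t} d(t_k) / sum_{j in R(t_k)} exp(h_j).

A subject's survival curve is `S(t | x) = exp(-H_0(t) exp(h))`, and the
predicted absolute survival time is the *median survival time*: the
smallest `t` with `S(t) <= 0.5`, linearly interpolated between the
bracketing curve points. When the curve never reaches 0.5 over the observed
range, an exponential tail with rate `-log S(t_last) / t_last` is fitted to
the last point and the crossing extrapolated, capped at a configurable
horizon (default 10 years) and flagged. The median is measured from
diagnosis (t = 0), since predictions are compared directly with observed
overall-survival times in the MAE; conditional residual life at a later
landmark is out of scope.

## Evaluation

All metrics take predictions oriented as survival times (larger = longer
survival) and return their evaluable denominators:

* **C-index** (Harrell): over pairs with `T_i < T_j` and subject `i` dead;
  tied observed times are not comparable; tied predictions score 0.5.
  Because the median-time transform is antitone in risk, the C-index of
  predicted times equals that of negated risk scores.
* **MAE** over uncensored subjects only — a censored time under-states the
  truth, so its absolute error is not meaningful.
* **2-/5-year status accuracy**: true status is alive if `T >= horizon`
  (any event indicator), dead if `E = 1` and `T < horizon`; subjects
  censored before the horizon are excluded as unknowable. This exclusion is
  the only label-faithful choice; the reported evaluable counts make it
  auditable.
* **Kaplan–Meier** and the two-group **log-rank** test are implemented in
  closed form (product-limit; hypergeometric O−E over V with a 1-df
  chi-square reference) and cross-checked against lifelines in the test
  suite. In the stage-subgroup analysis, the KM curve of a model's
  predicted times carries each subject's actual event indicator, so a
  perfect predictor is exactly exchangeable with the observed curve
  (log-rank p = 1).

Cross-validation is stratified 5-fold on event status (the quantity every
metric conditions on). Each fold trains on the other four with an internal
event-stratified validation split (default 20%) that drives early stopping
on the validation Cox loss (patience 3 by default), restoring the best
weights. Baseline hazards, covariate scalers and all other fitted state
derive from training folds only; a dedicated test corrupts held-out rows
and asserts nothing fitted changes.

## The synthetic cohort generator

The generator emulates a large NSCLC cohort so that the full pipeline is
testable without restricted hospital data:

* **Clinical covariates** — age ~ Normal(67.95, 9.63²) truncated at 20;
  sex, histology, T/N/M, overall stage and smoking history sampled from the
  reference cohort's category counts (74.6% male, 36.7% stage IV, 69.3%
  ever-smokers, ...); pack-years are zero for never-smokers and
  Gamma(2.9, 14.7) for ever-smokers, giving a cohort-wide mean near 29.4.
  Categorical blocks are sampled independently of each other.
* **True hazard** — the clinical linear predictor uses the reference
  multivariate Cox log hazard ratios (age +0.03/year, male +0.48, squamous
  −0.70, stage II/III/IV +0.58/+1.09/+1.36, ...), with continuous
  covariates centered. A standardized latent *image factor* `f ~ N(0,1)`,
  independent of the clinical covariates, enters the true log hazard with
  weight `gamma` (default 1.0). Setting `gamma = 0` produces volumes with
  no prognostic content — the negative control.
* **Outcomes** — event times by inverse-CDF sampling from a Weibull
  baseline (shape 1.2, a mild aging hazard; scale 2900 days, calibrated so
  the uncensored median is ≈ 400 days; an exponential baseline is available
  for closed-form tests). Censoring is the minimum of a 10-year
  administrative horizon and an independent exponential whose rate is
  solved by root finding so the expected censoring fraction hits the
  reference 30.9%.
* **Volumes** — default desk scale 32×32×64 voxels at 4 mm spacing (the
  native 128×128×427 is supported but not needed for testing): a smooth
  noise background plus 1–6 ellipsoidal Gaussian blobs whose count, peak
  intensity and radius all increase monotonically with the subject's image
  factor. The signal is injected through this single scalar factor — the
  minimal structure that makes "images add independent prognostic
  information" true and testable.

What the generator does **not** emulate: anatomy, scanner physics,
attenuation or partial-volume artifacts, correlated clinical covariates
(e.g. TNM consistent with overall stage), non-proportional hazards, or
informative censoring. Passing tests therefore certify the *pipeline* —
losses, estimators, baselines, metrics, splitting — under a data-generating
process where its assumptions hold by construction; they do not certify
performance on real PET cohorts.

## Numerical and engineering choices

The deep-learning stack (reverse-mode autograd, im2col convolutions backed
by BLAS, fused batch normalization, max pooling, Adam) is implemented on
NumPy in float32. Every layer's gradient is validated against central
finite differences, and the autograd Cox loss is validated against the
closed-form value and analytic gradient. Pure-NumPy compute is deterministic
on one CPU: identical seeds give bitwise-identical fits, which the suite
asserts.

Desk-scale experiment settings (used by the test suite and the acceptance
script) differ from the reference training configuration: learning rate
1e-3 rather than 1e-4, one to two epochs for the 3-D models, batch size 8,
and cohorts of 200–2000 subjects. The planted lesion signal is strong and
global, so a few hundred optimizer steps recover it; CPU-only NumPy
convolution makes longer 3-D schedules disproportionate to what the tests
need to demonstrate. The reference configuration (lr 1e-4, batch 6 per
device for volumes and 125 for clinical data, patience 3) remains the
`TrainConfig` default. "Patience" counts epochs without validation-loss
improvement. The early-stopping monitor is the validation Cox loss; the
epoch cap defaults to 200.

Degenerate inputs are errors, not silent values: a batch or cohort with no
events raises `DegenerateBatchError`; metrics with empty denominators
return an explicit undefined result (`nan` with count 0); an all-zero
volume cannot be normalized; a singular information matrix names the
offending design column; an unattainable censoring target reports the
feasible range.

## Known limitations

* Minibatch risk sets are a biased approximation to the full partial
  likelihood; the bias shrinks with batch size and is the accepted
  trade-off for image-based Cox training.
* The exponential-tail extrapolation of median survival is a modelling
  convention; predictions that rely on it are flagged.
* The 2-D ResNet trains from scratch on single-channel MIPs; no transfer
  learning.
* Multi-device training, mixed precision, time-varying covariates,
  competing risks and interval censoring are out of scope.
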