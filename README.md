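# survfusion

Multimodal deep survival prediction for non-small cell lung cancer (NSCLC)
prognosis: Cox-loss neural models over clinical covariates and whole-body
PET volumes, with censoring-aware evaluation and a synthetic multimodal
cohort generator.

## Who this is for

Researchers building or evaluating survival models that combine tabular
clinical data (age, sex, histology, TNM stage, smoking history) with 3-D
functional imaging. The package provides the full chain from raw inputs to
per-patient absolute survival times — and, because real PET cohorts are
restricted, a generator of synthetic cohorts on which every stage of the
pipeline is testable end-to-end.

## The model

Every estimator predicts a single log relative hazard h(x) per subject
under a proportional-hazards model, λ(t|x) = λ₀(t)·exp(h(x)):

| Estimator | h(x) | Input |
|---|---|---|
| `CoxPHSurvival` | β·x (Newton–Raphson, Efron ties) | encoded clinical design matrix |
| `DeepSurvMLP` | 2-hidden-layer GELU MLP (width 32/64/128) | clinical design matrix |
| `ResNet2DSurvival` | ResNet-18/34/50 | coronal maximum-intensity projection |
| `ResNet3DSurvival` | 3-D ResNet-10/18/34 (3×3×3 kernels) | PET volume |
| `MultimodalSurvival` | joint fusion: ResNet3D features ⊕ MLP hidden layer → linear head | volume + clinical |

The neural models train by minimizing the negative log Cox partial
likelihood (Breslow ties, computed within each minibatch, event-normalized,
plus an L2 penalty). A Breslow baseline hazard fitted on the training data
converts risk scores into survival curves S(t|x) = exp(−H₀(t)·exp(h)), and
the predicted absolute survival time is the median of that curve (linear
interpolation at the 0.5 crossing; exponential-tail extrapolation, flagged,
when the curve never reaches 0.5). Evaluation is censoring-aware:
Harrell's C-index, MAE over uncensored subjects, 2-/5-year status accuracy
with censored-before-horizon subjects excluded, Kaplan–Meier curves and
log-rank tests, aggregated over stratified 5-fold cross-validation.

The deep-learning stack (autograd, convolutions, batch norm, Adam) is
implemented on NumPy in float32; every gradient is finite-difference
checked, and fits are bitwise-reproducible per seed on one CPU. See
`docs/methods.md` for the complete model and design documentation.

## Worked example

Simulate a clinical-only cohort of 1200 subjects (reference covariate
marginals, ~31% censoring), cross-validate the DeepSurv MLP, and predict an
individual's survival time:

```python
import survfusion as sf

cfg = sf.CohortConfig(n_subjects=1200, seed=0, image_signal_weight=0.0)
cohort = sf.simulate_cohort(cfg, with_volumes=False)
X, y = cohort.design.matrix, (cohort.times, cohort.events)

mlp = sf.DeepSurvMLP(hidden_width=64, learning_rate=1e-3, batch_size=125,
                     max_epochs=200, patience=10, random_state=0)
result = sf.cross_validate(mlp, X, y, k=5, seed=0)
print(result.summary().round(3).to_string(index=False))

est = mlp.fit(X, y)
curve = est.predict_survival_function(X[:1])[0]
med = sf.median_survival_time(curve, est.horizon_days)
```

Output:

```
fold  mae_days  c_index  acc_2yr  acc_5yr
   0   426.322    0.665    0.665    0.906
   1   420.265    0.685    0.723    0.926
   2   460.565    0.685    0.665    0.893
   3   479.224    0.686    0.715    0.893
   4   455.398    0.680    0.699    0.903
mean   448.355    0.680    0.693    0.904
  sd    24.628    0.009    0.027    0.013
subject syn00000: stage II, observed 509 d (event=1), predicted median survival 960 d
```

Reading the table: each row is one held-out fold. A C-index of 0.680 means
68% of comparable patient pairs are ranked in the correct order (the true
linear predictor itself scores ≈0.70 on this cohort — the model is near the
information ceiling of the simulated signal); the MAE of ≈448 days is the
mean absolute gap between predicted median survival and observed time among
patients whose death was observed; the accuracies are the fractions of
patients whose alive/dead status at 2 and 5 years is predicted correctly.
The per-subject line shows the chain risk score → survival curve → median
survival time for one stage-II patient.

A command-line interface covers the same workflow on on-disk cohorts
(`survfusion simulate | train | evaluate | predict | mip`); configs are
YAML, every run writes a manifest with seeds and checksums.

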