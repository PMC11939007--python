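# Methods

## Model

For covariates `x`, received surgery `T ∈ {0 (NSM), 1 (MRM)}`, follow-up
time `Y` and event indicator `E`, the estimator models the two potential
survival functions with a shared encoder and two arm-specific Cox-mixture
heads:

* encoder `Φ(x)`: a small dense network (default one hidden layer of 16
  tanh units, 8 latent dimensions, dropout 0.2 in training mode);
* per arm, a gating network `g^T(Φ) ∈ Δ^{K−1}` and K component log-hazard
  heads `f_k^T(Φ)` (default K = 3); each component carries a Breslow
  cumulative baseline hazard `Λ_k^T(t)` estimated on the training event
  times with posterior-weighted risk sets;
* predicted survival
  `S(t|x,T) = Σ_k g_k^T(Φ) · exp(−Λ_k^T(t) · exp(f_k^T(Φ)))`.

Proportional hazards is assumed only *within* a component, so crossing
hazards between patient subgroups — the regime in which a single Cox model
misranks one arm — are representable.

### Objective

Each arm-stratified minibatch contributes

```
L = q·lCox^{T=0} + (1−q)·lCox^{T=1} + α·IPM_ε^p(Φ_{T=1}, Φ_{T=0}) + Q^{T=0} + Q^{T=1}
```

* `q` — realized fraction of the batch in arm 0 (stable because batches are
  arm-stratified).
* `lCox` — negative Breslow partial log-likelihood of the mixture-marginal
  log-hazard `η = log Σ_k g_k e^{f_k}`, averaged per event, risk sets within
  the batch.  A configuration switch (`marginal_cox=False`) drops these
  terms to recover pure Cox-mixture (E-step-only) training.
* `IPM` — debiased entropic optimal-transport divergence between the two
  arms' latent batches (ground cost Euclidean², ε = 1.0 on the cost scale by
  default, 30 log-domain iterations, at most 64 points per arm per batch,
  applied every 4th step with the envelope-theorem gradient at the converged
  dual potentials).  Weight α defaults to 0.1.
* `Q` — Monte-Carlo E-step loss: with component assignments `z_i^{(m)}`
  (M = 10 samples per subject, redrawn every 100 iterations from the
  posterior ∝ gate × component survival likelihood under the current
  Breslow baselines), the mean gating negative log-probability plus the
  component-conditional weighted Cox likelihoods at the sampled assignment
  frequencies.

The decomposition identity `total = q·lCox⁰ + (1−q)·lCox¹ + α·IPM + Q⁰ + Q¹`
holds to 1e−10 on every logged batch and is asserted in the tests from the
structured training log.

### Optimization

Manual-backpropagation dense networks trained with Adam (lr 2e−3) and
decoupled weight decay (1e−2, which also curbs the unbounded growth of
partial-likelihood scores).  Early stopping monitors the full objective on
a held-out fold with the Q terms evaluated at posterior expectations
(sampling-free, hence deterministic); patience is counted in iterations
(default 800, checked at E-steps).  All randomness flows from named child
streams of `random_state`; evaluation mode disables dropout, so fitting
and prediction are deterministic given the seed.

### Cross-validated ensemble

`fit` trains one replica per fold (default `n_folds=5`, stratified by
arm × event); each replica early-stops on its own fold and predictions
average the replicas' survival functions.  This is the five-fold training
protocol expressed as an ensemble; it materially stabilizes the recovered
treatment rule relative to a single fit.  Set `n_folds=None` for a single
replica (used by the degenerate-limit equivalence tests).

### Decision rule

TaR (time at risk) is the first time predicted survival falls to the
mortality threshold (default S = 0.10, i.e. 90% mortality), capped at the
analysis horizon (default 120 months; curves that never reach the
threshold are reported at the cap — effectively censored-at-cap, keeping
the ITE finite).  Survival curves are right-continuous step functions, so
the inverse is the first grid time with `S ≤ threshold`; model curves are
evaluated on fine grids, bounding the inversion error by the grid spacing.
`ITE = TaR^{MRM} − TaR^{NSM}`; positive ITE recommends MRM, zero or
negative recommends NSM (the tie goes to the less invasive surgery, which
is also the downgrading target).

### Degenerate limits and baselines

With K = 1 and α = 0 the model reduces to a per-arm proportional-hazards
network: the shared-encoder variant and an independently fitted per-arm
two-network T-learner (the DeepSurv-style baseline) reach the same held-out
concordance within noise.  The BITES-style baseline is K = 1 with α > 0 and
a shared encoder.  The linear Cox T-learner uses the in-package
Newton–Raphson fit (Breslow ties, step-halving line search, sandwich
variance under case weights) and flows through the same TaR/ITE path.  The
guideline rule recommends NSM when any favorable factor holds (grade I/II,
HER2-negative, N0, or node-negative); a random-survival-forest comparator
is a declared plug-in, not bundled.

## Evaluation framework

Patients whose received surgery equals the recommendation form the Consis
group.  Because concordance is not randomized, all contrasts are computed
raw and reweighted by stabilized inverse-probability-of-concordance
weights from a logistic propensity model on the prognostic adjustment set
(age, ER/PR/HER2, grade, axillary nodal status, TNM stage; propensity
scores clipped to [0.01, 0.99]).  Conventions:

* **HR** — hazard of Consis relative to Inconsis from the in-package Cox
  fit adjusted for the same covariate list; HR < 1 means following the
  recommendation is protective.  CIs from the model-based variance, or the
  robust sandwich variance when weighted.
* **RD** — 100·(S_Consis(τ) − S_Inconsis(τ)) from (weighted) Kaplan–Meier
  curves at τ = 120 months; positive is protective.
* **dRMST** — difference in the exact step integral of the K-M curves over
  [0, τ], in months.
* **IBS** — inverse-probability-of-censoring-weighted Brier score
  (censoring distribution by reverse K-M), trapezoid-integrated over a
  40-point grid on (0, τ], one value per treatment arm.
* RD and dRMST CIs use a seeded nonparametric bootstrap over test patients
  (default 500 resamples) with the per-patient recommendations held fixed;
  weighted estimators with unit weights equal their unweighted versions to
  1e−10.

1:1 propensity matching (greedy nearest-neighbor without replacement on
the logit scale, smaller group matched in descending propensity order,
ties broken by patient id, optional caliper) and standardized mean
differences (balance threshold 0.1) support the balance diagnostics.

### Downgrading and mediation

NST downgrading is the risk difference
`P(recommended NSM | NST) − P(recommended NSM | no NST)`, raw and
reweighted by stabilized inverse-probability-of-NST weights, overall and
within EBC/LABC/MBC (stage IV is metastatic; IIB restricted to T3N0
through IIIC is locally advanced; residual IIB (T2N1) is routed to EBC by
default via `iib_policy`).  Mediation uses the linear
product-of-coefficients decomposition with the received surgery as the
mediator; the outcome is configurable (10-year event indicator by default,
truncated survival months as an alternative — the scale is always printed
with the estimate), and `total = NDE + NIE` holds exactly in sample for
the nested OLS fits.  Both analyses bootstrap their CIs (500 resamples,
seeded).

## Synthetic cohorts

The generator emulates a registry-style surgical cohort: demographic and
tumor covariates with realistic marginals (age normal, tumor size
log-normal, stage/grade/receptor multinomials with loose T/N–TNM
consistency), confounded treatment assignment (logistic in age, tumor
size, nodal stage, grade, NST; ~73% MRM under the default scenario),
per-(subgroup, arm) Weibull event times with proportional covariate
effects inside a subgroup, an NST-by-MRM hazard interaction (the
downgrading mechanism), and censoring from an administrative 120-month
horizon plus exponential dropout (~35% censored overall).

Latent subgroup membership is a thresholded biology score (ER/PR/HER2,
grade, age) with a 2% flip probability, so the subgroup is nearly but not
perfectly identifiable from covariates.  The default "strong
heterogeneity" scenario has two subgroups (60/40) with opposite arm
benefits (Weibull scales 110 vs 45 months at shape 1.3, mirrored across
arms) at n = 4,000 — large enough for the neural fits, small enough for a
desk-scale run.  Ground truth records each patient's subgroup, propensity,
closed-form arm-specific survival, TaR and ITE, with
`ITE = TaR^{MRM} − TaR^{NSM}` exact by construction.

What the generator does *not* emulate: competing risks beyond a
cause-of-death label, time-varying covariates or treatments, measurement
error, and the registry's exact marginal distributions.  Passing the
recovery tests therefore demonstrates that the estimation machinery
recovers a known heterogeneous treatment rule under confounding and
censoring — not that the clinical conclusions transfer to any particular
registry.

## Numerical choices and problem sizes

* Cox fitting: Newton–Raphson with step-halving, convergence at gradient
  sup-norm 1e−9, quasi-separation flagged when a coefficient drives the
  linear-predictor spread beyond ~20; Breslow tie handling everywhere.
* Wald intervals for binomial proportions (they reproduce the descriptive
  rates of the motivating cohort to printed precision at n ≈ 38k);
  percentages rounded half-up to 1 decimal.
* K-M and Breslow curves extrapolate flat beyond the last event time (a
  stated limitation, logged when relevant).
* The mortality threshold (0.10), horizon (120 months), α, K, and the IPM
  settings are all estimator parameters; the defaults above were chosen on
  the synthetic scenarios at desk scale — in particular α = 0.1, the
  smallest value of the tuning grid, because stronger balancing collapses
  the low-dimensional latent space and removes prognostic signal at these
  sample sizes.
* Tests and the acceptance script run the full pipeline at n ≈ 4,000 with
  the five-fold ensemble; the balance, null-calibration and antisymmetry
  suites use n = 1,000–2,000 with single replicas.  These sizes are the
  package's reference desk-scale configuration.

## Known limitations

* Breslow baselines are flat beyond the last observed event time, so TaR
  beyond the training follow-up relies on the cap rule.
* The mediation estimator is linear; nonlinear or interaction-rich
  mediation is out of scope.
* Cause-specific survival is handled by refitting on the cause-specific
  event indicator (censoring at other-cause death), not by a competing
  risks model.
* The evaluation reweights by concordance propensity; doubly robust
  estimators are not implemented.
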