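# bimesurv

Individualized treatment-effect estimation for two-arm survival cohorts,
built around a **balanced Cox-mixture T-learner** for comparing
nipple-sparing mastectomy (NSM, arm 0) with modified radical mastectomy
(MRM, arm 1) in observational breast-cancer data, together with the
propensity-based framework for evaluating treatment *recommendations*.

## The problem

Randomized comparisons of NSM and MRM do not exist, so any individualized
comparison must come from observational cohorts in which surgery assignment
is confounded by age, stage, receptor status and nodal involvement, and in
which different patient subgroups may genuinely benefit from different
surgeries (so a single proportional-hazards model is misspecified).  The
package addresses both problems at once:

* a **T-learner**: separate risk models `m1(x)` (MRM) and `m0(x)` (NSM)
  with `CATE(x) = m1(x) − m0(x)`;
* a **shared covariate encoder Φ** whose latent arm distributions are pushed
  together with a debiased entropic-optimal-transport (p-Wasserstein)
  penalty — representation balancing against confounded assignment;
* a **Cox mixture** per arm: K latent components, each with its own
  log-hazard head `f_k(Φ)` and Breslow baseline `Λ_k(t)`, mixed by a gating
  network `g(Φ)`; proportional hazards is assumed only within a component.
  Fitting uses Monte Carlo EM (posterior-sampled component assignments).

The per-batch training objective is

```
L = q·lCox^{T=0} + (1−q)·lCox^{T=1} + α·IPM(Φ_{T=1}, Φ_{T=0}) + Q^{T=0} + Q^{T=1}
```

where `q` is the fraction of the batch in arm 0, `lCox` the mixture-marginal
negative Cox partial log-likelihood, and `Q` the Monte-Carlo E-step loss.
Predictions are survival curves `S(t|x, arm)`; the **time at risk** TaR is
the first month at which `S` reaches 0.10 (90% mortality), capped at 120
months, and the individual treatment effect is
`ITE = TaR^MRM − TaR^NSM` (months).  `ITE > 0` recommends MRM, otherwise
NSM (ties go to the less invasive surgery).

Recommendations are scored on patients grouped by concordance between the
recommended and received surgery (Consis vs Inconsis) via hazard ratios,
10-year risk differences, restricted-mean-survival-time differences and
integrated Brier scores, raw and reweighted by inverse probability of
concordance (IPTW); NST-driven "surgical downgrading" and a linear
NDE/NIE mediation decomposition complete the analysis suite.

Because the motivating registry extract is access-gated, the package ships
a synthetic-cohort generator with confounded assignment, latent-subgroup
heterogeneous Weibull survival and known ground truth, so every stage is
testable end to end.

## Worked example

```python
import numpy as np
from bimesurv import (generate_cohort, strong_heterogeneity_config,
                      BimeRecommender, CohortRecommender,
                      evaluate_recommendation)
from bimesurv.cli import split_cohort

cohort, truth = generate_cohort(strong_heterogeneity_config(n=4000, seed=1))
train, test = split_cohort(cohort, 0.7, seed=1)

model = CohortRecommender(BimeRecommender(random_state=0)).fit(train)
recs = model.recommend(test)
agree = (recs["recommended"].to_numpy()
         == (truth.ite[cohort.df.patient_id.isin(test.df.patient_id)] > 0)).mean()
print(f"agreement with ground-truth rule: {100*agree:.1f}%")

report = evaluate_recommendation(model, test, tau=120.0, seed=1)
print(report.to_frame().to_string(index=False))
```

This prints (a few minutes on one CPU):

```
agreement with ground-truth rule: 90.1%
 IBS_NSM  IBS_MRM               HR           HR_adj              RD_pct          RD_adj_pct        dRMST_months    dRMST_adj_months
   0.184     0.16 0.50 (0.43-0.59) 0.48 (0.41-0.57) 18.61 (12.75-23.99) 17.45 (10.17-23.35) 25.56 (20.42-30.11) 23.79 (17.73-28.82)
```

The model recovers the ground-truth treatment rule for 90% of held-out
patients.  In the Consis-vs-Inconsis contrast, `HR_adj` below 1 means that
following the recommendation is protective after IPTW reweighting;
`RD_adj` is the percentage-point survival difference at 10 years and
`dRMST_adj` the months of restricted mean survival gained over the same
horizon; the IBS columns are the per-arm integrated Brier scores of the
model's survival curves.

The same pipeline is scriptable:

```bash
bime simulate --n 4000 --seed 1 --out cohort.csv
bime evaluate --cohort cohort.csv --model bime --seed 1 --out metrics.json
bime downgrade --cohort cohort.csv --model bime --seed 1 --out downgrade.json
```

## Layout

| Module | Contents |
| --- | --- |
| `bimesurv.cohort` | data dictionary, CSV I/O, stage groups, descriptive summaries |
| `bimesurv.simulate` | synthetic confounded cohorts with known ground truth |
| `bimesurv.bime` | the balanced Cox-mixture T-learner (`BimeRecommender`) |
| `bimesurv.baselines` | Cox PH T-learner, DeepSurv/BITES-style configs, guideline rule |
| `bimesurv.causal` | propensity, IPTW, matching, K-M, log-rank, RMST, IBS, metrics report |
| `bimesurv.mediation` | NST downgrading and NDE/NIE mediation |
| `bimesurv.cli` | `bime` command-line pipeline |

See `docs/methods.md` for the model, assumptions and numerical choices.
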