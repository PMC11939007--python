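"""Comparator recommendation models in the same two-arm (T-learner) interface.

* ``CoxTLearner`` — one linear Cox proportional-hazards model per arm
  (in-package Newton-Raphson on the Breslow partial likelihood).
* DeepSurv-style — the neural T-learner without balancing or mixture
  (``BimeRecommender`` constrained to K=1, alpha=0, per-arm encoders).
* BITES-style — shared encoder with the IPM balance penalty but a single
  proportional-hazards component (K=1, alpha>0).
* ``NCCNRule`` — the guideline screening rule: NSM whenever any favorable
  factor holds (grade I/II, HER2-negative, N0, or axillary-node-negative).

All models emit the same per-patient recommendation schema, so the causal
evaluation is model-agnostic.  A random-survival-forest comparator is a
declared plug-in: any object satisfying the ``CohortRecommender`` protocol
can be evaluated, but none is bundled.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._coxph import cox_fit, breslow_cumhaz
from .bime import BimeRecommender, TarRecommenderMixin, _as_time_event
from .causal import SurvivalCurve
from .cohort import CohortTable, build_design_matrix, DEFAULT_COVARIATES

__all__ = ["CoxTLearner", "NCCNRule", "CohortRecommender", "make_baseline",
           "nccn_recommend", "BASELINE_NAMES"]

BASELINE_NAMES = ("bime", "cph", "deepsurv", "bites", "nccn")


class CoxTLearner(TarRecommenderMixin, BaseEstimator):
    """Linear Cox proportional-hazards T-learner.

    Fits an independent Cox model (with Breslow baseline) to each treatment
    arm on internally standardized covariates; predictions flow through the
    same survival-curve / time-at-risk / ITE path as the neural models.
    Covariates that are constant within an arm are dropped from that arm's
    model with a warning.
    """

    def __init__(self, threshold=0.10, cap=120.0, standardize=True):
        self.threshold = threshold
        self.cap = cap
        self.standardize = standardize

    def fit(self, X, y, treatment):
        X = np.asarray(X, float)
        time, event = _as_time_event(y)
        arm = np.asarray(treatment, int)
        if self.standardize:
            self.mean_ = X.mean(0)
            self.scale_ = np.where(X.std(0) == 0, 1.0, X.std(0))
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.scale_
        self.fits_ = {}
        self.kept_ = {}
        self.baselines_ = {}
        for a in (0, 1):
            m = arm == a
            if m.sum() == 0 or event[m].sum() == 0:
                raise ValueError(f"arm {a} lacks subjects or events")
            keep = np.flatnonzero(Xs[m].std(0) > 0)
            if len(keep) < Xs.shape[1]:
                dropped = sorted(set(range(Xs.shape[1])) - set(keep))
                warnings.warn(f"arm {a}: dropping constant covariates {dropped}")
            fit = cox_fit(Xs[m][:, keep], time[m], event[m])
            eta = Xs[m][:, keep] @ fit.beta
            self.fits_[a] = fit
            self.kept_[a] = keep
            self.baselines_[a] = breslow_cumhaz(eta, time[m], event[m])
        self.n_features_in_ = X.shape[1]
        return self

    def _eta(self, X, arm):
        Xs = (np.asarray(X, float) - self.mean_) / self.scale_
        return Xs[:, self.kept_[arm]] @ self.fits_[arm].beta

    def predict_survival_function(self, X, arm, times=None):
        """S(t | x, arm) = exp(-Lambda_arm(t) * exp(x beta_arm))."""
        if arm not in (0, 1):
            raise ValueError("arm must be 0 or 1")
        eta = self._eta(X, arm)
        bt, ch = self.baselines_[arm]
        if times is None:
            times = np.unique(np.concatenate([[0.0], bt, [self.cap]]))
        times = np.asarray(times, float)
        pos = np.searchsorted(bt, times, side="right") - 1
        Lam = np.where(pos >= 0, ch[np.clip(pos, 0, None)], 0.0)
        S = np.exp(-np.outer(np.exp(eta), Lam))
        return [SurvivalCurve(times, S[i]) for i in range(len(S))]


def nccn_recommend(row) -> int:
    """Guideline rule for one patient row: 0 (NSM) if ANY favorable factor
    holds — grade I/II, HER2-negative, N0, or axillary-node-negative —
    else 1 (MRM)."""
    for key in ("grade", "her2_positive", "n_stage", "aln_positive"):
        if key not in row or pd.isna(row[key]):
            raise KeyError(f"missing field {key!r} for the guideline rule")
    favorable = (
        row["grade"] in ("I", "II")
        or int(row["her2_positive"]) == 0
        or row["n_stage"] == "N0"
        or int(row["aln_positive"]) == 0
    )
    return 0 if favorable else 1


class NCCNRule:
    """Rule-based recommender; requires no fitting."""

    def fit(self, cohort: CohortTable):
        return self

    def recommend(self, cohort: CohortTable) -> pd.DataFrame:
        df = cohort.df
        rec = np.array([nccn_recommend(r) for _, r in df.iterrows()], int)
        return pd.DataFrame({
            "patient_id": df["patient_id"].to_numpy(),
            "tar_nsm": np.nan, "tar_mrm": np.nan, "ite": np.nan,
            "recommended": rec,
        })


class CohortRecommender:
    """Glue between a covariate-matrix estimator and the cohort table.

    Builds the design matrix from the cohort's data dictionary, fits the
    wrapped estimator on (X, [time, event], treatment), and exposes the
    cohort-level ``recommend`` / ``predict_curves`` interface the evaluation
    framework consumes.
    """

    def __init__(self, estimator, covariates=None, endpoint="overall"):
        self.estimator = estimator
        self.covariates = list(covariates) if covariates else list(DEFAULT_COVARIATES)
        self.endpoint = endpoint

    def fit(self, cohort: CohortTable):
        X, names, _ = build_design_matrix(cohort, self.covariates, standardize=False)
        self.feature_names_ = names
        time, event = cohort.survival_arrays(self.endpoint)
        self.estimator.fit(X, np.column_stack([time, event]), cohort.treatment)
        return self

    def _design(self, cohort):
        X, _, _ = build_design_matrix(cohort, self.covariates, standardize=False)
        return X

    def recommend(self, cohort: CohortTable) -> pd.DataFrame:
        X = self._design(cohort)
        tar = self.estimator.predict_tar(X)
        ite = tar[:, 1] - tar[:, 0]
        return pd.DataFrame({
            "patient_id": cohort.df["patient_id"].to_numpy(),
            "tar_nsm": tar[:, 0], "tar_mrm": tar[:, 1], "ite": ite,
            "recommended": (ite > 0).astype(int),
        })

    def predict_curves(self, cohort: CohortTable, arm: int):
        return self.estimator.predict_survival_function(self._design(cohort), arm)


def make_baseline(name: str, covariates=None, endpoint="overall",
                  random_state=0, **overrides):
    """Construct a recommendation model by name.

    ``deepsurv`` and ``bites`` are constrained configurations of the
    balanced Cox-mixture estimator (K=1; alpha=0 with per-arm encoders,
    or alpha>0 with a shared encoder, respectively).
    """
    name = name.lower()
    if name == "nccn":
        return NCCNRule()
    if name == "cph":
        est = CoxTLearner(**{k: v for k, v in overrides.items()
                             if k in ("threshold", "cap", "standardize")})
    elif name == "deepsurv":
        overrides.update(k=1, alpha=0.0, shared_encoder=False)
        est = BimeRecommender(random_state=random_state, **overrides)
    elif name == "bites":
        overrides.setdefault("alpha", 0.1)
        if overrides["alpha"] <= 0:
            raise ValueError("the BITES configuration requires alpha > 0")
        overrides.update(k=1, shared_encoder=True)
        est = BimeRecommender(random_state=random_state, **overrides)
    elif name == "bime":
        est = BimeRecommender(random_state=random_state, **overrides)
    elif name == "rsf":
        raise NotImplementedError(
            "a random-survival-forest comparator is not bundled; wrap an "
            "external implementation in the CohortRecommender interface "
            "(fit / recommend / predict_curves) to evaluate one"
        )
    else:
        raise ValueError(f"unknown baseline {name!r}; choose from {BASELINE_NAMES}")
    return CohortRecommender(est, covariates=covariates, endpoint=endpoint)
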