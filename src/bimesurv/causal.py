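"""Recommendation-evaluation framework: propensity scores, IPTW, matching,
balance diagnostics, nonparametric survival estimators and the
Consis/Inconsis metrics report.

Patients whose received surgery matches the model's recommendation form the
"Consis" group; the rest "Inconsis".  Because recommendation concordance is
not randomized, contrasts between the two groups are confounded; all
contrasts are therefore reported both raw and reweighted by inverse
probability of (concordance-group) membership, with the propensity fitted on
the prognostic covariate set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._coxph import cox_fit, CoxFit
from .cohort import CohortTable, build_design_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCurve", "PropensityFit", "MatchedSample", "MetricsReport",
    "fit_propensity", "iptw_weights", "psm_match", "smd", "km_curve",
    "logrank_test", "rmst", "risk_difference", "cox_hr", "integrated_brier",
    "evaluate_recommendation",
]

#: covariates used for confounding adjustment: prognosis- and
#: treatment-decision-related variables (age, receptor subtype, grade,
#: nodal status, TNM stage)
ADJUSTMENT_COVARIATES = [
    "age", "er_positive", "pr_positive", "her2_positive", "grade",
    "aln_positive", "tnm_stage",
]


# ---------------------------------------------------------------------------
# survival curve container


@dataclass
class SurvivalCurve:
    """Right-continuous step survival function on an ascending time grid.

    ``times[0]`` need not be 0; ``at(t)`` returns 1 for t before the first
    grid point.  Values must be nonincreasing and within [0, 1].
    """

    times: np.ndarray
    surv: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.surv = np.asarray(self.surv, float)
        if self.times.ndim != 1 or self.times.shape != self.surv.shape:
            raise ValueError("times and surv must be 1-D and equally long")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be ascending")
        if np.any(np.diff(self.surv) > 1e-12):
            raise ValueError("survival values must be nonincreasing")
        if self.surv.size and (self.surv.max() > 1 + 1e-12 or self.surv.min() < -1e-12):
            raise ValueError("survival values must lie in [0, 1]")

    def at(self, t) -> np.ndarray | float:
        """S(t) by step lookup (flat extrapolation beyond the last time)."""
        t = np.asarray(t, float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.surv[np.clip(idx, 0, len(self.surv) - 1)])
        return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# propensity, weights, matching, balance


@dataclass
class PropensityFit:
    """Logistic propensity model for a binary group indicator."""

    coef: np.ndarray
    names: list[str]
    scores: np.ndarray        # clipped to [clip, 1-clip]
    clip: float = 0.01


def fit_propensity(X, indicator, names=None, clip=0.01) -> PropensityFit:
    """Maximum-likelihood logistic regression of ``indicator`` on ``X``.

    Scores are clipped to ``[clip, 1 - clip]`` to keep downstream inverse
    weights finite.  Perfect separation raises, naming the covariate with
    the largest diverging coefficient.
    """
    X = np.asarray(X, float)
    indicator = np.asarray(indicator, int)
    if len(np.unique(indicator)) < 2:
        raise ValueError("indicator must take both values 0 and 1")
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    keep = np.flatnonzero(X.std(0) > 0)
    if len(keep) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"dropping constant covariates from propensity model: {dropped}")
        X = X[:, keep]
        names = [names[j] for j in keep]
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(indicator, Xc).fit(disp=False, maxiter=200)
    except np.linalg.LinAlgError as err:
        raise RuntimeError(f"propensity model is not identifiable: {err}") from err
    coef = res.params
    if not np.all(np.isfinite(coef)) or np.abs(coef[1:]).max() > 30:
        j = int(np.argmax(np.abs(coef[1:])))
        raise RuntimeError(
            f"propensity model did not converge; covariate {names[j]!r} "
            "appears to separate the groups"
        )
    scores = np.clip(res.predict(Xc), clip, 1 - clip)
    return PropensityFit(coef=np.asarray(coef), names=["const"] + names,
                         scores=scores, clip=clip)


def iptw_weights(fit: PropensityFit, indicator, stabilized=True) -> np.ndarray:
    """Inverse-probability-of-treatment weights from fitted propensities.

    Unstabilized: ``1/e`` for the indicated group, ``1/(1-e)`` otherwise.
    Stabilized weights multiply by the marginal group prevalence, so they
    average about 1 within each group.
    """
    indicator = np.asarray(indicator, int)
    e = fit.scores
    w = np.where(indicator == 1, 1.0 / e, 1.0 / (1.0 - e))
    if stabilized:
        p1 = indicator.mean()
        w = w * np.where(indicator == 1, p1, 1.0 - p1)
    return w


@dataclass
class MatchedSample:
    """1:1 matched pairs (indices into the original table)."""

    pairs: list[tuple[int, int]]   # (index in group 1, index in group 0)
    caliper: float | None = None

    @property
    def indices(self) -> np.ndarray:
        return np.array(sorted({i for p in self.pairs for i in p}), int)


def psm_match(fit: PropensityFit, indicator, caliper=None, ids=None) -> MatchedSample:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Matching distance is on the logit-propensity scale.  The smaller group's
    subjects are matched in order of descending propensity (ties broken by
    ``ids``), making the result deterministic.  ``caliper`` (on the logit
    scale) discards pairs farther apart than the threshold.
    """
    indicator = np.asarray(indicator, int)
    logit = np.log(fit.scores / (1 - fit.scores))
    idx1 = np.flatnonzero(indicator == 1)
    idx0 = np.flatnonzero(indicator == 0)
    if len(idx1) == 0 or len(idx0) == 0:
        raise ValueError("both indicator levels must be present")
    small, large = (idx1, idx0) if len(idx1) <= len(idx0) else (idx0, idx1)
    ids = np.asarray(ids) if ids is not None else np.arange(len(indicator)).astype(str)
    order = sorted(small, key=lambda i: (-logit[i], ids[i]))
    available = dict.fromkeys(large)   # insertion-ordered set
    pairs = []
    for i in order:
        if not available:
            break
        j = min(available, key=lambda j: (abs(logit[j] - logit[i]), ids[j]))
        if caliper is not None and abs(logit[j] - logit[i]) > caliper:
            continue
        del available[j]
        pairs.append((i, j) if indicator[i] == 1 else (j, i))
    if not pairs:
        raise ValueError("no matches found under the caliper")
    return MatchedSample(pairs=pairs, caliper=caliper)


def smd(x, grouping, weights=None) -> float:
    """Standardized mean difference |m1 - m0| / sqrt((v1 + v0) / 2).

    With ``weights``, weighted means and variances are used.  A zero pooled
    variance returns 0 with a warning.
    """
    x = np.asarray(x, float)
    g = np.asarray(grouping, int)
    w = np.ones(len(x)) if weights is None else np.asarray(weights, float)
    out = []
    for lev in (1, 0):
        m = g == lev
        ww = w[m]
        mu = np.average(x[m], weights=ww)
        var = np.average((x[m] - mu) ** 2, weights=ww)
        out.append((mu, var))
    (m1, v1), (m0, v0) = out
    pooled = (v1 + v0) / 2.0
    if pooled <= 0:
        warnings.warn("zero pooled variance in SMD; returning 0")
        return 0.0
    return float(abs(m1 - m0) / np.sqrt(pooled))


def smd_table(X, names, grouping, weights=None) -> pd.Series:
    """SMD for every column of a design matrix."""
    return pd.Series({nm: smd(X[:, j], grouping, weights)
                      for j, nm in enumerate(names)})


# ---------------------------------------------------------------------------
# nonparametric survival


def km_curve(times, events, weights=None) -> SurvivalCurve:
    """(Weighted) Kaplan-Meier product-limit estimator.

    The weighted variant replaces risk-set and event counts with weighted
    sums, as used under IPTW.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValueError("empty input")
    w = np.ones(len(times)) if weights is None else np.asarray(weights, float)
    order = np.argsort(times, kind="stable")
    t, e, ww = times[order], events[order], w[order]
    uniq = np.unique(t[e == 1])
    total = ww.sum()
    # weighted count removed before each unique event time
    removed_before = {u: ww[t < u].sum() for u in uniq}
    surv = []
    s = 1.0
    for u in uniq:
        at_risk = total - removed_before[u]
        d = ww[(t == u) & (e == 1)].sum()
        s *= 1.0 - d / at_risk
        surv.append(s)
    grid = np.concatenate([[0.0], uniq])
    vals = np.concatenate([[1.0], np.maximum(surv, 0.0)])
    return SurvivalCurve(np.asarray(grid), np.asarray(vals))


def logrank_test(times, events, grouping, weights=None) -> tuple[float, float]:
    """Two-group log-rank chi-square test (1 df).

    The weighted variant substitutes weighted risk/event counts in the
    hypergeometric expectation and variance sums.
    """
    from scipy.stats import chi2

    times = np.asarray(times, float)
    events = np.asarray(events, int)
    g = np.asarray(grouping, int)
    if len(np.unique(g)) < 2:
        raise ValueError("log-rank test requires two groups")
    if events.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    w = np.ones(len(times)) if weights is None else np.asarray(weights, float)
    uniq = np.unique(times[events == 1])
    O = E = V = 0.0
    for u in uniq:
        at = times >= u
        n_tot = w[at].sum()
        n1 = w[at & (g == 1)].sum()
        dmask = (times == u) & (events == 1)
        d = w[dmask].sum()
        d1 = w[dmask & (g == 1)].sum()
        O += d1
        E += d * n1 / n_tot
        if n_tot > 1:
            V += d * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d) / (n_tot - 1)
    if V <= 0:
        return 0.0, 1.0
    stat = (O - E) ** 2 / V
    return float(stat), float(chi2.sf(stat, df=1))


def rmst(curve: SurvivalCurve, tau: float) -> float:
    """Restricted mean survival time: exact step integral of S on [0, tau].

    Beyond the last grid point the curve is extrapolated flat (logged).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t, s = curve.times, curve.surv
    if t.size == 0:
        return tau
    if tau > t[-1]:
        logger.info("rmst: tau=%.6g beyond last grid point %.6g; flat extrapolation",
                    tau, t[-1])
    area = 0.0
    prev_t, prev_s = 0.0, 1.0
    for ti, si in zip(t, s):
        if ti >= tau:
            break
        if ti > prev_t:
            area += prev_s * (ti - prev_t)
        prev_t, prev_s = ti, si
    area += prev_s * (tau - prev_t)
    return float(area)


def risk_difference(curve_a: SurvivalCurve, curve_b: SurvivalCurve, tau: float) -> float:
    """100 x (S_A(tau) - S_B(tau)), in percentage points."""
    return float(100.0 * (curve_a.at(tau) - curve_b.at(tau)))


def cox_hr(X, time, event, indicator, weights=None, names=None,
           level=0.95) -> tuple[float, tuple[float, float], CoxFit]:
    """Hazard ratio for a binary indicator, adjusted for covariates X.

    The indicator enters as the first design column; with weights the CI
    uses the robust sandwich variance.
    """
    indicator = np.asarray(indicator, float)
    design = indicator[:, None] if X is None else np.column_stack([indicator, X])
    nm = ["indicator"] + (list(names) if names else
                          [f"x{j}" for j in range(design.shape[1] - 1)])
    fit = cox_fit(design, time, event, weights=weights, names=nm,
                  robust=weights is not None)
    hr, lo, hi = fit.hazard_ratio(0, level=level, robust=weights is not None)
    return hr, (lo, hi), fit


def integrated_brier(curves: list[SurvivalCurve], times, events, tau_grid) -> float:
    """IPCW integrated Brier score over ``tau_grid`` (trapezoid rule).

    The censoring distribution G is the Kaplan-Meier estimator of the
    censoring times; observations are weighted 1/G(T_i-) for deaths before t
    and 1/G(t) for survivors past t.  If G hits 0 inside the grid the grid
    is truncated with a warning.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    tau_grid = np.asarray(tau_grid, float)
    n = len(times)
    G = km_curve(times, 1 - events)

    def G_at_minus(t):
        return G.at(np.maximum(t - 1e-9, 0.0))

    g_grid = np.asarray([G.at(t) for t in tau_grid])
    if np.any(g_grid <= 0):
        cut = int(np.argmax(g_grid <= 0))
        warnings.warn("censoring survival reached 0 inside the grid; truncating")
        tau_grid = tau_grid[:cut]
        g_grid = g_grid[:cut]
        if tau_grid.size < 2:
            raise ValueError("grid collapsed after truncation")
    bs = np.zeros(len(tau_grid))
    S_pred = np.array([[c.at(t) for t in tau_grid] for c in curves])
    g_tm = G_at_minus(times)
    for k, t in enumerate(tau_grid):
        died = (times <= t) & (events == 1)
        alive = times > t
        contrib = np.zeros(n)
        contrib[died] = (0.0 - S_pred[died, k]) ** 2 / g_tm[died]
        contrib[alive] = (1.0 - S_pred[alive, k]) ** 2 / g_grid[k]
        bs[k] = contrib.sum() / n
    return float(np.trapezoid(bs, tau_grid) / (tau_grid[-1] - tau_grid[0]))


# ---------------------------------------------------------------------------
# the Consis/Inconsis report


@dataclass
class MetricsReport:
    """Recommendation-effect metrics, raw and IPTW-adjusted.

    HR is the hazard of the Consis group relative to Inconsis (HR < 1 means
    following the recommendation is protective); RD and dRMST are
    Consis - Inconsis at/over the horizon ``tau``.
    """

    tau: float
    n_consis: int
    n_inconsis: int
    hr: float
    hr_ci: tuple[float, float]
    hr_adj: float
    hr_adj_ci: tuple[float, float]
    rd: float
    rd_ci: tuple[float, float]
    rd_adj: float
    rd_adj_ci: tuple[float, float]
    drmst: float
    drmst_ci: tuple[float, float]
    drmst_adj: float
    drmst_adj_ci: tuple[float, float]
    ibs_nsm: float | None = None
    ibs_mrm: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ["tau", "n_consis", "n_inconsis", "hr", "hr_ci", "hr_adj",
              "hr_adj_ci", "rd", "rd_ci", "rd_adj", "rd_adj_ci", "drmst",
              "drmst_ci", "drmst_adj", "drmst_adj_ci", "ibs_nsm", "ibs_mrm"]}
        d.update(self.extras)
        return d

    def to_frame(self) -> pd.DataFrame:
        """One-row table shaped like a published model-performance row."""
        f = lambda x, ci: f"{x:.2f} ({ci[0]:.2f}-{ci[1]:.2f})"
        return pd.DataFrame([{
            "IBS_NSM": None if self.ibs_nsm is None else round(self.ibs_nsm, 3),
            "IBS_MRM": None if self.ibs_mrm is None else round(self.ibs_mrm, 3),
            "HR": f(self.hr, self.hr_ci),
            "HR_adj": f(self.hr_adj, self.hr_adj_ci),
            "RD_pct": f(self.rd, self.rd_ci),
            "RD_adj_pct": f(self.rd_adj, self.rd_adj_ci),
            "dRMST_months": f(self.drmst, self.drmst_ci),
            "dRMST_adj_months": f(self.drmst_adj, self.drmst_adj_ci),
        }])


def _km_contrast(time, event, consis, weights, tau):
    c_curve = km_curve(time[consis == 1], event[consis == 1],
                       None if weights is None else weights[consis == 1])
    i_curve = km_curve(time[consis == 0], event[consis == 0],
                       None if weights is None else weights[consis == 0])
    rd = risk_difference(c_curve, i_curve, tau)
    dr = rmst(c_curve, tau) - rmst(i_curve, tau)
    return rd, dr


def evaluate_recommendation(
    model,
    cohort: CohortTable,
    tau: float = 120.0,
    endpoint: str = "overall",
    covariates: list[str] | None = None,
    n_bootstrap: int = 500,
    seed: int = 0,
    compute_ibs: bool = True,
) -> MetricsReport:
    """Full Consis/Inconsis evaluation of a fitted recommendation model.

    ``model`` must provide ``recommend(cohort) -> DataFrame`` with a
    ``recommended`` column (and, for the Brier score, ``predict_curves``).
    HR CIs come from the (robust, when weighted) Cox variance; RD and dRMST
    CIs from a seeded nonparametric bootstrap over test patients with the
    per-patient recommendations held fixed.
    """
    recs = model.recommend(cohort)
    received = cohort.treatment
    consis = (recs["recommended"].to_numpy() == received).astype(int)
    if consis.sum() == 0 or consis.sum() == len(consis):
        name = "Consis" if consis.sum() == 0 else "Inconsis"
        raise ValueError(f"degenerate evaluation: the {name} group is empty")

    time, event = cohort.survival_arrays(endpoint)
    covariates = covariates or ADJUSTMENT_COVARIATES
    X, names, _ = build_design_matrix(cohort, covariates)

    pfit = fit_propensity(X, consis, names)
    w = iptw_weights(pfit, consis, stabilized=True)

    hr, hr_ci, _ = cox_hr(X, time, event, consis, names=names)
    hr_adj, hr_adj_ci, _ = cox_hr(X, time, event, consis, weights=w, names=names)

    rd, dr = _km_contrast(time, event, consis, None, tau)
    rd_adj, dr_adj = _km_contrast(time, event, consis, w, tau)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_bootstrap, 4))
    n = len(consis)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        cb, tb, eb, wb = consis[idx], time[idx], event[idx], w[idx]
        if cb.sum() in (0, len(cb)):
            boots[b] = np.nan
            continue
        boots[b, 0], boots[b, 1] = _km_contrast(tb, eb, cb, None, tau)
        boots[b, 2], boots[b, 3] = _km_contrast(tb, eb, cb, wb, tau)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)

    ibs_nsm = ibs_mrm = None
    if compute_ibs and hasattr(model, "predict_curves"):
        grid = np.linspace(1.0, tau, 40)
        for arm, label in ((0, "nsm"), (1, "mrm")):
            m = received == arm
            if m.sum() == 0:
                continue
            curves = model.predict_curves(cohort.subset(m), arm=arm)
            val = integrated_brier(curves, time[m], event[m], grid)
            if label == "nsm":
                ibs_nsm = val
            else:
                ibs_mrm = val

    return MetricsReport(
        tau=tau, n_consis=int(consis.sum()), n_inconsis=int((1 - consis).sum()),
        hr=hr, hr_ci=hr_ci, hr_adj=hr_adj, hr_adj_ci=hr_adj_ci,
        rd=rd, rd_ci=(float(lo[0]), float(hi[0])),
        rd_adj=rd_adj, rd_adj_ci=(float(lo[2]), float(hi[2])),
        drmst=dr, drmst_ci=(float(lo[1]), float(hi[1])),
        drmst_adj=dr_adj, drmst_adj_ci=(float(lo[3]), float(hi[3])),
        ibs_nsm=ibs_nsm, ibs_mrm=ibs_mrm,
        extras={"consis_rate": float(consis.mean()),
                "nsm_recommended_rate": float((recs["recommended"] == 0).mean())},
    )
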