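"""Causal analyses downstream of the recommendation model.

* **Surgical downgrading**: treating neoadjuvant systemic treatment (NST)
  as a binary exposure, the risk difference RD = P(recommended NSM | NST) -
  P(recommended NSM | no NST), raw and reweighted by the inverse
  probability of NST (propensity on the prognostic covariates), overall and
  within the EBC / LABC / MBC stage groups.
* **Mediation**: a linear product-of-coefficients decomposition of the
  recommendation-concordance effect into the natural direct effect (NDE)
  and the natural indirect effect (NIE) through the surgery actually
  received.  For the linear specification total = NDE + NIE holds exactly
  in sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .causal import fit_propensity, iptw_weights
from .cohort import CohortTable, build_design_matrix, stage_groups

__all__ = ["DowngradeResult", "MediationResult", "nst_downgrading", "mediation_nde"]


@dataclass
class DowngradeResult:
    """NST -> NSM-recommendation risk difference for one stage subgroup."""

    subgroup: str            # all / EBC / LABC / MBC
    rd: float                # percentage points
    rd_ci: tuple[float, float]
    rd_adj: float            # IPTW-adjusted, percentage points
    rd_adj_ci: tuple[float, float]
    n_nst: int
    n_no_nst: int


def _weighted_rd(rec_nsm, nst, w):
    p1 = np.average(rec_nsm[nst == 1], weights=w[nst == 1])
    p0 = np.average(rec_nsm[nst == 0], weights=w[nst == 0])
    return 100.0 * (p1 - p0)


def nst_downgrading(recs: pd.DataFrame, cohort: CohortTable,
                    covariates=None, n_bootstrap=500, seed=0,
                    iib_policy="EBC") -> list[DowngradeResult]:
    """Risk difference of an NSM recommendation attributable to NST.

    ``recs`` must carry a ``recommended`` column aligned with the cohort.
    The adjusted RD reweights by stabilized inverse-probability-of-NST
    weights.  Subgroups with an empty NST stratum are skipped with a
    warning.  CIs by seeded nonparametric bootstrap.
    """
    from .causal import ADJUSTMENT_COVARIATES

    covariates = covariates or ADJUSTMENT_COVARIATES
    rec_nsm = (recs["recommended"].to_numpy() == 0).astype(float)
    nst = cohort.df["nst"].to_numpy(int)
    X, names, _ = build_design_matrix(cohort, covariates)
    sg = stage_groups(cohort, iib_policy).to_numpy()
    rng = np.random.default_rng(seed)

    results = []
    for label in ("all", "EBC", "LABC", "MBC"):
        m = np.ones(len(nst), bool) if label == "all" else sg == label
        if m.sum() == 0 or nst[m].sum() == 0 or (1 - nst[m]).sum() == 0:
            warnings.warn(f"subgroup {label}: an NST stratum is empty; skipped")
            continue
        Xm, nm, rm = X[m], nst[m], rec_nsm[m]
        try:
            pfit = fit_propensity(Xm, nm, names)
        except RuntimeError as err:
            warnings.warn(f"subgroup {label}: propensity fit failed ({err}); skipped")
            continue
        w = iptw_weights(pfit, nm, stabilized=True)
        ones = np.ones(m.sum())
        rd = _weighted_rd(rm, nm, ones)
        rd_adj = _weighted_rd(rm, nm, w)
        boots = np.full((n_bootstrap, 2), np.nan)
        nmm = m.sum()
        for b in range(n_bootstrap):
            idx = rng.integers(0, nmm, nmm)
            nb, rb, wb = nm[idx], rm[idx], w[idx]
            if nb.sum() in (0, nmm):
                continue
            boots[b, 0] = _weighted_rd(rb, nb, np.ones(nmm))
            boots[b, 1] = _weighted_rd(rb, nb, wb)
        lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
        results.append(DowngradeResult(
            subgroup=label, rd=rd, rd_ci=(float(lo[0]), float(hi[0])),
            rd_adj=rd_adj, rd_adj_ci=(float(lo[1]), float(hi[1])),
            n_nst=int(nm.sum()), n_no_nst=int((1 - nm).sum()),
        ))
    return results


@dataclass
class MediationResult:
    """Linear mediation decomposition of an exposure effect."""

    nde: float
    nde_ci: tuple[float, float]
    nie: float
    nie_ci: tuple[float, float]
    total: float
    outcome_label: str

    def decomposition_residual(self) -> float:
        return abs(self.total - (self.nde + self.nie))


def mediation_nde(exposure, mediator, outcome, covariates=None,
                  n_bootstrap=500, seed=0,
                  outcome_label="outcome") -> MediationResult:
    """Product-of-coefficients mediation with linear regressions.

    ``outcome ~ exposure + mediator + covariates`` gives the NDE (exposure
    slope) and the mediator->outcome slope b; ``mediator ~ exposure +
    covariates`` gives the exposure->mediator slope a; NIE = a * b.  The
    total effect (exposure slope of the reduced model without the mediator)
    equals NDE + NIE exactly for nested OLS fits.  CIs by seeded bootstrap.
    """
    x = np.asarray(exposure, float)
    m = np.asarray(mediator, float)
    yv = np.asarray(outcome, float)
    C = None if covariates is None else np.asarray(covariates, float)
    if C is not None and C.ndim == 1:
        C = C[:, None]
    corr = np.corrcoef(x, m)[0, 1] if x.std() > 0 and m.std() > 0 else 1.0
    if abs(corr) > 0.999:
        raise ValueError("exposure and mediator are (near-)collinear")

    def _fit(xv, mv, yvv, Cv):
        full = np.column_stack([xv, mv] + ([Cv] if Cv is not None else []))
        med = np.column_stack([xv] + ([Cv] if Cv is not None else []))
        r_out = sm.OLS(yvv, sm.add_constant(full)).fit()
        r_med = sm.OLS(mv, sm.add_constant(med)).fit()
        nde = r_out.params[1]
        b = r_out.params[2]
        a = r_med.params[1]
        return float(nde), float(a * b)

    nde, nie = _fit(x, m, yv, C)
    reduced = np.column_stack([x] + ([C] if C is not None else []))
    total = float(sm.OLS(yv, sm.add_constant(reduced)).fit().params[1])

    rng = np.random.default_rng(seed)
    n = len(x)
    boots = np.full((n_bootstrap, 2), np.nan)
    for bix in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        try:
            boots[bix] = _fit(x[idx], m[idx], yv[idx],
                              None if C is None else C[idx])
        except Exception:
            continue
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return MediationResult(
        nde=nde, nde_ci=(float(lo[0]), float(hi[0])),
        nie=nie, nie_ci=(float(lo[1]), float(hi[1])),
        total=total, outcome_label=outcome_label,
    )
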