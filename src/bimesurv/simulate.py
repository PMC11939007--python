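"""Synthetic registry-style survival cohorts with known ground truth.

Emulates the structure of an observational mastectomy cohort: confounded
binary treatment assignment (NSM vs MRM), right-censored overall and
breast-cancer-specific survival, and latent-subgroup heterogeneous treatment
effects.  Event times are Weibull within latent subgroup x arm, proportional
hazards in the covariates *within* a subgroup; across subgroups the arms can
swap which surgery is beneficial, which violates a global proportional
hazards assumption — exactly the regime a Cox-mixture treatment-effect model
targets.

The generator records per-patient ground truth (latent subgroup, propensity,
closed-form arm-specific survival, time-at-risk and individual treatment
effect), so that recovery of the treatment rule can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, TNM_LEVELS, LOCATION_LEVELS, RACE_LEVELS

__all__ = ["SimConfig", "GroundTruth", "generate_cohort", "strong_heterogeneity_config"]


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Subgroup membership is driven by a covariate score (receptor status,
    grade, age) thresholded at the quantile implied by ``subgroup_probs``,
    with a small flip probability ``subgroup_noise`` — so the latent subgroup
    is nearly, but not perfectly, identifiable from covariates.

    Weibull parameters are per (subgroup, arm): ``weibull[k][arm] =
    (shape, scale_months)``.  Covariate effects act proportionally on the
    hazard.  ``nst_hazard_mult`` multiplies the MRM-arm hazard for patients
    who received neoadjuvant systemic treatment (NST), encoding the surgical
    downgrading mechanism; ``nst_assign_shift`` shifts the treatment
    log-odds for NST recipients.
    """

    n: int = 4000
    seed: int = 0
    k_true: int = 2
    subgroup_probs: tuple[float, ...] = (0.6, 0.4)
    subgroup_noise: float = 0.02
    # (shape, scale months) per subgroup, per arm [NSM, MRM]
    weibull: tuple = (
        ((1.3, 110.0), (1.3, 45.0)),   # subgroup 0: NSM strongly beneficial
        ((1.3, 45.0), (1.3, 110.0)),   # subgroup 1: MRM strongly beneficial
    )
    # proportional-hazard coefficients on standardized (age, tumor_size) and
    # raw ordinal n_stage
    hazard_age: float = 0.25
    hazard_size: float = 0.20
    hazard_nstage: float = 0.15
    # treatment assignment: logit P(MRM) = b0 + b·covariates
    assign_intercept: float = 0.2
    assign_age: float = 0.5
    assign_size: float = 0.4
    assign_nstage: float = 0.6
    assign_grade: float = 0.3
    nst_assign_shift: float = -0.3
    nst_hazard_mult: float = 1.3
    # censoring: administrative horizon plus independent exponential dropout
    horizon: float = 120.0
    censor_rate: float = 1.0 / 120.0
    bcss_fraction: float = 0.75

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def strong_heterogeneity_config(n: int = 4000, seed: int = 0) -> SimConfig:
    """The default two-subgroup scenario with opposite arm benefits."""
    return SimConfig(n=n, seed=seed)


@dataclass
class GroundTruth:
    """Per-patient generative truth for a synthetic cohort."""

    table: pd.DataFrame = field(repr=False)  # z, propensity, lp, per-arm weibull
    threshold: float = 0.10
    cap: float = 120.0

    def true_survival(self, i: int, arm: int, t) -> np.ndarray | float:
        """Closed-form S(t | x_i, arm) given patient i's latent subgroup."""
        if i not in self.table.index:
            raise KeyError(f"unknown patient index {i}")
        row = self.table.loc[i]
        shape = row[f"shape_arm{arm}"]
        scale = row[f"scale_arm{arm}"]
        lp = row[f"lp_arm{arm}"]
        t = np.asarray(t, float)
        return np.exp(-np.power(t / scale, shape) * np.exp(lp))

    def true_tar(self, i: int, arm: int) -> float:
        """First t with S(t) <= threshold, capped at ``cap`` months."""
        row = self.table.loc[i]
        shape = row[f"shape_arm{arm}"]
        scale = row[f"scale_arm{arm}"]
        lp = row[f"lp_arm{arm}"]
        t = scale * (-np.log(self.threshold) / np.exp(lp)) ** (1.0 / shape)
        return float(min(t, self.cap))

    def true_tar_ite(self, i: int) -> tuple[float, float, float]:
        """(TaR under MRM, TaR under NSM, ITE = TaR_MRM - TaR_NSM)."""
        tar_mrm = self.true_tar(i, 1)
        tar_nsm = self.true_tar(i, 0)
        return tar_mrm, tar_nsm, tar_mrm - tar_nsm

    @property
    def ite(self) -> np.ndarray:
        return self.table["ite"].to_numpy()

    @property
    def propensity(self) -> np.ndarray:
        return self.table["propensity"].to_numpy()

    @property
    def subgroup(self) -> np.ndarray:
        return self.table["z"].to_numpy()


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: SimConfig) -> tuple[CohortTable, GroundTruth]:
    """Draw a synthetic cohort and its generative ground truth.

    Reproducible given ``config.seed``; every source of randomness draws
    from a named child stream of the master seed.
    """
    if config.n < 10:
        raise ValueError("n must be >= 10 for a non-degenerate cohort")
    probs = np.asarray(config.subgroup_probs, float)
    if abs(probs.sum() - 1.0) > 1e-9 or (probs <= 0).any():
        raise ValueError("subgroup_probs must be a positive simplex vector")
    if len(probs) != config.k_true:
        raise ValueError("subgroup_probs length must equal k_true")

    ss = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(child) for name, child in
               zip(["covariates", "subgroup", "treatment", "event", "censoring", "cause"],
                   ss.spawn(6))}
    n = config.n
    rng = streams["covariates"]

    age = np.clip(rng.normal(56.0, 12.0, n), 22.0, 95.0)
    tumor_size = np.clip(rng.lognormal(np.log(26.0), 0.6, n), 1.0, 180.0)
    married = rng.binomial(1, 0.57, n)
    income_high = rng.binomial(1, 0.32, n)
    race = rng.choice(RACE_LEVELS, n, p=[0.76, 0.12, 0.12])
    grade = rng.choice(["I", "II", "III", "IV"], n, p=[0.12, 0.42, 0.455, 0.005])
    location = rng.choice(LOCATION_LEVELS, n,
                          p=[0.32, 0.09, 0.07, 0.04, 0.29, 0.01, 0.18])
    tnm = rng.choice(TNM_LEVELS, n, p=[0.17, 0.02, 0.20, 0.22, 0.21, 0.06, 0.10, 0.02])
    m_stage = np.where(tnm == "IV", "M1", "M0")
    iib_t3n0 = np.where(tnm == "IIB", rng.binomial(1, 0.1, n), 0)

    # T/N stages loosely consistent with the TNM group
    t_stage = np.empty(n, dtype=object)
    n_stage = np.empty(n, dtype=object)
    draw = rng.random((n, 2))
    for i, s in enumerate(tnm):
        if s in ("IA", "IB"):
            t_stage[i], n_stage[i] = "T1", "N0"
        elif s == "IIA":
            t_stage[i] = "T1" if draw[i, 0] < 0.4 else "T2"
            n_stage[i] = "N1" if t_stage[i] == "T1" else "N0"
        elif s == "IIB":
            if iib_t3n0[i]:
                t_stage[i], n_stage[i] = "T3", "N0"
            else:
                t_stage[i], n_stage[i] = "T2", "N1"
        elif s == "IIIA":
            t_stage[i] = "T3" if draw[i, 0] < 0.5 else "T2"
            n_stage[i] = "N2"
        elif s == "IIIB":
            t_stage[i], n_stage[i] = "T4", "N1" if draw[i, 0] < 0.5 else "N2"
        elif s == "IIIC":
            t_stage[i], n_stage[i] = ("T2" if draw[i, 0] < 0.5 else "T3"), "N3"
        else:  # IV
            t_stage[i] = ["T1", "T2", "T3", "T4"][int(draw[i, 0] * 4)]
            n_stage[i] = ["N0", "N1", "N2", "N3"][int(draw[i, 1] * 4)]
    n_ord = pd.Series(n_stage).map({"N0": 0, "N1": 1, "N2": 2, "N3": 3}).to_numpy(float)
    aln_positive = np.where(n_ord > 0, rng.binomial(1, 0.95, n), rng.binomial(1, 0.05, n))

    er_positive = rng.binomial(1, 0.78, n)
    pr_positive = np.where(er_positive == 1, rng.binomial(1, 0.82, n), rng.binomial(1, 0.15, n))
    her2_positive = rng.binomial(1, 0.21, n)
    grade_ord = pd.Series(grade).map({"I": 0, "II": 1, "III": 2, "IV": 3}).to_numpy(float)
    nst = streams["covariates"].binomial(1, _sigmoid(-1.5 + 0.5 * n_ord + 0.3 * grade_ord), n)

    age_z = (age - 56.0) / 12.0
    size_z = (np.log(tumor_size) - np.log(26.0)) / 0.6

    # latent subgroup: a biology score thresholded at the quantile implied by
    # subgroup_probs, then flipped with probability subgroup_noise
    score = (1.0 * er_positive + 0.8 * pr_positive - 0.9 * her2_positive
             - 0.5 * grade_ord - 0.3 * age_z)
    jitter = streams["subgroup"].normal(0, 1e-6, n)  # break exact ties deterministically
    cut = np.quantile(score + jitter, 1.0 - probs[0])
    z = (score + jitter < cut).astype(int)  # 1 = minority subgroup
    flip = streams["subgroup"].random(n) < config.subgroup_noise
    z = np.where(flip, 1 - z, z)

    # confounded treatment assignment
    logit = (config.assign_intercept + config.assign_age * age_z
             + config.assign_size * size_z + config.assign_nstage * n_ord
             + config.assign_grade * grade_ord + config.nst_assign_shift * nst)
    propensity = _sigmoid(logit)
    treatment = (streams["treatment"].random(n) < propensity).astype(int)

    # proportional-hazard linear predictor, shared across arms except the
    # NST-by-MRM interaction
    lp_base = (config.hazard_age * age_z + config.hazard_size * size_z
               + config.hazard_nstage * n_ord)
    lp_arm0 = lp_base.copy()
    lp_arm1 = lp_base + np.log(config.nst_hazard_mult) * nst

    weib = np.asarray(config.weibull, float)  # (k, 2, 2)
    if weib.shape != (config.k_true, 2, 2) or (weib <= 0).any():
        raise ValueError("weibull must be (k_true x 2 arms x (shape, scale)) positive")
    shape_arm0 = weib[z, 0, 0]
    scale_arm0 = weib[z, 0, 1]
    shape_arm1 = weib[z, 1, 0]
    scale_arm1 = weib[z, 1, 1]

    # factual event time: T = scale * (E / exp(lp))^(1/shape), E ~ Exp(1)
    E = streams["event"].exponential(1.0, n)
    shape_f = np.where(treatment == 1, shape_arm1, shape_arm0)
    scale_f = np.where(treatment == 1, scale_arm1, scale_arm0)
    lp_f = np.where(treatment == 1, lp_arm1, lp_arm0)
    t_event = scale_f * (E / np.exp(lp_f)) ** (1.0 / shape_f)

    c_drop = streams["censoring"].exponential(1.0 / config.censor_rate, n)
    c_time = np.minimum(config.horizon, c_drop)
    followup = np.round(np.minimum(t_event, c_time), 1)
    followup = np.maximum(followup, 0.1)
    event_overall = (t_event <= c_time).astype(int)
    event_bcss = event_overall * streams["cause"].binomial(1, config.bcss_fraction, n)

    df = pd.DataFrame({
        "patient_id": [f"P{i:06d}" for i in range(n)],
        "age": np.round(age, 1),
        "tumor_size": np.round(tumor_size, 1),
        "married": married, "race": race, "income_high": income_high,
        "grade": grade, "location": location,
        "t_stage": t_stage, "n_stage": n_stage, "m_stage": m_stage,
        "tnm_stage": tnm, "iib_t3n0": iib_t3n0,
        "aln_positive": aln_positive, "er_positive": er_positive,
        "pr_positive": pr_positive, "her2_positive": her2_positive,
        "nst": nst, "treatment": treatment,
        "followup_months": followup,
        "event_overall": event_overall, "event_bcss": event_bcss,
    })
    cohort = CohortTable(df)

    gt = pd.DataFrame({
        "z": z, "propensity": propensity,
        "shape_arm0": shape_arm0, "scale_arm0": scale_arm0, "lp_arm0": lp_arm0,
        "shape_arm1": shape_arm1, "scale_arm1": scale_arm1, "lp_arm1": lp_arm1,
    })
    threshold, cap = 0.10, 120.0
    for arm in (0, 1):
        t = (gt[f"scale_arm{arm}"]
             * (-np.log(threshold) / np.exp(gt[f"lp_arm{arm}"])) ** (1.0 / gt[f"shape_arm{arm}"]))
        gt[f"tar_arm{arm}"] = np.minimum(t, cap)
    gt["ite"] = gt["tar_arm1"] - gt["tar_arm0"]
    return cohort, GroundTruth(gt, threshold=threshold, cap=cap)
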