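"""Patient-level cohort container, CSV I/O, stage grouping and descriptive summaries.

The cohort is a flat table, one row per patient, holding demographics,
tumor/receptor/stage covariates, the surgical arm actually received
(``treatment``: 0 = nipple-sparing mastectomy, NSM; 1 = modified radical
mastectomy, MRM), follow-up in months and right-censoring indicators for
overall and breast-cancer-specific survival.  All downstream estimators in
this package consume this table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COLUMNS",
    "CATEGORY_LEVELS",
    "CohortTable",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "derive_stage_group",
    "stage_groups",
    "summarize_cohort",
    "proportion_ci",
    "build_design_matrix",
]

GRADE_LEVELS = ["I", "II", "III", "IV"]
LOCATION_LEVELS = [
    "upper_outer",
    "upper_inner",
    "lower_outer",
    "lower_inner",
    "central_overlapping",
    "nipple_axillary",
    "other",
]
T_LEVELS = ["T1", "T2", "T3", "T4"]
N_LEVELS = ["N0", "N1", "N2", "N3"]
M_LEVELS = ["M0", "M1"]
TNM_LEVELS = ["IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IIIC", "IV"]
RACE_LEVELS = ["white", "black", "other"]

CATEGORY_LEVELS: dict[str, list[str]] = {
    "race": RACE_LEVELS,
    "grade": GRADE_LEVELS,
    "location": LOCATION_LEVELS,
    "t_stage": T_LEVELS,
    "n_stage": N_LEVELS,
    "m_stage": M_LEVELS,
    "tnm_stage": TNM_LEVELS,
}

FLAG_COLUMNS = [
    "married",
    "income_high",
    "iib_t3n0",
    "aln_positive",
    "er_positive",
    "pr_positive",
    "her2_positive",
    "nst",
    "treatment",
    "event_overall",
    "event_bcss",
]

NUMERIC_COLUMNS = ["age", "tumor_size", "followup_months"]

#: canonical column order of the cohort CSV
COLUMNS = (
    ["patient_id", "age", "tumor_size", "married", "race", "income_high",
     "grade", "location", "t_stage", "n_stage", "m_stage", "tnm_stage"]
    + ["iib_t3n0", "aln_positive", "er_positive", "pr_positive",
       "her2_positive", "nst", "treatment", "followup_months",
       "event_overall", "event_bcss"]
)

NSM, MRM = 0, 1


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the schema or its invariants."""


def _check_levels(df: pd.DataFrame, errors: list[str]) -> None:
    for col, levels in CATEGORY_LEVELS.items():
        bad = ~df[col].isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            errors.append(
                f"column {col!r}, row {row}: unknown level {df[col].iloc[row]!r} "
                f"(allowed: {levels})"
            )


@dataclass
class CohortTable:
    """Validated patient-level survival cohort.

    Wraps a :class:`pandas.DataFrame` whose columns follow the package data
    dictionary (see :data:`COLUMNS`).  Invariants enforced at construction:

    * ``followup_months > 0``
    * a breast-cancer-specific death implies an overall death
    * ``m_stage == "M1"`` exactly for TNM stage IV rows
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        errors: list[str] = []
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise CohortValidationError(f"missing required columns: {missing}")
        df = df[COLUMNS].reset_index(drop=True).copy()
        for col in NUMERIC_COLUMNS:
            df[col] = pd.to_numeric(df[col])
        for col in FLAG_COLUMNS:
            df[col] = pd.to_numeric(df[col]).astype(int)
            if not df[col].isin([0, 1]).all():
                errors.append(f"column {col!r}: values outside {{0,1}}")
        df["patient_id"] = df["patient_id"].astype(str)
        _check_levels(df, errors)
        if not errors:
            bad = df["followup_months"] <= 0
            if bad.any():
                errors.append(
                    f"followup_months must be positive (rows {list(np.flatnonzero(bad))[:5]})"
                )
            bad = (df["event_bcss"] == 1) & (df["event_overall"] == 0)
            if bad.any():
                errors.append(
                    "event_bcss=1 requires event_overall=1 "
                    f"(rows {list(np.flatnonzero(bad))[:5]})"
                )
            m1 = df["m_stage"] == "M1"
            iv = df["tnm_stage"] == "IV"
            bad = m1 != iv
            if bad.any():
                errors.append(
                    "m_stage M1 must coincide with tnm_stage IV "
                    f"(rows {list(np.flatnonzero(bad))[:5]})"
                )
        if errors:
            raise CohortValidationError("; ".join(errors))
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def treatment(self) -> np.ndarray:
        return self.df["treatment"].to_numpy()

    def survival_arrays(self, endpoint: str = "overall") -> tuple[np.ndarray, np.ndarray]:
        """Return (time, event) arrays for ``endpoint`` in {'overall', 'bcss'}."""
        if endpoint not in ("overall", "bcss"):
            raise ValueError(f"unknown endpoint {endpoint!r}")
        t = self.df["followup_months"].to_numpy(float)
        e = self.df[f"event_{endpoint}"].to_numpy(int)
        return t, e

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self.df.loc[np.asarray(mask)].reset_index(drop=True))


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV (UTF-8, header row per the data dictionary)."""
    df = pd.read_csv(path)
    if df.isna().any().any():
        cols = list(df.columns[df.isna().any()])
        raise CohortValidationError(f"missing values in columns {cols}")
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort to CSV; ``read_cohort`` round-trips it exactly."""
    cohort.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stage groups

EBC, LABC, MBC = "EBC", "LABC", "MBC"

_LABC_STAGES = {"IIIA", "IIIB", "IIIC"}
_EBC_STAGES = {"IA", "IB", "IIA"}


def derive_stage_group(tnm_stage: str, iib_t3n0: int = 0, iib_policy: str = EBC) -> str:
    """Map TNM stage to the coarse clinical stage group.

    MBC is stage IV (metastatic).  LABC spans stage IIB restricted to T3N0
    through IIIA-IIIC (large tumors and/or extensive nodal involvement); EBC
    covers IA, IB and IIA.  Residual IIB (T2N1) falls between the two printed
    definitions; ``iib_policy`` routes it (default ``"EBC"``).
    """
    if tnm_stage == "IV":
        return MBC
    if tnm_stage in _LABC_STAGES:
        return LABC
    if tnm_stage == "IIB":
        if iib_t3n0:
            return LABC
        if iib_policy not in (EBC, LABC):
            raise ValueError(f"iib_policy must be 'EBC' or 'LABC', got {iib_policy!r}")
        return iib_policy
    if tnm_stage in _EBC_STAGES:
        return EBC
    raise ValueError(f"unknown tnm_stage {tnm_stage!r}")


def stage_groups(cohort: CohortTable, iib_policy: str = EBC) -> pd.Series:
    """Vectorized :func:`derive_stage_group` over a cohort."""
    df = cohort.df
    return pd.Series(
        [derive_stage_group(s, f, iib_policy)
         for s, f in zip(df["tnm_stage"], df["iib_t3n0"])],
        index=df.index, name="stage_group",
    )


# ---------------------------------------------------------------------------
# descriptive summaries


def _round1(x: float) -> float:
    # half-up at 1 decimal, matching clinical-table rounding conventions
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def proportion_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float, float]:
    """Wald normal-approximation CI for a binomial proportion.

    Returns ``(proportion, lower, upper)`` on the [0, 1] scale, interval
    truncated to [0, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    p = k / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(p * (1 - p) / n)
    return p, max(0.0, p - half), min(1.0, p + half)


def _mortality_block(df: pd.DataFrame, event_col: str) -> dict:
    n = len(df)
    k = int(df[event_col].sum())
    p, lo, hi = proportion_ci(k, n)
    return {
        "deaths": k,
        "n": n,
        "percent": _round1(100 * p),
        "ci_low_percent": _round1(100 * lo),
        "ci_high_percent": _round1(100 * hi),
    }


def _categorical_block(df: pd.DataFrame, col: str, levels: list) -> dict:
    n = len(df)
    out = {}
    for lev in levels:
        k = int((df[col] == lev).sum())
        out[str(lev)] = {"count": k, "percent": _round1(100 * k / n) if n else 0.0}
    return out


def summarize_cohort(cohort: CohortTable) -> dict:
    """Per-arm and pooled descriptive summary: counts, percentages
    (1 decimal, half-up) and Wald 95% CIs for the mortality rates."""
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    df = cohort.df
    groups = {"pooled": df, "nsm": df[df["treatment"] == NSM], "mrm": df[df["treatment"] == MRM]}
    summary: dict = {}
    for name, g in groups.items():
        if len(g) == 0:
            summary[name] = {"n": 0}
            continue
        block: dict = {"n": len(g), "percent_of_total": _round1(100 * len(g) / len(df))}
        block["age_mean"] = float(g["age"].mean())
        block["age_sd"] = float(g["age"].std(ddof=1)) if len(g) > 1 else 0.0
        block["tumor_size_mean"] = float(g["tumor_size"].mean())
        block["followup_median"] = float(g["followup_months"].median())
        for col, levels in CATEGORY_LEVELS.items():
            block[col] = _categorical_block(g, col, levels)
        for col in ["married", "income_high", "aln_positive", "er_positive",
                    "pr_positive", "her2_positive", "nst"]:
            k = int(g[col].sum())
            block[col] = {"count": k, "percent": _round1(100 * k / len(g))}
        block["mortality_overall"] = _mortality_block(g, "event_overall")
        block["mortality_bcss"] = _mortality_block(g, "event_bcss")
        summary[name] = block
    return summary


def summary_to_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)


# ---------------------------------------------------------------------------
# model design matrix


#: default modelling covariates (prognostic + treatment-decision variables)
DEFAULT_COVARIATES = [
    "age", "tumor_size", "married", "income_high", "race", "grade",
    "t_stage", "n_stage", "m_stage", "aln_positive",
    "er_positive", "pr_positive", "her2_positive", "nst",
]

_ORDINAL = {
    "grade": GRADE_LEVELS,
    "t_stage": T_LEVELS,
    "n_stage": N_LEVELS,
    "m_stage": M_LEVELS,
    "tnm_stage": TNM_LEVELS,
}


def build_design_matrix(
    cohort: CohortTable,
    covariates: list[str] | None = None,
    standardize: bool = True,
    stats_from: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, list[str], tuple[np.ndarray, np.ndarray]]:
    """Encode cohort covariates as a numeric matrix.

    Ordinal stage variables are integer-coded, ``race``/``location`` one-hot
    encoded (first level dropped), flags passed through.  Continuous columns
    are z-scored with the training-set statistics when ``standardize`` —
    pass ``stats_from=(mean, scale)`` to reuse a fitted scaler.

    Returns ``(X, column_names, (mean, scale))``.
    """
    covariates = list(covariates or DEFAULT_COVARIATES)
    df = cohort.df
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov in _ORDINAL:
            levels = _ORDINAL[cov]
            cols.append(df[cov].map({l: i for i, l in enumerate(levels)}).to_numpy(float))
            names.append(cov)
        elif cov in ("race", "location"):
            levels = CATEGORY_LEVELS[cov]
            for lev in levels[1:]:
                cols.append((df[cov] == lev).to_numpy(float))
                names.append(f"{cov}_{lev}")
        elif cov in NUMERIC_COLUMNS or cov in FLAG_COLUMNS:
            cols.append(df[cov].to_numpy(float))
            names.append(cov)
        else:
            raise KeyError(f"unknown covariate {cov!r}")
    X = np.column_stack(cols)
    if standardize:
        if stats_from is None:
            mean = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
        else:
            mean, scale = stats_from
        X = (X - mean) / scale
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    return X, names, (mean, scale)
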