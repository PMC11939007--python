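import numpy as np
import pytest

from bimesurv.cohort import CohortTable
from bimesurv.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest confounded cohort with heterogeneous effects."""
    cohort, gt = generate_cohort(SimConfig(n=600, seed=7))
    return cohort, gt


@pytest.fixture(scope="session")
def null_config():
    """Arms identical in both subgroups: no treatment effect anywhere."""
    w = ((1.2, 70.0), (1.2, 70.0))
    return SimConfig(n=1500, seed=11, weibull=(w, w), nst_hazard_mult=1.0)


@pytest.fixture()
def tiny_table():
    """Five handwritten valid patients."""
    import pandas as pd

    rows = []
    for i, (tnm, m, iib) in enumerate(
        [("IA", "M0", 0), ("IIB", "M0", 1), ("IIIA", "M0", 0),
         ("IV", "M1", 0), ("IIA", "M0", 0)]
    ):
        rows.append({
            "patient_id": f"P{i}", "age": 50.0 + i, "tumor_size": 20.0 + i,
            "married": i % 2, "race": "white", "income_high": 0,
            "grade": "II", "location": "upper_outer", "t_stage": "T2",
            "n_stage": "N1", "m_stage": m, "tnm_stage": tnm, "iib_t3n0": iib,
            "aln_positive": 1, "er_positive": 1, "pr_positive": 0,
            "her2_positive": 0, "nst": i % 2, "treatment": i % 2,
            "followup_months": 12.0 + i, "event_overall": int(i in (1, 3)),
            "event_bcss": int(i == 3),
        })
    return CohortTable(pd.DataFrame(rows))
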