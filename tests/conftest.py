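import numpy as np
import pandas as pd
import pytest

from pairsurv.cohort import Cohort
from pairsurv.synthetic import SimConfig, generate_cohort


def random_survival(rng, n, censor_frac=0.3, scale=100.0):
    """Random (times, status) fixture with mixed censoring."""
    times = rng.exponential(scale, n) + 1e-3
    status = rng.random(n) >= censor_frac
    if not status.any():
        status[rng.integers(n)] = True
    return times, status


def manual_cohort(expr_rows, clinical_rows, classes=None):
    """Build a Cohort from plain dicts/lists for hand-crafted cases.

    ``expr_rows``: {gene: {sample: value}}; ``clinical_rows``: list of
    (patient_id, time_days, status).
    """
    expr = pd.DataFrame(expr_rows).T
    clin = pd.DataFrame(clinical_rows,
                        columns=["patient_id", "time_days", "status"])
    sc = pd.Series(classes) if classes is not None else None
    return Cohort(expr, clin, sc)


@pytest.fixture(scope="session")
def null_cohort():
    """400 patients, 10 genes, no planted effects, some normals."""
    cfg = SimConfig(n_patients=400, n_genes=10, n_normal=40,
                    baseline_hazard=3.2e-4, censor_hazard=1e-4,
                    admin_cutoff=3650.0, seed=42)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def interaction_cohort():
    """1200 patients; genes 0 and 1 carry a planted pairwise interaction."""
    cfg = SimConfig(n_patients=1200, n_genes=6, baseline_hazard=3.2e-4,
                    censor_hazard=1e-4, admin_cutoff=3650.0,
                    interaction_effects={(0, 1): 0.8}, seed=11)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth
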