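import numpy as np
import pandas as pd
import pytest

from frailtraj.frailty_index import DeficitRegistry
from frailtraj.synthetic_cohort import CohortSpec, generate_cohort

# events/total per risk category (low-to-moderate, high, very high) as
# printed for the two cohorts
ELSA_COUNTS = [(89, 2196), (245, 2153), (149, 485)]
HRS_COUNTS = [(63, 2008), (198, 2739), (595, 3068)]
CATEGORY_LABELS = ["a_low_to_moderate", "b_high", "c_very_high"]


@pytest.fixture(scope="session")
def registry():
    return DeficitRegistry.default()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    spec = CohortSpec(n_participants=400, seed=7)
    cohort, truth = generate_cohort(spec)
    return cohort, truth


def expand_counts(counts):
    """Individual-level binary rows from (events, total) strata."""
    rows = []
    for j, (events, total) in enumerate(counts):
        for _ in range(events):
            rows.append({"outcome": 1.0, "exposure": CATEGORY_LABELS[j]})
        for _ in range(total - events):
            rows.append({"outcome": 0.0, "exposure": CATEGORY_LABELS[j]})
    return pd.DataFrame(rows)
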