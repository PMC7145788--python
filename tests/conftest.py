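import logging

import numpy as np
import pandas as pd
import pytest

from immunogem import synthetic_data as syn

logging.getLogger("cobra").setLevel(logging.CRITICAL)


@pytest.fixture(scope="session")
def toy_model():
    return syn.build_toy_sphingolipid_model()


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort with the default planted effects."""
    design = syn.CohortDesign(seed=7)
    values, smeta, fmeta, registry = syn.simulate_metabolomics(design, seed=7)
    return values, smeta, fmeta, registry


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted effects at all (null data)."""
    design = syn.CohortDesign(seed=11, missingness_rate=0.0)
    values, smeta, fmeta, registry = syn.simulate_metabolomics(
        design, effects=[], seed=11)
    return values, smeta, fmeta


def make_sample_meta(n_a, n_b, seed=0, group_a="PT1D", group_b="CTRL"):
    """Minimal two-group single-age sample metadata for contrast tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, n in ((group_a, n_a), (group_b, n_b)):
        for i in range(n):
            rows.append({"sample": f"{g}_{i}", "subject": f"{g}_{i}",
                         "group": g, "sex": "F" if rng.random() < 0.5 else "M",
                         "age_months": 24.0, "nominal_age": 24,
                         "seroconversion_age": np.nan})
    return pd.DataFrame(rows).set_index("sample")
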