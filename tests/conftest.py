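import numpy as np
import pandas as pd
import pytest

from neurotraj.model import FixedEffects
from neurotraj.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_fx() -> FixedEffects:
    return FixedEffects(t0=74.0, p0=0.5, v0=0.05,
                        sigma_eps=0.02, sigma_tau=7.0, sigma_xi=0.5)


@pytest.fixture(scope="session")
def small_cohort():
    """40 subjects, 2 regions, no covariate effects; shared by fast tests."""
    cfg = CohortConfig(n_subjects=40, n_regions=2, seed=7,
                       covariate_effects={})
    visits, covariates, truth = generate_cohort(cfg)
    return cfg, visits, covariates, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_visits(values_by_region: dict, subject_ids, ages,
                field=1.5, group="AD", is_duplicate=0) -> pd.DataFrame:
    """Hand-rolled visits table for worked examples."""
    n = len(subject_ids)
    base = {
        "subject_id": list(subject_ids),
        "age_years": list(ages),
        "group": [group] * n if isinstance(group, str) else list(group),
        "field_strength": [field] * n if np.isscalar(field) else list(field),
        "is_duplicate": [is_duplicate] * n if np.isscalar(is_duplicate)
        else list(is_duplicate),
    }
    base.update(values_by_region)
    return pd.DataFrame(base)
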