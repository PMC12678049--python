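import numpy as np
import pandas as pd
import pytest

from metaboaging.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort shared by read-only tests."""
    cfg = SimulationConfig(n_participants=1500, seed=42, n_metabolites=30,
                           n_causal_metabolites=8, n_proteins=60)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def assert_cohorts_equal(a, b):
    pd.testing.assert_frame_equal(a.covariates, b.covariates)
    pd.testing.assert_frame_equal(a.metabolites, b.metabolites)
    pd.testing.assert_frame_equal(a.proteins, b.proteins)
    assert set(a.outcomes) == set(b.outcomes)
    for ep in a.outcomes:
        pd.testing.assert_frame_equal(a.outcomes[ep], b.outcomes[ep])
    pd.testing.assert_frame_equal(a.frailty_items, b.frailty_items)
    pd.testing.assert_series_equal(a.telomere_raw, b.telomere_raw)
    pd.testing.assert_frame_equal(a.health_flags, b.health_flags)
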