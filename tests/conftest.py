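import numpy as np
import pandas as pd
import pytest

from polypen.simulate import (
    SimConfig,
    assign_disease_cross_sectional,
    assign_onset_ages,
    generate_population,
)


@pytest.fixture(scope="session")
def cohort():
    """Mid-size cohort with enough carriers for stratified estimates."""
    cfg = SimConfig(
        n_individuals=12_000,
        n_score_variants=60,
        carrier_frequency=0.02,
        baseline_prevalence=0.10,
        seed=11,
    )
    c = generate_population(cfg)
    c = assign_disease_cross_sectional(c)
    c = assign_onset_ages(c)
    return c


@pytest.fixture()
def toy_weights():
    return pd.DataFrame(
        {
            "variant_id": ["v1", "v2", "v3"],
            "chromosome": ["1", "1", "2"],
            "position": [100, 200, 300],
            "effect_allele": ["A", "C", "G"],
            "weight": [0.1, -0.2, 0.3],
        }
    )


@pytest.fixture()
def toy_dosages():
    return pd.DataFrame(
        [[0, 1, 2], [2, 0, 1]],
        index=pd.Index(["s1", "s2"], name="individual_id"),
        columns=["v1", "v2", "v3"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
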