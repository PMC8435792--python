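import numpy as np
import pytest

from metd.datagen import (CohortConfig, ElicitationConfig, GroupConfig,
                          generate_cohort, generate_elicitation)
from metd.models import McmcConfig


@pytest.fixture(scope="session")
def survey_frame():
    """Moment-matched synthetic survey at the published summary (n=137)."""
    return generate_elicitation(ElicitationConfig(moment_match=True, seed=11))


@pytest.fixture(scope="session")
def two_arm_cohort():
    """Two clearly separated arms (true Total changes 10 vs 30 kg)."""
    cfg = CohortConfig(study="s3", groups=(
        GroupConfig(label="MAX", protocol="MAX", n=50,
                    true_change={"SQ": 3.0, "BP": 3.0, "DL": 4.0},
                    change_sd={"SQ": 1.0, "BP": 1.0, "DL": 1.0}),
        GroupConfig(label="MAX_BOFF", protocol="MAX_BOFF", n=50,
                    true_change={"SQ": 10.0, "BP": 10.0, "DL": 10.0},
                    change_sd={"SQ": 1.0, "BP": 1.0, "DL": 1.0})),
        seed=21)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def fast_mcmc():
    """Short but convergent sampler settings for test-time fits."""
    return McmcConfig(chains=4, warmup=300, draws=400, seed=5)


@pytest.fixture(scope="session")
def meta_mcmc():
    """Longer chains for the nested meta-model, whose study-level variance
    is weakly identified and mixes more slowly."""
    return McmcConfig(chains=4, warmup=500, draws=1000, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
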