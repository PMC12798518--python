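import numpy as np
import pytest

from linkprev import CountData, McmcSettings, elicit_informative, mcmc_sample

COMPLETERS = CountData(n=549, k=311, source_label="self-report completers")
GENOA_ADMIN = CountData(n=1061, k=632, source_label="cohort A admin")
POST_ADMIN = CountData(n=2369, k=1394, source_label="cohort B admin")
MERGED_ADMIN = CountData(n=3430, k=2026, source_label="merged admin")


@pytest.fixture(scope="session")
def primary_chains():
    """Primary-analysis sampler run at the reference settings
    (4 chains x 20,000 iterations, warm-up 500, thin 5, seed 123)."""
    prior = elicit_informative(GENOA_ADMIN)
    return mcmc_sample(prior, COMPLETERS, McmcSettings(master_seed=123))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
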