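import warnings

import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def lexicon():
    from chronofood.nova_annotation import load_lexicon

    return load_lexicon()


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-participant, 10-day cohort reused by read-only tests."""
    from chronofood.synthetic_data import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_participants=20, days=10, seed=11, intervention_days=10))
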