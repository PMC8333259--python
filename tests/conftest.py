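import numpy as np
import pandas as pd
import pytest

from sbpjoint import SyntheticConfig, generate_cohort, recovery_config


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration cohort (318 subjects), shared across tests."""
    return generate_cohort(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fast fitting tests."""
    return generate_cohort(recovery_config(seed=7).replace(n_subjects=80))


@pytest.fixture(scope="session")
def recovery_cohort():
    """Reduced-design cohort at the study's size (318 subjects)."""
    return generate_cohort(recovery_config(seed=3))


@pytest.fixture()
def toy_survival():
    """Four subjects, times 1, 2 (censored), 3, 4: hand-computable KM."""
    return pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 0, 1, 1]})
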