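import numpy as np
import pytest

import urimir as u


@pytest.fixture(scope="session")
def default_spec():
    return u.default_paper_spec(seed=11)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    return u.generate_cohort(default_spec)


@pytest.fixture(scope="session")
def analysis(default_cohort):
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return u.analyze_cohort(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231109)
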