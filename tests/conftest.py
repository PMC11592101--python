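import numpy as np
import pytest

from methylstab import SyntheticSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_cohorts=2, n_subjects=20, n_probes=400, seed=7)


@pytest.fixture(scope="session")
def small_cohorts(small_spec):
    """Two generated cohorts with shared truth, session-cached."""
    out = [generate_cohort(small_spec, i) for i in range(small_spec.n_cohorts)]
    cohorts = [(b, d) for b, d, _ in out]
    truth = out[0][2]
    return cohorts, truth


@pytest.fixture(scope="session")
def small_study_dir(tmp_path_factory, small_spec):
    from methylstab import generate_study

    out = tmp_path_factory.mktemp("study")
    generate_study(small_spec, out)
    return out
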