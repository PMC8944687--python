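import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

import herdspan as hs
from herdspan import datasets


@pytest.fixture(scope="session")
def tosno_cohort():
    return datasets.tosno_cohort()


@pytest.fixture(scope="session")
def tosno_disposal(tosno_cohort):
    return hs.compute_disposal_series(tosno_cohort)


@pytest.fixture(scope="session")
def model_pops():
    return datasets.model_populations()


@pytest.fixture
def cohort_file(tmp_path, tosno_cohort):
    path = tmp_path / "cohort.csv"
    hs.io.write_cohort(path, tosno_cohort)
    return path
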