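import pytest

from allotrace import RepertoireSample
from allotrace.simulate import SimulationConfig, simulate_cohort


def make_sample(counts, sample_id="s", **kw):
    return RepertoireSample.from_counts(sample_id, counts, **kw)


@pytest.fixture
def mk_sample():
    return make_sample


@pytest.fixture(scope="session")
def small_config():
    # scaled-down cohort for fast structural tests; study-condition defaults
    # are exercised in the acceptance tests
    return SimulationConfig(
        n_subjects=4,
        seed=7,
        n_clones=2000,
        depth_pbmc=20_000,
        depth_mlr=8_000,
        depth_biopsy=1_500,
        depth_urine=400,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def rejection_subject(small_cohort):
    subj = next(s for s in small_cohort if s.biopsy_status == "acute_rejection")
    return subj


@pytest.fixture(scope="session")
def stable_subject(small_cohort):
    return next(s for s in small_cohort if s.biopsy_status == "stable")
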