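import numpy as np
import pytest

from tasd.preprocessing import preprocess_record
from tasd.synthetic_data import SynthConfig, simulate_cohort, simulate_subject


@pytest.fixture(scope="session")
def small_cfg():
    """Three short subjects: enough windows to exercise every stage quickly."""
    return SynthConfig(
        n_subjects=3,
        schedule=((1, 120.0), (2, 120.0), (3, 120.0)),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def preprocessed_cohort(small_cohort):
    records, truths = small_cohort
    return [preprocess_record(r) for r in records], truths


@pytest.fixture(scope="session")
def one_subject():
    cfg = SynthConfig(seed=3, schedule=((1, 200.0), (2, 200.0)))
    rec, truth = simulate_subject(cfg, 0)
    return preprocess_record(rec), truth
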