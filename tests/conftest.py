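import numpy as np
import pytest

from tractstrata.datamodel import ConnectomeTriplet
from tractstrata.pipeline import cohort_from_synthetic
from tractstrata.synthetic import SyntheticCohortConfig, generate_cohort, generate_followup


def make_triplet(subject_id="s0", n=6, rng=None, density=0.7):
    """Random small valid triplet for unit tests."""
    rng = rng or np.random.default_rng(0)
    iu = np.triu_indices(n, 1)
    exist = rng.random(iu[0].size) < density
    fn = np.where(exist, rng.integers(1, 20, iu[0].size), 0)
    exist = fn > 0
    length = np.where(exist, rng.uniform(5, 120, iu[0].size), 0.0)
    fa = np.where(exist, rng.uniform(0.1, 0.9, iu[0].size), 0.0)
    mats = []
    for v in (length, fn.astype(float), fa):
        m = np.zeros((n, n))
        m[iu] = v
        mats.append(m + m.T)
    labels = tuple(f"r{i}" for i in range(n))
    return ConnectomeTriplet(subject_id, labels, *mats).validate()


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny synthetic cohort with follow-up, reused across tests."""
    cfg = SyntheticCohortConfig(
        n_hc=6, n_rrms=6, n_nmosd=6, n_nodes=60, seed=11,
        n_followup_rrms=4, n_followup_nmosd=4,
    )
    return generate_followup(generate_cohort(cfg))


@pytest.fixture(scope="session")
def small_pipeline_cohort(small_cohort):
    return cohort_from_synthetic(small_cohort)
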