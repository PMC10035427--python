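import numpy as np
import pytest

from bfngcn import CohortSpec, TimeSeriesMatrix, block_pairs, sample_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ts():
    """A fixed random 4-ROI, 20-timepoint subject."""
    r = np.random.default_rng(7)
    return TimeSeriesMatrix(values=r.standard_normal((4, 20)), subject_id="toy")


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects, 8 ROIs, strong block effect — enough for end-to-end tests."""
    spec = CohortSpec(
        n_rois=8,
        n_timepoints=60,
        n_subjects_per_group=6,
        effect_block=block_pairs(range(4)),
        effect_delta=0.5,
        base_correlation=0.2,
        noise_sd=0.1,
        seed=42,
    )
    c = sample_cohort(spec)
    return list(zip(c.subjects, c.labels))
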