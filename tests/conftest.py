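import numpy as np
import pytest

import aromamap as am


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def standard_timeline():
    return am.SessionTimeline.standard(am.AROMAS, "p000", "male", "20s")


@pytest.fixture(scope="session")
def null_session(standard_timeline):
    """One full session with no stimulus effects."""
    eeg, ppg, tl = am.generate_session(standard_timeline, am.EffectSpec.null(), seed=77)
    return eeg, ppg, tl


@pytest.fixture(scope="session")
def small_cohort_results():
    """A 4-participant cohort (one per group) with illustrative effects,
    run through extraction once and shared across tests."""
    sizes = {k: 1 for k in am.synthetic.GENDER_BANDS}
    cohort = am.generate_cohort(sizes, am.EffectSpec.illustrative(), seed=404)
    summaries, resting = am.extract_cohort(cohort.iter_sessions())
    return cohort, summaries, resting
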