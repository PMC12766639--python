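import pytest

from somnolstm import simulate_cohort, simulate_hypnogram, simulate_night
from somnolstm.epochs import align_streams
from somnolstm.features import extract_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six short garmin nights; enough for grouped CV plumbing tests."""
    return simulate_cohort(
        6, night_len_epochs=60, device_profiles=("garmin",), seed=7
    )


@pytest.fixture(scope="session")
def small_datasets(small_cohort):
    return extract_cohort(small_cohort)


@pytest.fixture(scope="session")
def one_night():
    """One 40-epoch apple (50 Hz) night with its aligned representation."""
    hyp = simulate_hypnogram(40, seed=21, participant_id="night0")
    rec, hr, events = simulate_night(hyp, "apple", seed=22)
    aligned = align_streams(rec, hr, hyp)
    return {"hyp": hyp, "rec": rec, "hr": hr, "events": events, "aligned": aligned}
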