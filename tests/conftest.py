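import numpy as np
import pytest

from pvligt import (
    PayoffSchedule,
    TrialRecord,
    TrialSequence,
    build_default_schedule,
    draw_outcome,
)


@pytest.fixture(scope="session")
def schedule() -> PayoffSchedule:
    return build_default_schedule()


def make_sequence(decks, schedule, subject_id="s1", block_size=20) -> TrialSequence:
    """Build a TrialSequence from a deck-label string/list, realising outcomes
    from the schedule with per-deck draw positions advancing independently."""
    positions = {d: 0 for d in "ABCD"}
    records = []
    for t, d in enumerate(decks, start=1):
        positions[d] += 1
        win, loss = draw_outcome(schedule, d, positions[d])
        records.append(TrialRecord(trial=t, deck=d, win=win, loss=loss))
    return TrialSequence(subject_id=subject_id, records=records, block_size=block_size)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
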