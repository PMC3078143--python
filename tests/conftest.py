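import numpy as np
import pytest

from qtvar import BeatIntervalSeries, SubjectRecord


def make_series(rr, qt=None, annotation=None):
    """Build a series from plain lists; QT defaults to 0.4*RR."""
    rr = np.asarray(rr, dtype=float)
    qt = 0.4 * rr if qt is None else np.asarray(qt, dtype=float)
    ann = np.full(len(rr), "normal") if annotation is None else np.asarray(annotation)
    return BeatIntervalSeries(rr, qt, ann)


def make_record(rr, qt=None, annotation=None, subject_id="S001",
                group="control", session="rest"):
    return SubjectRecord(subject_id, group, session, make_series(rr, qt, annotation))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_record(rng):
    """40 physiological beats: RR ~1000 ms, QT ~400 ms, all normal."""
    rr = 1000 + rng.normal(0, 30, size=40)
    qt = 400 + rng.normal(0, 5, size=40)
    return make_record(rr, qt)
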