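import pandas as pd
import pytest

from dyadom.events_io import Ethogram, EventLog
from dyadom.synthetic_data import SyntheticConfig, simulate_dyad


@pytest.fixture(scope="session")
def eth():
    return Ethogram.default()


def make_log(rows, session_length=1200.0):
    return EventLog(
        pd.DataFrame(rows, columns=["dyad_id", "day", "subject_id", "behavior",
                                    "onset_s", "offset_s"]),
        session_length=session_length,
    )


@pytest.fixture()
def tiny_log():
    rows = [
        ("d1", 1, "m1", "lunge", 10.0, 11.0),
        ("d1", 1, "m2", "flee", 11.5, 12.0),
        ("d1", 1, "m1", "sniff-head", 50.0, 55.0),
        ("d1", 1, "m2", "idle", 60.0, 100.0),
        ("d1", 2, "m1", "bite", 5.0, 5.5),
        ("d1", 2, "m2", "freeze", 6.0, 9.0),
    ]
    return make_log(rows)


@pytest.fixture(scope="session")
def synth_dyad():
    cfg = SyntheticConfig()
    log, truth = simulate_dyad(cfg, "A", 1)
    return cfg, log, truth


def random_log(rng, n_rows=30, n_days=2, session_length=1200.0):
    eth = Ethogram.default()
    behaviors = sorted(eth.behaviors)
    rows = []
    for _ in range(n_rows):
        onset = rng.uniform(0, session_length - 10)
        rows.append(
            (
                "d" + str(rng.integers(2)),
                int(rng.integers(1, n_days + 1)),
                "m" + str(rng.integers(2)),
                behaviors[rng.integers(len(behaviors))],
                round(onset, 3),
                round(onset + rng.uniform(0, 10), 3),
            )
        )
    return make_log(rows, session_length=session_length)
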