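import numpy as np
import pytest

import equigait as eg


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny 3-horse cohort (60 s sessions) for structural tests."""
    return eg.simulate_cohort(eg.CohortConfig(n_horses=3, session_length_s=60, seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """The default study cohort: 5 horses x 4 locations x 600 s @ 50 Hz."""
    return eg.simulate_cohort(eg.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def knee_windows(default_cohort):
    """Scaled pure windows (4 s @ 25 Hz, knee) split by the fixed validation
    horse, ready for training."""
    train_sessions, val_sessions = eg.fixed_validation_split(
        default_cohort, "horse00"
    )
    cfg = eg.WindowConfig(4, 25)
    train = eg.WindowedDataset.concat(
        [
            eg.extract_pure_windows(s, cfg)
            for s in train_sessions
            if s.location == "knee"
        ]
    )
    val = eg.WindowedDataset.concat(
        [
            eg.extract_pure_windows(s, cfg)
            for s in val_sessions
            if s.location == "knee"
        ]
    )
    scaler = eg.fit_scaler(train)
    return eg.apply_scaler(scaler, train), eg.apply_scaler(scaler, val)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
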