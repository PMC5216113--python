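import numpy as np
import pytest

from swallowsense.evaluation import prepare_session, simulate_subjects
from swallowsense.segmentation import CycleSegmenter
from swallowsense.simulate import SimulationConfig, simulate_session
from swallowsense.svm import SwallowSVM


@pytest.fixture(scope="session")
def mixed_session():
    """A default-scenario session with swallows of both phases."""
    cfg = SimulationConfig(duration=300.0, seed=7)
    signal, truth = simulate_session(cfg)
    return signal, truth


@pytest.fixture(scope="session")
def mixed_cycles(mixed_session):
    signal, _ = mixed_session
    return CycleSegmenter().transform(signal)


@pytest.fixture(scope="session")
def small_cohort():
    """Three simulated subjects, one session each."""
    return simulate_subjects(3, seed=11, config_overrides={"duration": 420.0})


@pytest.fixture(scope="session")
def fitted_svm(small_cohort):
    """A SwallowSVM trained on two subjects, plus held-out test data."""
    subjects = list(small_cohort)
    prepared = {s: [prepare_session(sig, ann) for sig, ann in v]
                for s, v in small_cohort.items()}
    train = [prepared[s] for s in subjects[1:]]
    X = np.vstack([f.to_numpy() for sess in train for f, _, _ in sess])
    y = np.concatenate([lab for sess in train for _, lab, _ in sess])
    model = SwallowSVM().fit(X, np.where(y == 1, 1, -1))
    f_te, y_te, _ = prepared[subjects[0]][0]
    return model, X, y, f_te.to_numpy(), y_te
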