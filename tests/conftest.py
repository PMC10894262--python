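import numpy as np
import pytest

import lfaseq as L
from lfaseq.pipeline import train_on_panel


@pytest.fixture(scope="session")
def layout():
    return L.StripLayout()


@pytest.fixture(scope="session")
def kinetics():
    return L.KineticParams()


@pytest.fixture(scope="session")
def acq():
    return L.AcquisitionSpec()


def make_panel(reps=10, negatives=10, noise_seed=7, test_reps=3,
               split_seed=11, val_seed=3):
    """Standard 8-level dilution panel with per-level held-out test records."""
    ladder = L.serial_dilution(50, 2, 8)
    manifest = L.simulate_panel(
        ladder, reps, negatives, L.StripLayout(), L.KineticParams(),
        L.AcquisitionSpec(), L.NoiseSpec(seed=noise_seed))
    rng = np.random.default_rng(split_seed)
    by_level = {}
    for i, r in enumerate(manifest.records):
        by_level.setdefault(r.level, []).append(i)
    for idx in by_level.values():
        for i in rng.choice(idx, test_reps, replace=False):
            manifest.records[i].split = "test"
    return L.split_train_val(manifest, 0.10, seed=val_seed)


@pytest.fixture(scope="session")
def standard_panel():
    """8 levels x 10 reps + 10 blanks, 12 frames at 10 s, default noise."""
    return make_panel()


@pytest.fixture(scope="session")
def small_panel():
    """Cheap 4-level panel for smoke tests."""
    return make_panel(reps=3, negatives=3, test_reps=1)


@pytest.fixture(scope="session")
def trained_models(standard_panel):
    """Level regressors trained on the standard panel for seeds 0, 1, 2."""
    models = {}
    for seed in (0, 1, 2):
        model, report = train_on_panel(standard_panel,
                                       L.ModelConfig(seed=seed))
        models[seed] = (model, report)
    return models
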