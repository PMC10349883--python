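import warnings

import numpy as np
import pytest

from sleepsci import simulate_eeg, simulate_hypnogram
from sleepsci.config import ModelConfig
from sleepsci.preprocess import preprocess_recording
from sleepsci.synthetic import EEGGenParams

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", module="sklearn")
try:
    from sklearn.exceptions import ConvergenceWarning
    warnings.filterwarnings("ignore", category=ConvergenceWarning)
except ImportError:
    pass


@pytest.fixture(scope="session")
def night():
    """One-hour synthetic night with ground truth, preprocessed once."""
    hyp = simulate_hypnogram(120, seed=1)
    rec, truth = simulate_eeg(hyp, EEGGenParams(), seed=2)
    clean, grid = preprocess_recording(rec, hyp)
    return {"hypnogram": hyp, "raw": rec, "truth": truth,
            "clean": clean, "grid": grid}


@pytest.fixture(scope="session")
def short_night():
    """20-minute night for cheaper end-to-end checks."""
    hyp = simulate_hypnogram(40, seed=11)
    rec, truth = simulate_eeg(hyp, EEGGenParams(), seed=12)
    clean, grid = preprocess_recording(rec, hyp)
    return {"hypnogram": hyp, "raw": rec, "truth": truth,
            "clean": clean, "grid": grid}


@pytest.fixture(scope="session")
def fast_model_cfg():
    """Reduced hyperparameter grid for protocol-structure tests."""
    return ModelConfig(l1_ratios=(0.5, 1.0), n_alphas=15)


@pytest.fixture(autouse=True)
def _seeded_numpy():
    np.random.seed(0)
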