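"""Shared fixtures.

The expensive end-to-end artefacts (the 80-subject synthetic
calibration and its MEPAT record) are session-scoped so the whole
suite pays for them once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from gummix.pipeline import TrainingPolicy, calibrate, extract_dataset
from gummix.synthetic import SyntheticConfig, generate_calibration_set, generate_specimen

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def specimen_t0(default_config):
    """Unchewed specimen: pure red face / pure white face."""
    return generate_specimen(0, 0.05, default_config, seed=11)


@pytest.fixture(scope="session")
def specimen_t20(default_config):
    """Well-mixed specimen at the reference 20 strokes."""
    return generate_specimen(20, 0.05, default_config, seed=12)


@pytest.fixture(scope="session")
def full_calibration():
    """The reference-population calibration: 80 subjects x 5 cycles.

    Runs the complete pipeline (segmentation, feature extraction,
    q-score selection, reduced-sweep cascade training) once for the
    session and returns the CalibrationResult.
    """
    config = SyntheticConfig(n_subjects=80, cycles=(0, 5, 10, 15, 20), seed=42)
    specimens = generate_calibration_set(config)
    mp, labels = extract_dataset(specimens)
    result = calibrate(
        specimens,
        policy=TrainingPolicy(h_sweep=10, restarts=3, seed=42),
        mp=mp, labels=labels,
    )
    return result


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
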