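"""Shared fixtures: tiny seeded recordings and synthetic study tables."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from asft.io import Recording

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")
from asft.features import extract_study_features
from asft.synthetic import SimConfig, simulate_study


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_recording(rng) -> Recording:
    """4 channels, 10 s at 100 Hz: mixed tones plus noise."""
    fs = 100.0
    t = np.arange(int(10 * fs)) / fs
    data = np.stack([
        10 * np.sin(2 * np.pi * 6 * t) + rng.standard_normal(t.size),
        8 * np.sin(2 * np.pi * 10 * t) + rng.standard_normal(t.size),
        5 * np.sin(2 * np.pi * 20 * t) + rng.standard_normal(t.size),
        rng.standard_normal(t.size),
    ])
    return Recording(subject_id="S00", session="pre", state="alert", fs=fs,
                     channels=("FP1", "FP2", "O1", "O2"), data=data)


@pytest.fixture(scope="session")
def small_study_table():
    """3 subjects × 2 sessions × 12 s at 500 Hz → 66 rows × 512 columns."""
    cfg = SimConfig(n_subjects=3, duration_s=12.0, seed=7)
    return extract_study_features(simulate_study(cfg))


@pytest.fixture(scope="session")
def medium_study_table():
    """8 subjects × 2 sessions × 12 s → 176 rows; for CV-protocol tests."""
    cfg = SimConfig(n_subjects=8, duration_s=12.0, seed=9)
    return extract_study_features(simulate_study(cfg))
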