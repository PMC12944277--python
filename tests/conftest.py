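"""Shared fixtures: small synthetic cohorts and a trained classifier.

Everything is generated programmatically at session scope so expensive
artefacts (training runs, 3-animal cohorts) are built once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

import gaitloop as gl
from gaitloop import kinematics


@pytest.fixture(scope="session")
def noise_free_sham():
    """20 s sham session without jitter or abnormal bouts, plus truth."""
    cfg = gl.GaitGenConfig(
        group="sham", duration_s=20.0, seed=5, noise_deg=0.0, abnormal_rate_per_s=0.0
    )
    return gl.generate_session(cfg)


@pytest.fixture(scope="session")
def noisy_sci():
    """15 s injured-gait session with abnormal bouts, plus truth."""
    cfg = gl.GaitGenConfig(
        group="sci", duration_s=15.0, seed=99, abnormal_rate_per_s=0.05
    )
    return gl.generate_session(cfg)


@pytest.fixture(scope="session")
def training_material():
    """Two 30 s labelled sessions (sham + SCI) as (angle_samples, labels)."""
    sessions = []
    for group, seed in [("sham", 11), ("sci", 12)]:
        cfg = gl.GaitGenConfig(
            group=group, duration_s=30.0, seed=seed, abnormal_rate_per_s=0.05
        )
        session, truth = gl.generate_session(cfg)
        sessions.append((kinematics.angles_from_session(session), truth.labels))
    return sessions


@pytest.fixture(scope="session")
def trained_model(training_material):
    """Classifier trained on the sham+SCI material, with its dataset."""
    dataset = gl.build_dataset(training_material, seed=0)
    model, history = gl.train(dataset, epochs_max=80, seed=0)
    return model, history, dataset


@pytest.fixture(scope="session")
def sham_cohort_stats():
    """Group stats recovered from 3 virtual sham animals x 180 s."""
    cfg = gl.GaitGenConfig(group="sham", duration_s=180.0, seed=1)
    summaries = []
    for name, session, _truth in gl.generate_group(cfg, n_animals=3):
        samples, labels, transitions, cycles = gl.label_session(session)
        summaries.append(gl.gait_metrics.summarize_animal(name, cycles, samples))
    return gl.aggregate_group("sham", summaries), summaries


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
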