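"""Shared fixtures: tiny hand-built trials and session-scoped synthetic datasets."""

import numpy as np
import pytest
from hypothesis import settings

from gaitpower.io_dataset import (BreathSample, ConditionMeta, SignalChannel,
                                  SubjectMeta, TrialRecording)
from gaitpower.synthetic import GeneratorConfig, generate_dataset

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_channel(name, samples, rate=2000.0):
    return SignalChannel.from_name(name, np.asarray(samples, dtype=float), rate)


def make_trial(channels=None, n_samples=100, rate=2000.0, breaths=None,
               subject_id="T00", condition_id="walk", mass=70.0, baseline=True):
    """Minimal valid trial: a right vertical GRF plus any extra channels."""
    if channels is None:
        channels = [make_channel("grf_r_z", np.zeros(n_samples), rate)]
    if breaths is None:
        breaths = [BreathSample(time=1.0, vo2=1.0, vco2=0.8)]
    return TrialRecording(
        subject=SubjectMeta(subject_id=subject_id, mass=mass),
        condition=ConditionMeta(condition_id=condition_id,
                                is_baseline_normal_walk=baseline),
        channels=channels, breaths=breaths)


@pytest.fixture
def trial_factory():
    return make_trial


@pytest.fixture
def channel_factory():
    return make_channel


@pytest.fixture(scope="session")
def planted_assisted():
    """Noise-free planted-linear assisted dataset: 6 subjects x 9 conditions."""
    cfg = GeneratorConfig.planted(design="assisted", n_subjects=6, trial_s=12.0, seed=1)
    trials, record = generate_dataset(cfg)
    return trials, record


@pytest.fixture(scope="session")
def planted_features(planted_assisted):
    """Assembled per-cycle features of the planted dataset (all channels)."""
    from gaitpower.features import assemble_features

    trials, record = planted_assisted
    labels = dict(record.true_power)
    return assemble_features(trials, labels), labels


@pytest.fixture(scope="session")
def realistic_assisted():
    """Small noisy assisted dataset: 3 subjects x 9 conditions, 8 s trials."""
    cfg = GeneratorConfig(design="assisted", n_subjects=3, trial_s=8.0, seed=7)
    trials, record = generate_dataset(cfg)
    return trials, record


@pytest.fixture(scope="session")
def realistic_incline():
    """Small noisy incline-load dataset: 3 subjects x 12 conditions."""
    cfg = GeneratorConfig.incline_load(n_subjects=3, trial_s=8.0, seed=9)
    trials, record = generate_dataset(cfg)
    return trials, record
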