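"""Shared fixtures: small synthetic recordings and cohorts.

Everything is generated programmatically at test time; no stored data.
"""

import numpy as np
import pytest

from tremormark.io import Condition, Recording
from tremormark.synthetic import SimParams, synth_cohort, synth_emg

FS = 512.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_params():
    """Generator settings for fast unit tests (10-s recordings)."""
    return SimParams(duration_s=10.0, seed=99)


@pytest.fixture(scope="session")
def tremor_recording(short_params):
    """One 10-s DBS-off recording with a 5 Hz burst train."""
    return synth_emg(
        5.0, 40.0, 0.9, short_params, np.random.default_rng(7), patient_id="P001"
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six patients with 12-s recordings, for I/O and pipeline plumbing."""
    params = SimParams(n_patients=6, duration_s=12.0, seed=5)
    return synth_cohort(params), params


def sine(freq, duration_s=10.0, fs=FS, amplitude=1.0, phase=0.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t + phase)
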