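import dataclasses

import numpy as np
import pytest

from ddsim import SampledSignal, SimConfig, simulate_composite


@pytest.fixture(scope="session")
def default_truth():
    """One default simulated composite with ground truth (seeded)."""
    return simulate_composite(SimConfig(seed=11))


@pytest.fixture(scope="session")
def short_truth():
    """A shorter composite for fast per-test decompositions."""
    return simulate_composite(SimConfig(seed=11, duration=0.5))


@pytest.fixture()
def two_tone():
    """5 Hz + 50 Hz equal-amplitude tones, 4 s at 1 kHz."""
    fs = 1000.0
    t = np.arange(int(4 * fs)) / fs
    return SampledSignal(np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 50 * t), fs)


# at least one full cardiac cycle (period 0.83 s at the default 72 bpm):
# shorter windows leave an unaveraged pulsatile drift that mimics a wall trend

def null_wall_config(seed: int, duration: float = 1.0) -> SimConfig:
    cfg = SimConfig(seed=seed, duration=duration)
    return dataclasses.replace(cfg, wall=dataclasses.replace(cfg.wall, wall_amp=0.0))


def null_blood_config(seed: int, duration: float = 1.0) -> SimConfig:
    return dataclasses.replace(SimConfig(seed=seed, duration=duration), blood_amp=0.0)
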