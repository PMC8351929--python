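import numpy as np
import pytest

from gaitevents import SyntheticConfig, SyntheticCycleTruth, generate_dataset


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free dataset: labelling must recover ground truth exactly."""
    cfg = SyntheticConfig(
        n_participants=6, cycles_per_participant=10, seed=11, qc_violation_rate=0.0
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Moderately noisy dataset with QC violations injected."""
    cfg = SyntheticConfig(
        n_participants=6,
        cycles_per_participant=10,
        seed=13,
        noise_sd=0.05,
        qc_violation_rate=0.15,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def example_truth():
    return SyntheticCycleTruth(
        cycle_duration=0.7,
        contact_start_time=0.2,
        contact_end_time=0.445,
        speed=3.5,
        strike_pattern="rearfoot",
        foot_strike_angle=12.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
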