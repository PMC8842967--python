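import numpy as np
import pytest

from fogdetect import SensorLocation, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 participants x 2 walks x 20 s at 64 Hz, two sensors (fast)."""
    cfg = SyntheticConfig(
        n_participants=2,
        walks_per_participant=2,
        walk_duration_s=20.0,
        sample_rate=64.0,
        fog_propensity=(0.3, 0.45),
        sensors=(SensorLocation.ANKLE_L, SensorLocation.HEAD),
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_recording(
    n_samples=160,
    sample_rate=64.0,
    sensors=(SensorLocation.ANKLE_L,),
    participant_id="P01",
    walk_id="w0",
    seed=0,
):
    """Small random-but-valid walk recording for structural tests."""
    from fogdetect import WalkRecording

    r = np.random.default_rng(seed)
    return WalkRecording(
        participant_id=participant_id,
        walk_id=walk_id,
        sample_rate=sample_rate,
        signals={s: r.standard_normal((6, n_samples)) for s in sensors},
        labels=r.uniform(size=n_samples) < 0.3,
    )
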