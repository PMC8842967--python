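"""Synthetic labeled IMU walk cohorts.

Generates cohorts with the statistical structure a windowed FOG detector
must exploit: outside freezing episodes every sensor carries a locomotor
oscillation (step fundamental plus two harmonics) whose amplitude scales
with how informative that body location is; during an episode the
locomotor component is suppressed and leg-worn sensors additionally
carry band-limited 3-8 Hz "trembling".  Labels mirror the episode
schedule at sample resolution.

The default configuration emulates a small Parkinson's cohort walking a
freeze-eliciting course: 7 participants, 5-14 walks of 90 s each at
128 Hz, with participant-specific fractions of time frozen spanning
roughly 10-54 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .signal_io import Cohort, LEG_LOCATIONS, SensorLocation, WalkRecording

__all__ = [
    "SyntheticConfig",
    "FogSchedule",
    "DEFAULT_INFORMATIVENESS",
    "TABLE_PROPENSITIES",
    "generate_fog_schedule",
    "synthesize_walk",
    "generate_cohort",
]

#: per-location gain in [0, 1]: how strongly the gait / tremble
#: components appear at that location.  Legs and lumbar are informative,
#: wrists and head are nearly pure noise.
DEFAULT_INFORMATIVENESS: dict[SensorLocation, float] = {
    SensorLocation.HEAD: 0.05,
    SensorLocation.CHEST: 0.45,
    SensorLocation.LUMBAR: 0.75,
    SensorLocation.WRIST_L: 0.15,
    SensorLocation.WRIST_R: 0.15,
    SensorLocation.THIGH_L: 0.80,
    SensorLocation.THIGH_R: 0.80,
    SensorLocation.ANKLE_L: 1.00,
    SensorLocation.ANKLE_R: 1.00,
    SensorLocation.FOOT_L: 0.90,
    SensorLocation.FOOT_R: 0.90,
}

#: participant-level fractions of time frozen of a real 7-participant
#: freeze-eliciting-course cohort (mean % time FOG per participant / 100)
TABLE_PROPENSITIES = (0.198, 0.123, 0.237, 0.537, 0.099, 0.453, 0.283)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    ``fog_propensity`` gives one probability-like occupancy per
    participant (fraction of walking time spent frozen); if fewer values
    than participants are given the list is cycled.
    ``walks_per_participant`` is either a fixed count or an inclusive
    ``(low, high)`` range sampled per participant.
    """

    n_participants: int = 7
    walks_per_participant: int | tuple[int, int] = (5, 14)
    walk_duration_s: float = 90.0
    sample_rate: float = 128.0
    fog_propensity: Sequence[float] = TABLE_PROPENSITIES
    mean_fog_duration_s: float = 5.0
    step_freq_hz: float = 1.0
    step_freq_jitter_hz: float = 0.15
    tremble_band_hz: tuple[float, float] = (3.0, 8.0)
    informativeness: Mapping[SensorLocation, float] = field(
        default_factory=lambda: dict(DEFAULT_INFORMATIVENESS)
    )
    sensors: tuple[SensorLocation, ...] = tuple(SensorLocation)
    gait_amplitude: float = 2.0
    tremble_amplitude: float = 1.5
    fog_gait_attenuation: float = 0.1  # residual locomotion during FOG
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "informativeness",
            {SensorLocation.coerce(k): float(v) for k, v in self.informativeness.items()},
        )
        object.__setattr__(
            self, "sensors", tuple(SensorLocation.coerce(s) for s in self.sensors)
        )
        for loc in self.sensors:
            if loc not in self.informativeness:
                raise ValueError(f"no informativeness gain for sensor {loc.value}")
        for loc, g in self.informativeness.items():
            if not 0.0 <= g <= 1.0:
                raise ValueError(f"informativeness[{loc.value}]={g} outside [0, 1]")
        if self.walk_duration_s <= 0 or self.mean_fog_duration_s <= 0:
            raise ValueError("durations must be positive")
        for p in self.fog_propensity:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"fog propensity {p} outside [0, 1]")
        if self.fog_gait_attenuation > 0.2:
            raise ValueError("locomotion must be attenuated by >= 80 % during FOG")

    def propensity_of(self, participant_index: int) -> float:
        return float(self.fog_propensity[participant_index % len(self.fog_propensity)])


@dataclass(frozen=True)
class FogSchedule:
    """Non-overlapping, sorted FOG episodes within one walk (seconds)."""

    intervals: tuple[tuple[float, float], ...]
    duration_s: float

    def __post_init__(self) -> None:
        prev_end = 0.0
        for start, end in self.intervals:
            if not (0.0 <= start < end <= self.duration_s + 1e-9):
                raise ValueError(f"interval ({start}, {end}) outside [0, {self.duration_s}]")
            if start < prev_end - 1e-12:
                raise ValueError("intervals overlap or are unsorted")
            prev_end = end

    @property
    def total_fog_s(self) -> float:
        return sum(e - s for s, e in self.intervals)

    @property
    def occupancy(self) -> float:
        return self.total_fog_s / self.duration_s

    def labels(self, sample_rate: float, n_samples: int) -> np.ndarray:
        """Boolean per-sample labels mirroring the schedule exactly."""
        t = np.arange(n_samples) / sample_rate
        lab = np.zeros(n_samples, dtype=bool)
        for start, end in self.intervals:
            lab |= (t >= start) & (t < end)
        return lab


def _lognormal_with_mean(mean: float, sigma: float, rng: np.random.Generator, size=None):
    mu = np.log(mean) - 0.5 * sigma**2
    return rng.lognormal(mu, sigma, size=size)


def generate_fog_schedule(
    duration_s: float,
    propensity: float,
    mean_dur_s: float,
    rng: np.random.Generator,
    sigma: float = 0.5,
) -> FogSchedule:
    """Draw a walk's FOG episode schedule.

    A two-state alternating renewal process: episode durations are
    log-normal with the stated mean; gap durations are log-normal with
    mean chosen so the long-run occupancy equals *propensity*.  The
    process is started a few cycles before t=0 and clipped to the walk,
    which keeps the expected occupancy close to the target despite the
    finite walk length.
    """
    if not 0.0 <= propensity <= 1.0:
        raise ValueError("propensity must lie in [0, 1]")
    if propensity == 0.0:
        return FogSchedule((), duration_s)
    if propensity >= 1.0:
        return FogSchedule(((0.0, duration_s),), duration_s)

    mean_gap = mean_dur_s * (1.0 - propensity) / propensity
    burn_in = 3.0 * (mean_dur_s + mean_gap)
    t = -burn_in * rng.uniform()  # random phase start
    frozen = rng.uniform() < propensity
    intervals: list[tuple[float, float]] = []
    while t < duration_s:
        if frozen:
            dur = float(_lognormal_with_mean(mean_dur_s, sigma, rng))
            start, end = max(t, 0.0), min(t + dur, duration_s)
            if end > start:
                intervals.append((start, end))
        else:
            dur = float(_lognormal_with_mean(mean_gap, sigma, rng))
        t += dur
        frozen = not frozen
    return FogSchedule(tuple(intervals), duration_s)


def _bandlimited_noise(
    n: int, sample_rate: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS noise band-passed to *band* (4th-order Butterworth)."""
    low, high = band
    high = min(high, 0.49 * sample_rate)
    sos = sps.butter(4, [low, high], btype="band", fs=sample_rate, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n + int(sample_rate)))[int(sample_rate):]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def synthesize_walk(
    cfg: SyntheticConfig,
    participant_index: int,
    schedule: FogSchedule,
    rng: np.random.Generator,
    walk_id: str = "walk0",
    step_freq_hz: float | None = None,
) -> WalkRecording:
    """Render one walk's signals from a FOG schedule.

    Per channel: gait = sum of three harmonics of the participant's step
    frequency with random phases, scaled by the location gain; during
    FOG the gait amplitude is multiplied by ``fog_gait_attenuation``
    (>= 80 % suppression) and leg locations gain a 3-8 Hz tremble
    component.  Gyro channels share the component structure with
    independent phases and noise.
    """
    fs = cfg.sample_rate
    n = int(round(cfg.walk_duration_s * fs))
    t = np.arange(n) / fs
    labels = schedule.labels(fs, n)
    fog = labels.astype(float)
    walkmask = 1.0 - (1.0 - cfg.fog_gait_attenuation) * fog

    f0 = step_freq_hz if step_freq_hz is not None else cfg.step_freq_hz
    signals: dict[SensorLocation, np.ndarray] = {}
    for loc in cfg.sensors:
        gain = cfg.informativeness[loc]
        mat = np.empty((6, n))
        for ch in range(6):
            gait = np.zeros(n)
            for h, rel in enumerate((1.0, 0.5, 0.25), start=1):
                amp = cfg.gait_amplitude * rel * (0.8 + 0.4 * rng.uniform())
                gait += amp * np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi))
            x = gain * gait * walkmask
            if loc in LEG_LOCATIONS and gain > 0 and labels.any():
                tremble = _bandlimited_noise(n, fs, cfg.tremble_band_hz, rng)
                x = x + gain * cfg.tremble_amplitude * tremble * fog
            x = x + cfg.noise_sd * rng.standard_normal(n)
            mat[ch] = x
        signals[loc] = mat

    return WalkRecording(
        participant_id=f"P{participant_index + 1:02d}",
        walk_id=walk_id,
        sample_rate=fs,
        signals=signals,
        labels=labels,
    )


def generate_cohort(cfg: SyntheticConfig) -> Cohort:
    """Generate a full cohort, deterministically for a fixed seed."""
    if cfg.n_participants < 2:
        raise ValueError("need >= 2 participants for leave-one-subject-out validation")
    root = np.random.default_rng(cfg.seed)
    walks: list[WalkRecording] = []
    for p in range(cfg.n_participants):
        prng = np.random.default_rng(root.integers(2**31))
        if isinstance(cfg.walks_per_participant, int):
            n_walks = cfg.walks_per_participant
        else:
            lo, hi = cfg.walks_per_participant
            n_walks = int(prng.integers(lo, hi + 1))
        f0 = cfg.step_freq_hz + prng.uniform(-cfg.step_freq_jitter_hz, cfg.step_freq_jitter_hz)
        prop = cfg.propensity_of(p)
        for w in range(n_walks):
            schedule = generate_fog_schedule(
                cfg.walk_duration_s, prop, cfg.mean_fog_duration_s, prng
            )
            walks.append(
                synthesize_walk(
                    cfg, p, schedule, prng, walk_id=f"walk{w:02d}", step_freq_hz=f0
                )
            )
    return Cohort(walks)
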