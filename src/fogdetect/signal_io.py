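"""Reading, writing and resampling of labeled multi-sensor IMU walks.

A *walk* is one continuous recording of a participant walking a
freeze-eliciting course while wearing body-fixed inertial measurement
units (IMUs).  Each IMU contributes six channels: tri-axial acceleration
(m s^-2) and tri-axial angular velocity (rad s^-1).  Every sample carries
a binary freezing-of-gait (FOG) label derived from expert video rating.

On disk a walk is a plain CSV with columns ``time_s``, then
``{location}_{acc|gyr}_{x|y|z}`` per sensor, then ``label`` (0/1).  A
cohort is a directory with a ``manifest.csv`` mapping
``participant_id, walk_id, path``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "SensorLocation",
    "WalkRecording",
    "Cohort",
    "SchemaError",
    "read_walk",
    "write_walk",
    "resample",
    "read_cohort",
    "write_cohort",
    "AXES",
    "CHANNEL_SUFFIXES",
]

#: channel suffixes in canonical order within one sensor
AXES = ("x", "y", "z")
CHANNEL_SUFFIXES = tuple(f"{kind}_{ax}" for kind in ("acc", "gyr") for ax in AXES)


class SensorLocation(str, enum.Enum):
    """Body locations where an IMU may be worn.

    The declaration order is the canonical sensor ordering used for
    channel stacking throughout the package.
    """

    HEAD = "head"
    CHEST = "chest"
    LUMBAR = "lumbar"
    WRIST_L = "wrist_L"
    WRIST_R = "wrist_R"
    THIGH_L = "thigh_L"
    THIGH_R = "thigh_R"
    ANKLE_L = "ankle_L"
    ANKLE_R = "ankle_R"
    FOOT_L = "foot_L"
    FOOT_R = "foot_R"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def coerce(cls, value: "SensorLocation | str") -> "SensorLocation":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ValueError(
                f"unknown sensor location {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


#: sensors on the legs — the only locations where FOG trembling appears
LEG_LOCATIONS = frozenset(
    {
        SensorLocation.THIGH_L,
        SensorLocation.THIGH_R,
        SensorLocation.ANKLE_L,
        SensorLocation.ANKLE_R,
        SensorLocation.FOOT_L,
        SensorLocation.FOOT_R,
    }
)


def canonical_order(
    sensors: Iterable["SensorLocation | str"],
) -> tuple[SensorLocation, ...]:
    """Return *sensors* sorted into the canonical (declaration) order."""
    coerced = {SensorLocation.coerce(s) for s in sensors}
    return tuple(s for s in SensorLocation if s in coerced)


class SchemaError(ValueError):
    """A walk file does not follow the expected CSV schema."""


@dataclass
class WalkRecording:
    """One walk's synchronized multi-sensor signals plus per-sample labels.

    Parameters
    ----------
    participant_id, walk_id
        Identifiers; a cohort groups walks by participant.
    sample_rate
        Sampling frequency in Hz (all sensors synchronized).
    signals
        Mapping ``SensorLocation -> (6, n_samples)`` array; rows are
        acc x/y/z then gyr x/y/z.
    labels
        Boolean array of length ``n_samples``; ``True`` = FOG.
    """

    participant_id: str
    walk_id: str
    sample_rate: float
    signals: dict[SensorLocation, np.ndarray]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.signals = {
            SensorLocation.coerce(k): np.asarray(v, dtype=float)
            for k, v in self.signals.items()
        }
        self.labels = np.asarray(self.labels, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not self.signals:
            raise ValueError("recording must carry at least one sensor")
        n = self.labels.shape[0]
        for loc, mat in self.signals.items():
            if mat.ndim != 2 or mat.shape[0] != 6:
                raise ValueError(f"sensor {loc.value}: expected (6, n) signal matrix")
            if mat.shape[1] != n:
                raise ValueError(
                    f"sensor {loc.value}: {mat.shape[1]} samples but "
                    f"{n} labels"
                )
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"sensor {loc.value}: non-finite samples")
        if n < 2 * self.sample_rate:
            raise ValueError(
                f"recording too short: {n} samples < one 2-s window "
                f"({2 * self.sample_rate:.0f} samples)"
            )

    @property
    def n_samples(self) -> int:
        return int(self.labels.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def sensors(self) -> tuple[SensorLocation, ...]:
        return canonical_order(self.signals)

    @property
    def percent_time_fog(self) -> float:
        return 100.0 * float(np.mean(self.labels))

    def equals(self, other: "WalkRecording", atol: float = 1e-9) -> bool:
        if (
            self.participant_id != other.participant_id
            or self.walk_id != other.walk_id
            or self.sample_rate != other.sample_rate
            or self.sensors != other.sensors
            or not np.array_equal(self.labels, other.labels)
        ):
            return False
        return all(
            np.allclose(self.signals[s], other.signals[s], atol=atol, rtol=0)
            for s in self.sensors
        )


@dataclass
class Cohort:
    """An ordered collection of walks spanning >= 2 participants."""

    walks: list[WalkRecording] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.walks:
            raise ValueError("cohort must contain at least one walk")

    @property
    def participants(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for w in self.walks:
            seen.setdefault(w.participant_id, None)
        return tuple(seen)

    @property
    def sample_rate(self) -> float:
        rates = {w.sample_rate for w in self.walks}
        if len(rates) != 1:
            raise ValueError(f"cohort has mixed sample rates: {sorted(rates)}")
        return rates.pop()

    def common_sensors(self) -> tuple[SensorLocation, ...]:
        common = set(self.walks[0].signals)
        for w in self.walks[1:]:
            common &= set(w.signals)
        return canonical_order(common)

    def percent_time_fog(self) -> float:
        """Cohort-level % time FOG, pooled over all samples."""
        total = sum(w.n_samples for w in self.walks)
        fog = sum(int(w.labels.sum()) for w in self.walks)
        return 100.0 * fog / total


def _signal_columns(sensors: Sequence[SensorLocation]) -> list[str]:
    return [f"{s.value}_{suf}" for s in sensors for suf in CHANNEL_SUFFIXES]


def read_walk(
    path: str | Path,
    participant_id: str = "",
    walk_id: str = "",
) -> WalkRecording:
    """Read one walk CSV.

    Channel assignment is header-driven: column order in the file never
    matters.  The sample rate is inferred from the ``time_s`` column
    (median spacing, rounded to the nearest Hz).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed CSV ({exc})") from exc
    for required in ("time_s", "label"):
        if required not in df.columns:
            raise SchemaError(f"{path}: missing required column {required!r}")

    label_col = df["label"]
    if not label_col.isin([0, 1, True, False]).all():
        bad = label_col[~label_col.isin([0, 1, True, False])].iloc[0]
        raise SchemaError(f"{path}: non-boolean label value {bad!r}")

    sensors: dict[SensorLocation, np.ndarray] = {}
    for loc in SensorLocation:
        cols = [f"{loc.value}_{suf}" for suf in CHANNEL_SUFFIXES]
        present = [c in df.columns for c in cols]
        if all(present):
            sensors[loc] = df[cols].to_numpy(dtype=float).T
        elif any(present):
            missing = [c for c, p in zip(cols, present) if not p]
            raise SchemaError(f"{path}: incomplete sensor {loc.value}: missing {missing}")
    if not sensors:
        raise SchemaError(f"{path}: no complete sensor column groups found")

    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = float(np.median(np.diff(t)))
        rate = round(1.0 / dt) if dt > 0 else 0.0
    else:
        rate = 0.0
    return WalkRecording(
        participant_id=participant_id or path.stem,
        walk_id=walk_id or path.stem,
        sample_rate=float(rate),
        signals=sensors,
        labels=label_col.to_numpy().astype(bool),
    )


def write_walk(rec: WalkRecording, path: str | Path) -> Path:
    """Write *rec* to the CSV walk schema; round-trips through read_walk."""
    rec.validate()
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.sample_rate
    data: dict[str, np.ndarray] = {"time_s": t}
    for loc in rec.sensors:
        for i, suf in enumerate(CHANNEL_SUFFIXES):
            data[f"{loc.value}_{suf}"] = rec.signals[loc][i]
    data["label"] = rec.labels.astype(int)
    # %.17g preserves doubles exactly through text
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    return path


def resample(rec: WalkRecording, target_rate: float) -> WalkRecording:
    """Decimate a recording to *target_rate* Hz.

    The decimation factor must be an integer.  Signals pass through a
    zero-phase low-pass (8th-order Butterworth, cutoff 0.45 * target
    rate) before taking every factor-th sample; labels are decimated by
    the same index selection so signal/label alignment is exact.
    """
    if target_rate > rec.sample_rate:
        raise ValueError(
            f"cannot upsample: target {target_rate} Hz > source {rec.sample_rate} Hz"
        )
    ratio = rec.sample_rate / target_rate
    factor = round(ratio)
    if abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"target rate {target_rate} Hz does not evenly divide "
            f"{rec.sample_rate} Hz"
        )
    if factor == 1:
        return WalkRecording(
            rec.participant_id,
            rec.walk_id,
            rec.sample_rate,
            {k: v.copy() for k, v in rec.signals.items()},
            rec.labels.copy(),
        )
    sos = sps.butter(8, 0.45 * target_rate, btype="low", fs=rec.sample_rate, output="sos")
    keep = np.arange(0, rec.n_samples, factor)
    signals = {
        loc: sps.sosfiltfilt(sos, mat, axis=1)[:, keep]
        for loc, mat in rec.signals.items()
    }
    return WalkRecording(
        rec.participant_id,
        rec.walk_id,
        float(target_rate),
        signals,
        rec.labels[keep],
    )


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write a cohort as per-walk CSVs plus a ``manifest.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.walks:
        fname = f"{rec.participant_id}_{rec.walk_id}.csv"
        write_walk(rec, directory / fname)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "walk_id": rec.walk_id,
                "path": fname,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    return directory


def read_cohort(directory: str | Path) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise SchemaError(f"{directory}: no manifest.csv")
    df = pd.read_csv(manifest, dtype=str)
    for required in ("participant_id", "walk_id", "path"):
        if required not in df.columns:
            raise SchemaError(f"{manifest}: missing required column {required!r}")
    walks = [
        read_walk(directory / row.path, row.participant_id, row.walk_id)
        for row in df.itertuples()
    ]
    return Cohort(walks)
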