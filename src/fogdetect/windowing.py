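"""Segmentation of walks into normalized, labeled, weighted 2-s windows.

The detector consumes fixed-length windows of raw multi-channel IMU
data.  This module computes the overlap (stride) needed to reach a
target window count, cuts windows that never span walk boundaries,
assigns each window the majority label of its samples, normalizes each
channel to zero mean / unit variance, applies the random-rotation
augmentation, and attaches the per-participant, per-class loss weights
(each participant's weights sum to 1; each class within a participant
sums to 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .signal_io import (
    AXES,
    CHANNEL_SUFFIXES,
    Cohort,
    SensorLocation,
    canonical_order,
)

__all__ = [
    "WindowSet",
    "compute_stride",
    "expected_window_count",
    "majority_label",
    "segment",
    "normalize_windows",
    "augment_rotation",
    "compute_weights",
    "channel_names",
]


def channel_names(sensor_set: Sequence[SensorLocation]) -> list[str]:
    """Canonical channel labels for a sensor subset."""
    return [f"{s.value}_{suf}" for s in sensor_set for suf in CHANNEL_SUFFIXES]


@dataclass
class WindowSet:
    """Labeled windows as a dense array, plus per-window metadata.

    ``data`` has shape ``(n_windows, n_channels, n_samples)`` with
    channels stacked sensor-by-sensor in canonical order (acc x/y/z then
    gyr x/y/z within each sensor).  ``data`` holds *raw* (unnormalized)
    samples; normalization is applied at training / prediction time so
    augmentation can rotate the raw signal first.
    """

    data: np.ndarray
    labels: np.ndarray
    participant_ids: np.ndarray
    walk_ids: np.ndarray
    start_s: np.ndarray
    sensor_set: tuple[SensorLocation, ...]
    sample_rate: float
    window_len_s: float
    stride_s: float
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.data.shape[0]
        for name in ("labels", "participant_ids", "walk_ids", "start_s"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length != n_windows")
        if self.data.ndim != 3:
            raise ValueError("data must be (n_windows, n_channels, n_samples)")

    def __len__(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.data.shape[1])

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[2])

    @property
    def participants(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.participant_ids:
            seen.setdefault(str(p), None)
        return tuple(seen)

    def subset(self, mask: np.ndarray) -> "WindowSet":
        return replace(
            self,
            data=self.data[mask],
            labels=self.labels[mask],
            participant_ids=self.participant_ids[mask],
            walk_ids=self.walk_ids[mask],
            start_s=self.start_s[mask],
            weights=None if self.weights is None else self.weights[mask],
        )

    def split_participant(self, participant: str) -> tuple["WindowSet", "WindowSet"]:
        """(train, held_out) split for one leave-one-subject-out fold."""
        held = self.participant_ids == participant
        if not held.any():
            raise KeyError(f"participant {participant!r} has no windows")
        return self.subset(~held), self.subset(held)


def expected_window_count(
    walk_durations_s: Sequence[float], window_len_s: float, stride_s: float
) -> int:
    """Closed-form count: sum over walks of floor((T - L)/s) + 1."""
    return int(
        sum(
            int(np.floor((t - window_len_s) / stride_s + 1e-9)) + 1
            for t in walk_durations_s
        )
    )


def compute_stride(
    walk_durations_s: Sequence[float],
    window_len_s: float,
    target_count: int,
    sample_rate: float,
) -> float:
    """Largest stride (on a 1-sample grid) reaching >= *target_count* windows.

    The count is monotonically non-increasing in the stride, so a binary
    search over integer sample strides finds the largest feasible one.
    """
    if any(t < window_len_s for t in walk_durations_s):
        raise ValueError("every walk must be at least one window long")
    if target_count < len(walk_durations_s):
        raise ValueError("target_count must be >= number of walks")

    def count(stride_samples: int) -> int:
        return expected_window_count(
            walk_durations_s, window_len_s, stride_samples / sample_rate
        )

    max_stride = max(
        1, int(max((t - window_len_s) * sample_rate for t in walk_durations_s))
    )
    if count(1) < target_count:
        raise ValueError(
            f"target {target_count} infeasible: at 1-sample stride only "
            f"{count(1)} windows are achievable"
        )
    lo, hi = 1, max_stride  # count(lo) >= target
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if count(mid) >= target_count:
            lo = mid
        else:
            hi = mid - 1
    return lo / sample_rate


def majority_label(label_slice: np.ndarray) -> bool:
    """Majority vote over a window's sample labels; exact ties count as FOG."""
    label_slice = np.asarray(label_slice, dtype=bool)
    if label_slice.size == 0:
        raise ValueError("empty label slice")
    return bool(2 * int(label_slice.sum()) >= label_slice.size)


def segment(
    cohort: Cohort,
    sensor_set: Iterable[SensorLocation | str],
    window_len_s: float = 2.0,
    stride_s: float | None = None,
) -> WindowSet:
    """Cut every walk into windows restricted to *sensor_set* channels.

    Windows never span walk boundaries; start times lie on the stride
    grid of each walk.  ``stride_s`` defaults to the window length
    (non-overlapping "examples" as used for clinical metrics).
    """
    sensors = canonical_order(sensor_set)
    if not sensors:
        raise ValueError("sensor_set must be non-empty")
    fs = cohort.sample_rate
    if stride_s is None:
        stride_s = window_len_s
    win = int(round(window_len_s * fs))
    step = int(round(stride_s * fs))
    if step < 1:
        raise ValueError("stride below one sample")

    for walk in cohort.walks:
        for s in sensors:
            if s not in walk.signals:
                raise ValueError(
                    f"sensor {s.value} missing from walk "
                    f"{walk.participant_id}/{walk.walk_id}"
                )

    datas, labels, pids, wids, starts = [], [], [], [], []
    for walk in cohort.walks:
        stacked = np.concatenate([walk.signals[s] for s in sensors], axis=0)
        n = walk.n_samples
        for start in range(0, n - win + 1, step):
            sl = slice(start, start + win)
            datas.append(stacked[:, sl])
            labels.append(majority_label(walk.labels[sl]))
            pids.append(walk.participant_id)
            wids.append(walk.walk_id)
            starts.append(start / fs)
    return WindowSet(
        data=np.asarray(datas, dtype=np.float32),
        labels=np.asarray(labels, dtype=bool),
        participant_ids=np.asarray(pids, dtype=object),
        walk_ids=np.asarray(wids, dtype=object),
        start_s=np.asarray(starts, dtype=float),
        sensor_set=sensors,
        sample_rate=fs,
        window_len_s=window_len_s,
        stride_s=stride_s,
    )


def normalize_windows(data: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Zero-mean, unit-variance per channel row (population variance).

    Constant rows map to all zeros.  Accepts ``(..., n_channels,
    n_samples)``; normalization is per window, per channel.
    """
    data = np.asarray(data)
    mean = data.mean(axis=-1, keepdims=True)
    sd = data.std(axis=-1, keepdims=True)  # population sd
    out = np.where(sd > eps, (data - mean) / np.where(sd > eps, sd, 1.0), 0.0)
    return out.astype(data.dtype, copy=False)


def _rotation_matrix(angles: np.ndarray) -> np.ndarray:
    """Compose axis rotations in x -> y -> z order into one orthonormal matrix."""
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def augment_rotation(
    data: np.ndarray,
    rng: np.random.Generator,
    max_angle_rad: float = np.pi,
    angles: np.ndarray | None = None,
) -> np.ndarray:
    """Randomly rotate each sensor's accel and gyro triplets jointly.

    For every window and every sensor, three angles are drawn uniformly
    in ``[-max_angle, +max_angle]`` (one per axis) and composed in
    x -> y -> z order into one orthonormal matrix, which is applied to
    every acc sample-triplet and every gyro sample-triplet of that
    sensor.  Per-sample triplet norms are preserved.  Apply to *raw*
    windows, before normalization.

    ``angles`` (shape ``(n_windows, n_sensors, 3)``) overrides the
    random draw — a hook for fixed-angle tests.
    """
    data = np.asarray(data)
    squeeze = data.ndim == 2
    if squeeze:
        data = data[None]
    n_win, n_ch, n_samp = data.shape
    if n_ch % 6:
        raise ValueError("channel count must be a multiple of 6 (one sensor = 6 channels)")
    n_sensors = n_ch // 6
    if angles is None:
        angles = rng.uniform(-max_angle_rad, max_angle_rad, size=(n_win, n_sensors, 3))
    out = np.empty_like(data)
    view = data.reshape(n_win, n_sensors, 2, 3, n_samp)
    out_view = out.reshape(n_win, n_sensors, 2, 3, n_samp)
    for w in range(n_win):
        for s in range(n_sensors):
            rot = _rotation_matrix(angles[w, s]).astype(data.dtype)
            out_view[w, s, 0] = rot @ view[w, s, 0]  # accel triplet
            out_view[w, s, 1] = rot @ view[w, s, 1]  # gyro triplet
    return out[0] if squeeze else out


def compute_weights(ws: WindowSet) -> WindowSet:
    """Attach per-window loss weights.

    A window of participant ``p`` and class ``c`` gets weight
    ``0.5 / n_{p,c}``: each participant's weights sum to 1 and each
    class within a participant sums to 0.5, so no participant or
    majority class dominates the loss.
    """
    weights = np.empty(len(ws), dtype=float)
    missing = []
    for p in ws.participants:
        is_p = ws.participant_ids == p
        for cls in (False, True):
            sel = is_p & (ws.labels == cls)
            n = int(sel.sum())
            if n == 0:
                missing.append((p, "FOG" if cls else "non-FOG"))
            else:
                weights[sel] = 0.5 / n
    if missing:
        desc = ", ".join(f"{p} lacks {c} windows" for p, c in missing)
        raise ValueError(f"cannot weight classes: {desc}")
    return replace(ws, weights=weights)
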