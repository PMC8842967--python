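"""Walk-level clinical metrics and agreement with human ratings.

Window probabilities become clinically meaningful through three steps:
threshold the per-example probabilities (examples are non-overlapping
2-s windows), post-process the binary sequence (merge FOG periods one
example apart into a single event, then drop events only one example
long), and summarize each walk as *percent time FOG* and *number of FOG
events*.  Agreement between model-derived and human-rated metrics is
quantified with the intraclass correlation ICC(1,1): single-rating,
absolute-agreement, one-way random effects, with reliability classed on
the 95 % CI (< 0.50 poor, 0.50-0.75 moderate, 0.75-0.90 good, > 0.90
excellent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "WalkExampleSeries",
    "ClinicalMetrics",
    "ICCResult",
    "threshold_labels",
    "postprocess_events",
    "compute_clinical_metrics",
    "ground_truth_metrics",
    "icc_1_1",
    "classify_icc",
    "optimize_threshold",
    "THRESHOLD_GRID",
]

#: the threshold grid searched when optimizing a clinical metric's ICC
THRESHOLD_GRID = np.round(np.arange(0, 101) / 100.0, 2)

_BANDS = ("poor", "moderate", "good", "excellent")


@dataclass
class WalkExampleSeries:
    """Per-example model probabilities and ground-truth labels of one walk."""

    walk_id: str
    participant_id: str
    example_len_s: float
    probabilities: np.ndarray
    truth_labels: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.truth_labels = np.asarray(self.truth_labels, dtype=bool)
        if self.probabilities.shape != self.truth_labels.shape:
            raise ValueError("probabilities and truth labels must align")
        if self.probabilities.size == 0:
            raise ValueError("empty example series")
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValueError("probabilities outside [0, 1]")


@dataclass(frozen=True)
class ClinicalMetrics:
    percent_time_fog: float
    n_fog_events: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_time_fog <= 100.0:
            raise ValueError("percent_time_fog outside [0, 100]")
        if self.n_fog_events < 0:
            raise ValueError("n_fog_events negative")


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci95: tuple[float, float]
    reliability_class: str
    degenerate: bool = False


def threshold_labels(probs: Sequence[float], threshold: float) -> np.ndarray:
    """Binary labels: FOG iff probability strictly above the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    return np.asarray(probs, dtype=float) > threshold


def _runs(binary: np.ndarray) -> list[list[int]]:
    """Half-open [start, end) runs of True."""
    b = np.asarray(binary, dtype=bool).astype(np.int8)
    d = np.diff(np.concatenate(([0], b, [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [[int(s), int(e)] for s, e in zip(starts, ends)]


def postprocess_events(binary: Sequence[bool]) -> list[tuple[int, int]]:
    """Merge-then-filter rule for model-predicted FOG periods.

    Step 1: FOG periods separated by exactly one non-FOG example are
    combined into a single event (iterated to a fixed point, since a
    merge can create a new one-example gap).  Step 2: remaining events
    just one example long are relabeled non-FOG.  Returns sorted
    half-open index intervals.
    """
    runs = _runs(np.asarray(binary, dtype=bool))
    changed = True
    while changed:
        changed = False
        merged: list[list[int]] = []
        for run in runs:
            if merged and run[0] - merged[-1][1] == 1:
                merged[-1][1] = run[1]
                changed = True
            else:
                merged.append(run)
        runs = merged
    return [(s, e) for s, e in runs if e - s > 1]


def compute_clinical_metrics(
    series: WalkExampleSeries, threshold: float
) -> ClinicalMetrics:
    """Model-derived metrics: threshold, post-process, then summarize."""
    binary = threshold_labels(series.probabilities, threshold)
    events = postprocess_events(binary)
    n_examples = series.probabilities.size
    fog_examples = sum(e - s for s, e in events)
    return ClinicalMetrics(
        percent_time_fog=100.0 * fog_examples / n_examples,
        n_fog_events=len(events),
    )


def ground_truth_metrics(series: WalkExampleSeries) -> ClinicalMetrics:
    """Human-rated metrics, taken as-is (no threshold, no post-processing).

    Events are counted as non-FOG -> FOG transitions; a walk that begins
    frozen counts its leading run as one event.
    """
    truth = series.truth_labels
    return ClinicalMetrics(
        percent_time_fog=100.0 * float(np.mean(truth)),
        n_fog_events=len(_runs(truth)),
    )


def icc_1_1(ratings: np.ndarray) -> ICCResult:
    """ICC(1,1): one-way random effects, single rating, absolute agreement.

    ``ratings`` is an ``(n_targets, k_raters)`` matrix.  The estimate is
    ``(MSB - MSW) / (MSB + (k-1) MSW)`` from the one-way ANOVA
    decomposition; the two-sided 95 % CI comes from F = MSB/MSW with
    (n-1, n(k-1)) degrees of freedom.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D (targets x raters) matrix")
    n, k = x.shape
    if n < 3:
        raise ValueError("need >= 3 targets for ICC")
    if k < 2:
        raise ValueError("need >= 2 raters for ICC")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings contain non-finite values")

    row_means = x.mean(axis=1)
    grand = x.mean()
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((x - row_means[:, None]) ** 2) / (n * (k - 1))

    if msb < 1e-12 and msw < 1e-12:
        # all values identical: agreement is perfect but uninformative
        return ICCResult(1.0, (1.0, 1.0), "excellent", degenerate=True)
    if msw < 1e-12:
        return ICCResult(1.0, (1.0, 1.0), "excellent", degenerate=False)

    est = (msb - msw) / (msb + (k - 1) * msw)
    f_obs = msb / msw
    df1, df2 = n - 1, n * (k - 1)
    f_u = stats.f.ppf(0.975, df1, df2)
    f_l = stats.f.ppf(0.975, df2, df1)
    lower = (f_obs / f_u - 1.0) / (f_obs / f_u + k - 1.0)
    upper = (f_obs * f_l - 1.0) / (f_obs * f_l + k - 1.0)
    ci = (float(lower), float(upper))
    return ICCResult(float(est), ci, classify_icc(ci))


def _band(value: float) -> str:
    if value < 0.50:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value <= 0.90:
        return "good"
    return "excellent"


def classify_icc(ci95: tuple[float, float]) -> str:
    """Reliability class of a 95 % CI; spanning bands gives a range."""
    low, high = _band(ci95[0]), _band(ci95[1])
    if low == high:
        return low
    return f"{low} to {high}"


def _metric_value(m: ClinicalMetrics, metric: str) -> float:
    if metric == "percent_time":
        return m.percent_time_fog
    if metric == "n_events":
        return float(m.n_fog_events)
    raise ValueError(f"unknown metric {metric!r}")


def optimize_threshold(
    series_list: Sequence[WalkExampleSeries],
    metric: str = "percent_time",
) -> tuple[float, ICCResult]:
    """Pick the threshold maximizing a clinical metric's ICC with truth.

    Sweeps the 0.00..1.00 grid (step 0.01); for each threshold forms the
    (n_walks x 2) model-vs-truth ratings matrix and computes ICC(1,1).
    Ties break toward the lower threshold.  Thresholds yielding
    degenerate (all-identical) ratings are skipped; if every threshold
    is degenerate an error reports the diagnostics.
    """
    if len(series_list) < 3:
        raise ValueError("need >= 3 walks to optimize a threshold")
    truth = np.array(
        [_metric_value(ground_truth_metrics(s), metric) for s in series_list]
    )
    best: tuple[float, ICCResult] | None = None
    for thr in THRESHOLD_GRID:
        model = np.array(
            [
                _metric_value(compute_clinical_metrics(s, float(thr)), metric)
                for s in series_list
            ]
        )
        icc = icc_1_1(np.column_stack([truth, model]))
        if icc.degenerate:
            continue
        if best is None or icc.estimate > best[1].estimate:
            best = (float(thr), icc)
    if best is None:
        raise ValueError(
            f"every threshold degenerate for metric {metric!r}: ground-truth "
            f"values {truth.tolist()} are constant and predictions match"
        )
    return best
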