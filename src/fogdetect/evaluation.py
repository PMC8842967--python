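"""Window-level scoring and the sensor-set comparison experiments.

AUROC (probability a random FOG window outranks a random non-FOG
window) and average precision are the window-level scores.  The sensor
experiments train the same model on different IMU subsets over
identical windows — only the channel rows differ, so comparisons are
paired — and apply two selection rules:

* **best technical set** — the subset with the highest mean held-out
  AUROC;
* **minimal set** — the smallest subset whose mean AUROC is within a
  relative tolerance (default 5 %) of the best technical set's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn import metrics as skm

from .signal_io import Cohort, SensorLocation, canonical_order

__all__ = [
    "UndefinedMetricError",
    "auroc",
    "average_precision",
    "SensorSetResult",
    "SetSelection",
    "evaluate_sensor_sets",
    "select_sets",
    "DEFAULT_CANDIDATE_SETS",
]


class UndefinedMetricError(ValueError):
    """A ranking metric is undefined (a class is absent)."""


def _check(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    return labels, scores


def auroc(labels: Sequence[bool], scores: Sequence[float]) -> float:
    """Area under the ROC curve (Mann-Whitney formulation)."""
    labels, scores = _check(labels, scores)
    if labels.all() or not labels.any():
        raise UndefinedMetricError("AUROC undefined: only one class present")
    return float(skm.roc_auc_score(labels, scores))


def average_precision(labels: Sequence[bool], scores: Sequence[float]) -> float:
    """Average precision: sum of (R_k - R_{k-1}) * P_k over the score sweep."""
    labels, scores = _check(labels, scores)
    if not labels.any():
        raise UndefinedMetricError("average precision undefined: no positives")
    return float(skm.average_precision_score(labels, scores))


@dataclass
class SensorSetResult:
    """LOSO summary for one sensor subset."""

    sensor_set: tuple[SensorLocation, ...]
    mean_auroc: float
    sd_auroc: float
    mean_ap: float
    n_folds: int
    per_fold: list = field(default_factory=list, repr=False)

    @property
    def name(self) -> str:
        return "+".join(s.value for s in self.sensor_set)


@dataclass
class SetSelection:
    """The best-technical and minimal sensor sets."""

    best_technical: tuple[SensorLocation, ...]
    minimal: tuple[SensorLocation, ...]
    tolerance_fraction: float
    best_auroc: float
    minimal_auroc: float

    @property
    def relative_gap(self) -> float:
        """(best - minimal) / best, the quantity tested against tolerance."""
        return (self.best_auroc - self.minimal_auroc) / self.best_auroc


#: default candidate subsets: full set, the survey-named combinations,
#: and all singletons
def _default_candidates() -> list[tuple[SensorLocation, ...]]:
    S = SensorLocation
    named: list[tuple[SensorLocation, ...]] = [
        tuple(S),
        (S.LUMBAR, S.ANKLE_L, S.ANKLE_R),
        (S.ANKLE_L, S.ANKLE_R),
        (S.WRIST_L, S.ANKLE_L, S.ANKLE_R),
        (S.WRIST_L, S.ANKLE_L),
    ]
    named.extend((s,) for s in S)
    return named


DEFAULT_CANDIDATE_SETS: list[tuple[SensorLocation, ...]] = _default_candidates()


def evaluate_sensor_sets(
    cohort: Cohort,
    candidate_sets: Iterable[Iterable[SensorLocation | str]],
    cfg,
    window_len_s: float = 2.0,
    stride_s: float | None = None,
    n_repeats: int | None = None,
) -> list[SensorSetResult]:
    """Run the LOSO experiment once per candidate sensor subset.

    Windowing (window length, stride, start grid) is identical across
    subsets — only the channel rows differ — so AUROC comparisons
    between subsets are paired.
    """
    from .fog_net import loso_cv, summarize_folds
    from .windowing import segment

    candidates = [canonical_order(c) for c in candidate_sets]
    available = set(cohort.common_sensors())
    for cand in candidates:
        missing = [s.value for s in cand if s not in available]
        if missing:
            raise ValueError(f"candidate set references absent sensors: {missing}")

    results = []
    for cand in candidates:
        ws = segment(cohort, cand, window_len_s=window_len_s, stride_s=stride_s)
        folds = loso_cv(ws, cfg, n_repeats=n_repeats)
        summary = summarize_folds(folds)
        results.append(
            SensorSetResult(
                sensor_set=cand,
                mean_auroc=summary["mean_auroc"],
                sd_auroc=summary["sd_auroc"],
                mean_ap=summary["mean_ap"],
                n_folds=summary["n_folds"],
                per_fold=folds,
            )
        )
    return results


def select_sets(
    results: Sequence[SensorSetResult], tolerance: float = 0.05
) -> SetSelection:
    """Apply the best-technical and minimal-set rules.

    Best technical = argmax mean AUROC (ties: fewer sensors, then
    lexicographic).  Minimal = smallest set with mean AUROC >=
    (1 - tolerance) * best (ties: higher AUROC).  The tolerance is
    *relative* to the best set's AUROC.
    """
    if not results:
        raise ValueError("no sensor-set results to select from")

    def set_key(r: SensorSetResult):
        return (-r.mean_auroc, len(r.sensor_set), tuple(s.value for s in r.sensor_set))

    best = min(results, key=set_key)
    threshold = (1.0 - tolerance) * best.mean_auroc
    qualifying = [r for r in results if r.mean_auroc >= threshold]
    minimal = min(
        qualifying,
        key=lambda r: (len(r.sensor_set), -r.mean_auroc,
                       tuple(s.value for s in r.sensor_set)),
    )
    return SetSelection(
        best_technical=best.sensor_set,
        minimal=minimal.sensor_set,
        tolerance_fraction=tolerance,
        best_auroc=best.mean_auroc,
        minimal_auroc=minimal.mean_auroc,
    )
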