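"""Predefined study configurations.

``paper_scale_config`` mirrors the cohort shape the generator defaults
emulate (7 participants, 5-14 walks of 90 s at 128 Hz).  The
``desk_scale_*`` helpers define the package's compact experimental
protocol used by the test-suite experiments and the results script: a
4-participant cohort with three 30-s walks each, synthesized directly
at the 64 Hz analysis rate, segmented to ~500 overlapping 2-s windows,
and a model run with a reduced epoch budget.  The synthetic signal is
strongly separable, so the small budget is sufficient for convergence;
the protocol keeps a full sensor-set experiment in the minutes range on
one CPU core.
"""

from __future__ import annotations

import numpy as np

from .evaluation import evaluate_sensor_sets, select_sets
from .fog_net import ModelConfig
from .pipeline import clinical_series_loso
from .signal_io import SensorLocation
from .synthetic import SyntheticConfig, generate_cohort
from .windowing import compute_stride

__all__ = [
    "paper_scale_config",
    "desk_scale_synthetic",
    "desk_scale_clinical_synthetic",
    "desk_scale_model",
    "run_desk_sensor_experiment",
    "run_desk_clinical_study",
    "DESK_TARGET_WINDOWS",
    "DESK_SINGLETONS",
    "DESK_CANDIDATE_SETS",
]

#: overlapping-window target for desk-scale training sets
DESK_TARGET_WINDOWS = 500

S = SensorLocation

#: singleton sensors spanning the informativeness range (for ranking)
DESK_SINGLETONS: tuple[tuple[SensorLocation, ...], ...] = (
    (S.ANKLE_L,),
    (S.LUMBAR,),
    (S.CHEST,),
    (S.WRIST_L,),
    (S.HEAD,),
)

#: desk-scale candidate sets: nested informative sets, the singletons
#: above, and a weak decoy
DESK_CANDIDATE_SETS: tuple[tuple[SensorLocation, ...], ...] = (
    (S.LUMBAR, S.ANKLE_L, S.ANKLE_R),
    (S.ANKLE_L, S.ANKLE_R),
) + DESK_SINGLETONS


def paper_scale_config(seed: int = 0) -> SyntheticConfig:
    """The generator's default cohort shape (real-cohort scale)."""
    return SyntheticConfig(seed=seed)


def desk_scale_synthetic(seed: int = 0) -> SyntheticConfig:
    """Compact cohort for minutes-scale experiments.

    Four participants, three 30-s walks each, synthesized directly at
    the 64 Hz analysis rate.  Freezing propensities span the realistic
    0.20-0.54 range so every participant contributes both classes.
    """
    return SyntheticConfig(
        n_participants=4,
        walks_per_participant=3,
        walk_duration_s=30.0,
        sample_rate=64.0,
        fog_propensity=(0.20, 0.28, 0.45, 0.54),
        seed=seed,
    )


def desk_scale_clinical_synthetic(seed: int = 0) -> SyntheticConfig:
    """Cohort for the clinical-agreement study.

    Walk-level metrics (percent time FOG, event counts) need longer and
    more numerous walks than window-level scores do: four 60-s walks
    per participant give 16 rating targets of 30 examples each, enough
    for a stable ICC.  Training cost is unchanged because the
    overlapping-window target stays at ``DESK_TARGET_WINDOWS``.
    """
    return SyntheticConfig(
        n_participants=4,
        walks_per_participant=4,
        walk_duration_s=60.0,
        sample_rate=64.0,
        fog_propensity=(0.20, 0.28, 0.45, 0.54),
        seed=seed,
    )


def desk_scale_model(seed: int = 0, n_repeats: int = 1) -> ModelConfig:
    """Default architecture with a reduced optimization budget.

    Batches of 32 over ~500 windows give enough Adam updates within 12
    epochs; rotation augmentation is limited to +/- 30 degrees (the
    realistic sensor-mounting variation) because arbitrary full
    rotations need a far larger epoch budget to learn through.
    """
    return ModelConfig(
        batch_size=32,
        max_epochs=12,
        early_stop_patience=6,
        augment_max_angle_rad=float(np.pi / 6),
        n_repeats=n_repeats,
        seed=seed,
    )


def run_desk_sensor_experiment(
    seed: int,
    candidate_sets=DESK_CANDIDATE_SETS,
    tolerance: float = 0.05,
):
    """One desk-scale sensor-set comparison.

    Generates the compact cohort, computes the overlap stride for the
    window target, LOSO-trains one model per candidate set (paired
    windows across sets) and applies the best-technical / minimal-set
    rules.  Returns ``(results, selection)``.
    """
    cohort = generate_cohort(desk_scale_synthetic(seed))
    stride = compute_stride(
        [w.duration_s for w in cohort.walks], 2.0, DESK_TARGET_WINDOWS,
        cohort.sample_rate,
    )
    results = evaluate_sensor_sets(
        cohort,
        candidate_sets,
        desk_scale_model(seed),
        stride_s=stride,
        n_repeats=1,
    )
    return results, select_sets(results, tolerance)


def run_desk_clinical_study(seed: int, sensor_set=(S.ANKLE_L,)):
    """One desk-scale clinical-agreement study.

    LOSO-trains on the clinical cohort, converts held-out window
    probabilities on non-overlapping examples into per-walk metrics and
    optimizes the decision threshold per metric.  Returns
    ``({metric: (threshold, ICCResult)}, series)``.
    """
    from .clinical import optimize_threshold

    cohort = generate_cohort(desk_scale_clinical_synthetic(seed))
    stride = compute_stride(
        [w.duration_s for w in cohort.walks], 2.0, DESK_TARGET_WINDOWS,
        cohort.sample_rate,
    )
    series = clinical_series_loso(
        cohort, sensor_set, desk_scale_model(seed), train_stride_s=stride
    )
    optimized = {
        metric: optimize_threshold(series, metric)
        for metric in ("percent_time", "n_events")
    }
    return optimized, series
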