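"""The FOG window classifier and leave-one-subject-out validation.

A two-layer 1D convolutional network maps a normalized 2-s IMU window
to the probability that its majority label is freezing of gait.  Models
are validated leave-one-subject-out (LOSO): each fold trains on all
participants but one and is scored on the excluded participant, with
early stopping driven by the held-out participant's loss.  Experiments
repeat the whole LOSO loop several times with distinct seeds to average
out training stochasticity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import nn
from .evaluation import UndefinedMetricError, auroc, average_precision
from .windowing import WindowSet, augment_rotation, compute_weights, normalize_windows

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "FoldResult",
    "build_model",
    "train_fold",
    "predict_proba",
    "loso_cv",
    "summarize_folds",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults are the selected configuration of the detector: two conv
    layers of 16 filters with kernel length 17 and 50 % dropout, pool
    length 2, a 10-node dense layer, Adam at 1e-3 with batches of 512.
    """

    n_conv_layers: int = 2
    filters_per_layer: int = 16
    kernel_len: int = 17
    pool_len: int = 2
    dense_units: int = 10
    dropout_rate: float = 0.5
    learning_rate: float = 0.001
    batch_size: int = 512
    max_epochs: int = 100
    early_stop_patience: int = 10
    n_repeats: int = 30
    augment: bool = True
    augment_max_angle_rad: float = np.pi
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "filters_per_layer",
            "kernel_len",
            "pool_len",
            "dense_units",
            "batch_size",
            "max_epochs",
            "early_stop_patience",
            "n_repeats",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_conv_layers != 2:
            raise ValueError("architecture is fixed at two convolutional layers")

    def fold_seed(self, repeat: int, fold: int) -> int:
        """Reproducibility bookkeeping: seed + repeat*1000 + fold index."""
        return (self.seed + repeat * 1000 + fold) % (2**31)


@dataclass
class TrainedModel:
    """A (possibly untrained) window -> FOG-probability predictor."""

    net: nn.ConvNet1D
    config: ModelConfig
    training_history: dict = field(default_factory=dict)

    @property
    def input_spec(self) -> tuple[int, int]:
        return (self.net.n_channels, self.net.n_samples)

    def predict_window(self, window: np.ndarray) -> float:
        """Probability for a single raw ``(n_channels, n_samples)`` window."""
        return float(self.net.predict_proba(normalize_windows(np.asarray(window))))


@dataclass
class FoldResult:
    """Scores of one LOSO fold on its held-out participant."""

    held_out_participant: str
    repeat: int
    window_scores: np.ndarray
    window_labels: np.ndarray
    auroc: float  # NaN when the held-out participant is single-class
    average_precision: float
    walk_ids: np.ndarray | None = None
    start_s: np.ndarray | None = None
    history: dict = field(default_factory=dict, repr=False)


def build_model(cfg: ModelConfig, n_channels: int, n_samples: int,
                seed: int | None = None) -> TrainedModel:
    """Instantiate the network with deterministic initialization."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    net = nn.ConvNet1D(
        n_channels,
        n_samples,
        rng,
        n_filters=cfg.filters_per_layer,
        kernel_len=cfg.kernel_len,
        pool_len=cfg.pool_len,
        dense_units=cfg.dense_units,
        dropout_rate=cfg.dropout_rate,
    )
    return TrainedModel(net=net, config=cfg)


def train_fold(
    train: WindowSet,
    validation: WindowSet,
    cfg: ModelConfig,
    seed: int | None = None,
) -> TrainedModel:
    """Train one fold with per-window weighting and early stopping.

    Training windows are re-augmented with fresh random rotations every
    epoch (raw rotate, then normalize); validation windows are only
    normalized, never augmented.  Weights are computed on the training
    set alone.  Early stopping monitors the validation (held-out
    participant) loss and restores the best parameters.
    """
    overlap = set(train.participants) & set(validation.participants)
    if overlap:
        raise ValueError(f"train/validation share participants: {sorted(overlap)}")
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set contains a single class")
    train = compute_weights(train)
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    model = build_model(cfg, train.n_channels, train.n_samples, seed=seed)
    y_train = train.labels.astype(np.float32)
    w_train = train.weights.astype(np.float32)
    x_val = normalize_windows(validation.data)
    y_val = validation.labels.astype(np.float32)

    def epoch_data(epoch: int):
        if cfg.augment:
            x = augment_rotation(train.data, rng, cfg.augment_max_angle_rad)
        else:
            x = train.data
        return normalize_windows(x), y_train, w_train

    history = nn.train_network(
        model.net,
        epoch_data,
        x_val,
        y_val,
        rng=rng,
        lr=cfg.learning_rate,
        batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs,
        patience=cfg.early_stop_patience,
    )
    model.training_history = history
    return model


def predict_proba(model: TrainedModel, ws: WindowSet) -> np.ndarray:
    """One probability per window (order-preserving, deterministic).

    Windows are normalized here; they must be raw (never augmented).
    """
    if (ws.n_channels, ws.n_samples) != model.input_spec:
        raise ValueError(
            f"window shape ({ws.n_channels}, {ws.n_samples}) does not match "
            f"model input {model.input_spec}"
        )
    return model.net.predict_proba(normalize_windows(ws.data))


def loso_cv(
    ws: WindowSet,
    cfg: ModelConfig,
    n_repeats: int | None = None,
) -> list[FoldResult]:
    """Leave-one-subject-out cross-validation with repeats.

    Every participant is held out exactly once per repeat; repeats
    differ only by their seed offset.  A held-out participant whose
    windows are single-class has no defined AUROC: the fold is recorded
    with NaN metrics and excluded from summaries.
    """
    participants = ws.participants
    if len(participants) < 2:
        raise ValueError("LOSO requires >= 2 participants")
    n_repeats = cfg.n_repeats if n_repeats is None else n_repeats
    results: list[FoldResult] = []
    for repeat in range(n_repeats):
        for fold, participant in enumerate(participants):
            train, held = ws.split_participant(participant)
            seed = cfg.fold_seed(repeat, fold)
            model = train_fold(train, held, cfg, seed=seed)
            scores = predict_proba(model, held)
            try:
                fold_auroc = auroc(held.labels, scores)
                fold_ap = average_precision(held.labels, scores)
            except UndefinedMetricError:
                logger.warning(
                    "fold %s repeat %d: held-out windows single-class; "
                    "metrics recorded as missing",
                    participant,
                    repeat,
                )
                fold_auroc = fold_ap = float("nan")
            logger.info(
                "fold %s repeat %d: %d epochs, AUROC %.3f",
                participant,
                repeat,
                model.training_history.get("stopped_epoch", -1) + 1,
                fold_auroc,
            )
            results.append(
                FoldResult(
                    held_out_participant=participant,
                    repeat=repeat,
                    window_scores=scores,
                    window_labels=held.labels.copy(),
                    auroc=fold_auroc,
                    average_precision=fold_ap,
                    walk_ids=held.walk_ids.copy(),
                    start_s=held.start_s.copy(),
                    history=model.training_history,
                )
            )
    return results


def summarize_folds(results: Sequence[FoldResult]) -> dict:
    """Mean-over-folds then mean-over-repeats AUROC/AP summary."""
    by_repeat: dict[int, list[FoldResult]] = {}
    for r in results:
        by_repeat.setdefault(r.repeat, []).append(r)
    rep_auroc, rep_ap = [], []
    for folds in by_repeat.values():
        aurocs = [f.auroc for f in folds if np.isfinite(f.auroc)]
        aps = [f.average_precision for f in folds if np.isfinite(f.average_precision)]
        if aurocs:
            rep_auroc.append(float(np.mean(aurocs)))
        if aps:
            rep_ap.append(float(np.mean(aps)))
    return {
        "mean_auroc": float(np.mean(rep_auroc)) if rep_auroc else float("nan"),
        "sd_auroc": float(np.std(rep_auroc, ddof=1)) if len(rep_auroc) > 1 else 0.0,
        "mean_ap": float(np.mean(rep_ap)) if rep_ap else float("nan"),
        "n_folds": sum(len(v) for v in by_repeat.values()),
        "n_missing": sum(
            1 for r in results if not np.isfinite(r.auroc)
        ),
    }
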