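"""Frozen desk-scale study conditions and the three federated experiments.

The paper-scale protocol (50 clients, 128/64-unit model, lr 0.001 with 30
local epochs over up to 200 rounds on datasets of tens of thousands of
windows) implies millions of SGD steps. The desk-scale replications here
run on synthetic cohorts roughly three orders of magnitude smaller, so
the optimization budget is rescaled accordingly: a 16/8-unit model,
the paper-scale 30 local epochs per round, 20 communication rounds, and
learning rate 0.1 (compensating the ~1000x reduction in total step
count). These conditions are
fixed here, in one place, and shared by the test suite and the
acceptance script.

Experiments:

* federated vs centralized (matched total epochs),
* plain vs inverse-class-frequency weighted aggregation under a 10:5:1
  class imbalance (minority-class F1),
* homogeneous vs heterogeneous (skew 0.8) client distributions across
  communication rounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .federated import centralized_baseline, run_federated
from .pipeline import simulate_windows
from .rnn import HybridClassifier, TrainConfig
from .synthetic import DEFAULT_REGIMES, SimConfig, partition_clients
from .types import FeatureWindow

__all__ = [
    "DESK_SCALE_ROUNDS",
    "DESK_SCALE_CLIENTS",
    "desk_scale_cohort",
    "imbalanced_cohort",
    "desk_scale_train_config",
    "desk_scale_model",
    "federated_vs_centralized",
    "imbalance_experiment",
    "distribution_experiment",
    "smoothed",
]

DESK_SCALE_ROUNDS = 20
DESK_SCALE_CLIENTS = 8
_DESK_LR = 0.1
_DESK_LOCAL_EPOCHS = 30
_DESK_HIDDEN = (16, 8)
_DESK_SUBJECTS = 10
_DESK_DURATION_S = 90.0
_DESK_BOUT_S = 12.0


def desk_scale_cohort(seed: int) -> SimConfig:
    """The standard 6-class, 10-subject desk-scale cohort."""
    return SimConfig(
        n_subjects=_DESK_SUBJECTS,
        duration_s=_DESK_DURATION_S,
        bout_length_s=_DESK_BOUT_S,
        seed=seed,
    )


#: 10:5:1 imbalance over three activities (minority: running).
IMBALANCE_MIX = {"walking": 10 / 16, "sitting": 5 / 16, "running": 1 / 16}


def imbalanced_cohort(seed: int) -> SimConfig:
    regimes = tuple(r for r in DEFAULT_REGIMES if r.name in IMBALANCE_MIX)
    return SimConfig(
        n_subjects=_DESK_SUBJECTS,
        duration_s=_DESK_DURATION_S,
        bout_length_s=_DESK_BOUT_S,
        regimes=regimes,
        class_mix=dict(IMBALANCE_MIX),
        seed=seed,
    )


def desk_scale_train_config(seed: int, local_epochs: int = _DESK_LOCAL_EPOCHS) -> TrainConfig:
    return TrainConfig(
        learning_rate=_DESK_LR,
        batch_size=32,
        local_epochs=local_epochs,
        seed=seed,
    )


def desk_scale_model(classes: list[str], seed: int) -> HybridClassifier:
    return HybridClassifier(
        n_features=161,
        n_classes=len(classes),
        classes=classes,
        lstm_units=_DESK_HIDDEN[0],
        gru_units=_DESK_HIDDEN[1],
        input_mode="features",
        seed=seed,
    )


def _prepare(config: SimConfig):
    train, val, test, _ = simulate_windows(config)
    classes = sorted({w.label for w in train + val + test})
    return train, val, test, classes


@dataclass
class ComparisonResult:
    federated_accuracy: float
    centralized_accuracy: float
    n_validation: int


def federated_vs_centralized(
    seed: int, rounds: int = DESK_SCALE_ROUNDS
) -> ComparisonResult:
    """Homogeneous federated run vs pooled training with matched epochs."""
    train, val, _, classes = _prepare(desk_scale_cohort(seed))
    model = desk_scale_model(classes, seed)
    shards = partition_clients(
        train, DESK_SCALE_CLIENTS, "homogeneous", seed=seed
    )
    cfg = desk_scale_train_config(seed)
    init = model.init_params(seed)
    fed_params, _ = run_federated(
        model, shards, rounds=rounds, config=cfg, initial_params=init,
        master_seed=seed,
    )
    matched = desk_scale_train_config(
        seed, local_epochs=_DESK_LOCAL_EPOCHS * rounds
    )
    central_params, _ = centralized_baseline(model, train, matched, initial_params=init)
    fed_acc = _accuracy(model, fed_params, val)
    cen_acc = _accuracy(model, central_params, val)
    return ComparisonResult(fed_acc, cen_acc, len(val))


def _accuracy(model: HybridClassifier, params, windows: list[FeatureWindow]) -> float:
    preds = model.predict(params, windows)
    return float(np.mean([p == w.label for p, w in zip(preds, windows)]))


@dataclass
class ImbalanceResult:
    minority_class: str
    minority_f1_plain: float
    minority_f1_weighted: float
    accuracy_plain: float
    accuracy_weighted: float
    minority_val_support: int = 0  # minority windows in the validation set


def imbalance_experiment(seed: int, rounds: int = DESK_SCALE_ROUNDS) -> ImbalanceResult:
    """Plain FedAvg vs weighted FedAvg under the 10:5:1 imbalance.

    Same cohort, same heterogeneous shards, same seeds — only the
    aggregation rule differs between the two arms.
    """
    from .evaluation import compute_metrics

    train, val, _, classes = _prepare(imbalanced_cohort(seed))
    minority = min(
        classes, key=lambda c: sum(1 for w in train if w.label == c)
    )
    model = desk_scale_model(classes, seed)
    shards = partition_clients(train, DESK_SCALE_CLIENTS, "heterogeneous", 0.8, seed=seed)
    cfg = desk_scale_train_config(seed)
    init = model.init_params(seed)
    results = {}
    for agg in ("fedavg", "weighted_fedavg"):
        params, _ = run_federated(
            model, shards, rounds=rounds, config=cfg, aggregation=agg,
            initial_params=init, master_seed=seed,
        )
        preds = model.predict(params, val)
        results[agg] = compute_metrics(preds, [w.label for w in val], classes=classes)
    return ImbalanceResult(
        minority_class=str(minority),
        minority_f1_plain=results["fedavg"].f1[minority],
        minority_f1_weighted=results["weighted_fedavg"].f1[minority],
        accuracy_plain=results["fedavg"].accuracy,
        accuracy_weighted=results["weighted_fedavg"].accuracy,
        minority_val_support=sum(1 for w in val if w.label == minority),
    )


@dataclass
class DistributionResult:
    homogeneous_accuracy: list[float]  # per round
    heterogeneous_accuracy: list[float]


def distribution_experiment(
    seed: int, rounds: int = DESK_SCALE_ROUNDS, skew: float = 0.8
) -> DistributionResult:
    """Homogeneous vs heterogeneous client partitions, same cohort and seeds."""
    train, val, _, classes = _prepare(desk_scale_cohort(seed))
    model = desk_scale_model(classes, seed)
    cfg = desk_scale_train_config(seed)
    init = model.init_params(seed)
    curves = {}
    for mode in ("homogeneous", "heterogeneous"):
        shards = partition_clients(train, DESK_SCALE_CLIENTS, mode, skew, seed=seed)
        _, logs = run_federated(
            model, shards, rounds=rounds, config=cfg, validation_windows=val,
            initial_params=init, master_seed=seed,
        )
        curves[mode] = [log.metrics.accuracy for log in logs]
    return DistributionResult(
        homogeneous_accuracy=curves["homogeneous"],
        heterogeneous_accuracy=curves["heterogeneous"],
    )


def smoothed(series: list[float], window: int = 5) -> list[float]:
    """Moving average over a trailing window (round-series smoother)."""
    x = np.asarray(series, dtype=np.float64)
    if x.size < window:
        return [float(x.mean())]
    kernel = np.ones(window) / window
    return list(np.convolve(x, kernel, mode="valid"))
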