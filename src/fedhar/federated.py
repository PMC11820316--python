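"""Federated training simulation: FedAvg, weighted FedAvg, round loop.

The engine simulates clients in-process. Each communication round the
global parameters are broadcast, every client runs local SGD on its own
shard, and the server aggregates the returned parameters:

* fedavg           — size-weighted average  Theta = sum_j (D_j / D_total) theta_j
* mean             — plain arithmetic mean (the equal-sizes special case)
* weighted_fedavg  — client weights additionally reflect inverse class
                     frequencies: with w_c = D_total / (C * count_c),
                     omega_j  proportional to  sum_c count_{j,c} * w_c,
                     normalized to sum to 1, so clients holding rare
                     classes contribute more to the global model.

Privacy contract: the aggregation path receives only ModelParams and
counts — window contents never leave the shard except into the client's
own local training call.

Reproducibility: a master seed fans out to one child seed per
(round, client) through numpy SeedSequence, so runs are bit-identical
regardless of client execution order.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .evaluation import MetricsReport, compute_metrics
from .params import ModelParams
from .rnn import HybridClassifier, TrainConfig, with_seed
from .types import ClientShard, FeatureWindow

__all__ = [
    "AggregationError",
    "RoundLog",
    "fedavg",
    "mean_aggregate",
    "weighted_fedavg",
    "inverse_class_frequency_weights",
    "client_round_seed",
    "run_federated",
    "centralized_baseline",
]


class AggregationError(ValueError):
    pass


@dataclass
class RoundLog:
    """Per-round record: validation metrics and client loss summary."""

    round_index: int
    metrics: MetricsReport | None
    client_losses: dict[str, float] = field(default_factory=dict)
    wall_time_s: float = 0.0


def _check_manifests(params_list: list[ModelParams]):
    if not params_list:
        raise AggregationError("no client parameters to aggregate")
    manifest = params_list[0].manifest
    for j, p in enumerate(params_list[1:], start=1):
        if p.manifest != manifest:
            raise AggregationError(f"client {j} parameter manifest differs")


def _weighted_sum(params_list: list[ModelParams], weights: np.ndarray) -> ModelParams:
    out = ModelParams()
    for name in params_list[0]:
        out[name] = sum(
            w * p[name] for w, p in zip(weights, params_list)
        )
    return out


def fedavg(params_list: list[ModelParams], sizes: list[int]) -> ModelParams:
    """Size-weighted federated average: Theta = sum_j (D_j/D_total) theta_j."""
    _check_manifests(params_list)
    sizes = np.asarray(sizes, dtype=np.float64)
    if sizes.shape[0] != len(params_list):
        raise AggregationError("one size per client required")
    if np.any(sizes <= 0):
        raise AggregationError("client sizes must be positive")
    return _weighted_sum(params_list, sizes / sizes.sum())


def mean_aggregate(params_list: list[ModelParams]) -> ModelParams:
    """Plain arithmetic mean of client parameters (equal-sizes FedAvg)."""
    _check_manifests(params_list)
    m = len(params_list)
    return _weighted_sum(params_list, np.full(m, 1.0 / m))


def inverse_class_frequency_weights(shards: list[ClientShard]) -> dict[str, float]:
    """w_c = D_total / (C * count_c) from the pooled training class counts."""
    counts: dict[str, int] = {}
    for shard in shards:
        for label, n in shard.class_counts.items():
            counts[label] = counts.get(label, 0) + n
    total = sum(counts.values())
    n_classes = len(counts)
    return {c: total / (n_classes * n) for c, n in counts.items()}


def weighted_fedavg(
    params_list: list[ModelParams],
    shards: list[ClientShard],
    class_weights: dict[str, float] | None = None,
) -> ModelParams:
    """Inverse-class-frequency weighted aggregation (see module docstring).

    With uniform class weights (balanced classes) this reduces exactly to
    size-weighted fedavg.
    """
    _check_manifests(params_list)
    if len(shards) != len(params_list):
        raise AggregationError("one shard per parameter set required")
    if class_weights is None:
        class_weights = inverse_class_frequency_weights(shards)
    observed = set()
    for shard in shards:
        observed.update(shard.class_counts)
    for c, w in class_weights.items():
        if w <= 0:
            raise AggregationError(f"class weight for {c!r} must be positive")
        if c not in observed:
            raise AggregationError(f"class {c!r} has zero global count")
    scores = np.array(
        [
            sum(n * class_weights[c] for c, n in shard.class_counts.items())
            for shard in shards
        ],
        dtype=np.float64,
    )
    return _weighted_sum(params_list, scores / scores.sum())


def client_round_seed(master_seed: int, round_index: int, client_index: int) -> int:
    """Deterministic per-(round, client) child seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(round_index), int(client_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _evaluate(
    model: HybridClassifier, params: ModelParams, windows: list[FeatureWindow]
) -> MetricsReport:
    predictions = model.predict(params, windows)
    return compute_metrics(predictions, [w.label for w in windows], classes=model.classes)


def run_federated(
    model: HybridClassifier,
    clients: list[ClientShard],
    rounds: int,
    config: TrainConfig,
    aggregation: str = "fedavg",
    validation_windows: list[FeatureWindow] | None = None,
    class_weights: dict[str, float] | None = None,
    initial_params: ModelParams | None = None,
    master_seed: int | None = None,
) -> tuple[ModelParams, list[RoundLog]]:
    """Simulate ``rounds`` communication rounds with full participation.

    Per round: broadcast the global parameters, run local training on
    every client (train_local receives only the client's own shard),
    aggregate the returned parameters, evaluate on the validation set,
    and log. Returns the final global parameters and one RoundLog per
    round (round_index 1..rounds).
    """
    if not clients:
        raise AggregationError("no clients")
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    if aggregation not in ("fedavg", "mean", "weighted_fedavg"):
        raise AggregationError(f"unknown aggregation {aggregation!r}")
    master = config.seed if master_seed is None else master_seed
    global_params = (
        initial_params.copy() if initial_params is not None else model.init_params(master)
    )
    if aggregation == "weighted_fedavg" and class_weights is None:
        class_weights = inverse_class_frequency_weights(clients)
    logs: list[RoundLog] = []
    for r in range(1, rounds + 1):
        tic = time.perf_counter()
        locals_: list[ModelParams] = []
        losses: dict[str, float] = {}
        for j, shard in enumerate(clients):
            child = with_seed(config, client_round_seed(master, r, j))
            try:
                updated = model.train_local(global_params, shard, child)
            except Exception as err:
                raise type(err)(f"round {r}, client {shard.client_id}: {err}") from err
            locals_.append(updated)
            losses[shard.client_id] = model.evaluate_loss(updated, shard.windows)
        sizes = [shard.size for shard in clients]
        try:
            if aggregation == "fedavg":
                global_params = fedavg(locals_, sizes)
            elif aggregation == "mean":
                global_params = mean_aggregate(locals_)
            else:
                global_params = weighted_fedavg(locals_, clients, class_weights)
        except AggregationError as err:
            raise AggregationError(f"round {r}: {err}") from err
        metrics = (
            _evaluate(model, global_params, validation_windows)
            if validation_windows
            else None
        )
        logs.append(
            RoundLog(
                round_index=r,
                metrics=metrics,
                client_losses=losses,
                wall_time_s=time.perf_counter() - tic,
            )
        )
    return global_params, logs


def centralized_baseline(
    model: HybridClassifier,
    all_windows: list[FeatureWindow],
    config: TrainConfig,
    validation_windows: list[FeatureWindow] | None = None,
    initial_params: ModelParams | None = None,
) -> tuple[ModelParams, MetricsReport | None]:
    """Train one model on the pooled data with the same protocol."""
    if not all_windows:
        raise AggregationError("no training windows")
    pool = ClientShard(client_id="central", windows=list(all_windows))
    params = (
        initial_params.copy()
        if initial_params is not None
        else model.init_params(config.seed)
    )
    params = model.train_local(params, pool, config)
    metrics = (
        _evaluate(model, params, validation_windows) if validation_windows else None
    )
    return params, metrics
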