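"""Readers, writers, dataset splitting, and run configuration.

The canonical interchange format is a per-subject CSV with the header
``timestamp,ax1,ay1,az1,ax2,ay2,az2,label`` (timestamp in seconds,
accelerations in g); single-sensor files use ``ax1,ay1,az1`` only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import FeatureWindow, SensorStream

__all__ = [
    "ParseError",
    "read_accel_csv",
    "write_accel_csv",
    "write_feature_csv",
    "read_feature_csv",
    "split_dataset",
    "RunConfig",
    "load_run_config",
]

CSV_COLUMNS_6 = ["timestamp", "ax1", "ay1", "az1", "ax2", "ay2", "az2", "label"]
CSV_COLUMNS_3 = ["timestamp", "ax1", "ay1", "az1", "label"]


class ParseError(ValueError):
    pass


def write_accel_csv(stream: SensorStream, path):
    """Write a stream in the documented CSV dialect."""
    path = Path(path)
    n_sensors = stream.n_channels // 3
    cols = CSV_COLUMNS_6 if n_sensors == 2 else CSV_COLUMNS_3
    frame = pd.DataFrame(
        {"timestamp": stream.times, **{
            cols[1 + i]: stream.channels[i] for i in range(stream.n_channels)
        }, "label": stream.labels}
    )
    frame.to_csv(path, index=False, columns=cols, float_format="%.9g")


def read_accel_csv(path, subject_id: str | None = None) -> SensorStream:
    """Parse an accelerometer CSV into a SensorStream.

    Sample rate is inferred from the median timestamp delta;
    non-monotone timestamps are rejected with the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path)
    except Exception as err:
        raise ParseError(f"{path}: {err}") from err
    columns = list(frame.columns)
    if columns == CSV_COLUMNS_6:
        accel_cols = CSV_COLUMNS_6[1:-1]
    elif columns == CSV_COLUMNS_3:
        accel_cols = CSV_COLUMNS_3[1:-1]
    else:
        raise ParseError(
            f"{path}: unexpected header {columns}; want {CSV_COLUMNS_6} or {CSV_COLUMNS_3}"
        )
    if len(frame) < 2:
        raise ParseError(f"{path}: need at least 2 rows")
    for col in ["timestamp"] + accel_cols:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna()
        if bad.any():
            line = int(np.argmax(bad.to_numpy())) + 2  # header is line 1
            raise ParseError(f"{path}: non-numeric {col!r} at line {line}")
        frame[col] = values
    ts = frame["timestamp"].to_numpy(dtype=np.float64)
    deltas = np.diff(ts)
    if np.any(deltas <= 0):
        line = int(np.argmax(deltas <= 0)) + 3
        raise ParseError(f"{path}: non-monotone timestamp at line {line}")
    rate = 1.0 / float(np.median(deltas))
    return SensorStream(
        subject_id=subject_id or path.stem,
        sample_rate=rate,
        channels=frame[accel_cols].to_numpy(dtype=np.float64).T,
        labels=frame["label"].astype(str).to_numpy(),
        start_time=float(ts[0]),
    )


def write_feature_csv(windows: list[FeatureWindow], manifest: list[str], path):
    """Feature matrix CSV: manifest columns plus window_id/subject/label."""
    rows = []
    for w in windows:
        if w.features is None:
            raise ValueError(f"window {w.window_id} has no features")
        rows.append(
            {"window_id": w.window_id, "subject_id": w.subject_id, "label": w.label,
             **dict(zip(manifest, w.features))}
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_feature_csv(path, manifest: list[str]) -> list[FeatureWindow]:
    frame = pd.read_csv(path)
    missing = [c for c in manifest if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing feature columns {missing[:3]}...")
    out = []
    for _, row in frame.iterrows():
        out.append(
            FeatureWindow(
                window_id=int(row["window_id"]),
                subject_id=str(row["subject_id"]),
                label=str(row["label"]),
                features=row[manifest].to_numpy(dtype=np.float64),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Dataset splitting
# ---------------------------------------------------------------------------


def split_dataset(
    windows: list[FeatureWindow],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[list[FeatureWindow], list[FeatureWindow], list[FeatureWindow]]:
    """Subject-stratified train/validation/test split.

    All of one subject's windows land in the same split (preventing
    leakage of within-subject correlation); subjects are dealt greedily
    to the split with the largest remaining deficit. With fewer subjects
    than splits the split degrades to window level with a warning.
    """
    if len(windows) < 3:
        raise ValueError("need at least 3 windows to split")
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    subjects: dict[str, list[FeatureWindow]] = {}
    for w in windows:
        subjects.setdefault(w.subject_id, []).append(w)
    names = sorted(subjects)
    n_needed = sum(1 for f in fractions if f > 0)
    if len(names) < n_needed:
        warnings.warn(
            f"only {len(names)} subjects for {n_needed} splits; "
            "falling back to window-level splitting"
        )
        shuffled = [windows[i] for i in rng.permutation(len(windows))]
        n = len(shuffled)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        return (
            shuffled[:n_train],
            shuffled[n_train : n_train + n_val],
            shuffled[n_train + n_val :],
        )
    order = [names[i] for i in rng.permutation(len(names))]
    total = len(windows)
    splits: list[list[FeatureWindow]] = [[], [], []]
    assigned = [0, 0, 0]
    for name in order:
        deficits = [fractions[k] * total - assigned[k] for k in range(3)]
        k = int(np.argmax(deficits))
        splits[k].extend(subjects[name])
        assigned[k] += len(subjects[name])
    return tuple(splits)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Resolved configuration for one end-to-end run."""

    simulation: dict = field(default_factory=dict)
    preprocessing: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    federated: dict = field(default_factory=dict)
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self):
        self.split_fractions = tuple(self.split_fractions)
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")

    def to_dict(self) -> dict:
        return {
            "simulation": self.simulation,
            "preprocessing": self.preprocessing,
            "model": self.model,
            "training": self.training,
            "federated": self.federated,
            "split_fractions": list(self.split_fractions),
            "seed": self.seed,
        }

    def snapshot(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def load_run_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"config file not found: {path}")
    payload = yaml.safe_load(path.read_text()) or {}
    known = {
        "simulation",
        "preprocessing",
        "model",
        "training",
        "federated",
        "split_fractions",
        "seed",
    }
    unknown = set(payload) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**payload)
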