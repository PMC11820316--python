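"""Core data containers shared across the pipeline."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np


@dataclass
class SensorStream:
    """One subject's continuous multi-channel accelerometer recording.

    channels is [n_channels x T] in g units; either one tri-axial sensor
    (3 rows) or two (6 rows, thigh then lower back). labels has one
    activity string per sample. start_time is the absolute time (seconds)
    of the first sample, used when synchronizing streams.
    """

    subject_id: str
    sample_rate: float
    channels: np.ndarray
    labels: np.ndarray
    start_time: float = 0.0

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.channels.ndim != 2:
            raise ValueError("channels must be a 2-D [n_channels x T] array")
        if self.channels.shape[0] not in (3, 6):
            raise ValueError(
                f"expected 3 or 6 channels (one or two tri-axial sensors), "
                f"got {self.channels.shape[0]}"
            )
        if self.labels.shape[0] != self.channels.shape[1]:
            raise ValueError("labels must have one entry per sample")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate


@dataclass
class FeatureWindow:
    """One segmented window: raw sequence, optional feature vector, label.

    window_id is a stable integer identity so that client partitions can
    be checked for disjointness.
    """

    window_id: int
    subject_id: str
    label: str
    sequence: np.ndarray | None = None  # [L x n_channels] raw samples
    features: np.ndarray | None = None  # length-161 engineered vector

    def __repr__(self):
        return f"FeatureWindow(id={self.window_id}, subject={self.subject_id}, label={self.label})"


@dataclass
class ClientShard:
    """One simulated federated client's local dataset."""

    client_id: str
    windows: list[FeatureWindow] = field(default_factory=list)

    @property
    def size(self) -> int:
        """Number of local samples (D_j in the aggregation formulas)."""
        return len(self.windows)

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(w.label for w in self.windows))

    @property
    def labels(self) -> list[str]:
        return [w.label for w in self.windows]
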