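"""Sliding-window segmentation of synchronized streams.

Windows are half-open sample-index intervals [t1, t2), 0-based, of fixed
length L = round(window_seconds * sample_rate) with step
S = round(L * (1 - overlap)). Each window is labeled by majority vote of
its per-sample labels, with ties broken by the label of the window's
center sample.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .types import FeatureWindow, SensorStream

__all__ = ["Segment", "sliding_windows", "segment_to_feature_window", "window_count"]

DEFAULT_WINDOW_S = 5.0
DEFAULT_OVERLAP = 0.5


@dataclass(frozen=True)
class Segment:
    """One window: half-open [t1, t2) over the stream's sample index."""

    t1: int
    t2: int
    label: str
    window_id: int

    @property
    def length(self) -> int:
        return self.t2 - self.t1


def window_count(n_samples: int, length: int, step: int) -> int:
    """Closed-form number of windows: floor((T - L)/S) + 1 for T >= L."""
    if n_samples < length:
        return 0
    return (n_samples - length) // step + 1


def _majority_label(labels: np.ndarray) -> str:
    counts = Counter(labels.tolist())
    best = max(counts.values())
    winners = {lab for lab, c in counts.items() if c == best}
    if len(winners) == 1:
        return str(next(iter(winners)))
    center = labels[len(labels) // 2]
    if center in winners:
        return str(center)
    return str(sorted(winners)[0])  # deterministic fallback


def sliding_windows(
    stream: SensorStream,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    id_offset: int = 0,
) -> list[Segment]:
    """Cut a stream into fixed-length overlapping windows.

    Streams shorter than one window yield an empty list. window_ids are
    id_offset, id_offset+1, ... in order of strictly increasing t1.
    """
    length = int(round(window_s * stream.sample_rate))
    if length < 8:
        raise ValueError(
            f"window of {window_s} s at {stream.sample_rate} Hz has only "
            f"{length} samples (need >= 8)"
        )
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    step = max(int(round(length * (1.0 - overlap))), 1)
    segments = []
    for k in range(window_count(stream.n_samples, length, step)):
        t1 = k * step
        t2 = t1 + length
        segments.append(
            Segment(
                t1=t1,
                t2=t2,
                label=_majority_label(stream.labels[t1:t2]),
                window_id=id_offset + k,
            )
        )
    return segments


def segment_to_feature_window(stream: SensorStream, segment: Segment) -> FeatureWindow:
    """Materialize a Segment as a FeatureWindow carrying the raw samples."""
    return FeatureWindow(
        window_id=segment.window_id,
        subject_id=stream.subject_id,
        label=segment.label,
        sequence=stream.channels[:, segment.t1 : segment.t2].T.copy(),
    )
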