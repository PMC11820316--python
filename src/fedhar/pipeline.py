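"""End-to-end helpers tying generation, preprocessing and training together."""

from __future__ import annotations

import numpy as np

from .io import split_dataset
from .preprocessing import FeatureScaler, attach_features
from .segmentation import (
    DEFAULT_OVERLAP,
    DEFAULT_WINDOW_S,
    segment_to_feature_window,
    sliding_windows,
)
from .synthetic import SimConfig, generate_dataset
from .types import FeatureWindow, SensorStream

__all__ = ["build_windows", "scale_features", "simulate_windows"]


def build_windows(
    streams: list[SensorStream],
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    with_features: bool = True,
) -> list[FeatureWindow]:
    """Segment every stream and (optionally) attach 161-feature vectors.

    window_ids are globally unique across the pool.
    """
    windows: list[FeatureWindow] = []
    offset = 0
    for stream in streams:
        segments = sliding_windows(stream, window_s, overlap, id_offset=offset)
        windows.extend(segment_to_feature_window(stream, seg) for seg in segments)
        offset += len(segments)
    if with_features:
        attach_features(windows)
    return windows


def scale_features(
    train: list[FeatureWindow],
    *other_splits: list[FeatureWindow],
) -> FeatureScaler:
    """Fit min-max scaling on the training split and apply it everywhere."""
    scaler = FeatureScaler().fit(np.stack([w.features for w in train]))
    for split in (train, *other_splits):
        for w in split:
            w.features = scaler.transform(w.features)
    return scaler


def simulate_windows(
    config: SimConfig,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    split_seed: int | None = None,
):
    """Generate a cohort, extract features, split, and scale.

    Returns (train, validation, test) FeatureWindow lists with scaled
    features, plus the fitted scaler.
    """
    streams = generate_dataset(config)
    windows = build_windows(streams, window_s, overlap)
    seed = config.seed if split_seed is None else split_seed
    train, val, test = split_dataset(windows, fractions, seed=seed)
    scaler = scale_features(train, val, test)
    return train, val, test, scaler
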