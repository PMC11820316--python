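"""Signal preprocessing: synchronization, gravity/movement decomposition,
and the 161-feature window descriptor.

Each accelerometer channel is split into a gravity (orientation) and a
movement (dynamic) component with a zero-phase fourth-order low-pass
Butterworth filter at 1 Hz: gravity is the filtered signal, movement is
the residual, so gravity + movement reconstructs the input exactly.

Per window the pipeline computes, following the fixed manifest:

* 6 axes x (8 gravity statistics + 8 movement statistics)      =  96
* 2 per-sensor vector magnitudes x (8 gravity + 8 movement)    =  32
* pairwise Pearson correlations among the 8 movement signals   =  28
* per-axis cross-sensor gravity means                          =   3
* whole-window vector-magnitude means                          =   2
                                                        total  = 161

Gravity statistics: mean, median, standard deviation (population,
n denominator), coefficient of variation (0 when |mean| < 1e-12), 25th
and 75th percentiles (linear interpolation), minimum, maximum.

Movement statistics: skewness and kurtosis (plain standardized third and
fourth moments, 0 for constant windows), signal energy (sum of squares),
mean and standard deviation of the one-sided unnormalized DFT magnitudes
(DC bin excluded -- DC is gravity leakage by construction), dominant
frequency and its magnitude, and the magnitude-weighted spectral
centroid. All-zero spectra yield 0 for every frequency feature.

All features are min-max scaled to [0, 1] using ranges fitted on the
training split only; unseen values are clipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import signal as sp_signal

from .types import FeatureWindow, SensorStream

__all__ = [
    "SynchronizationError",
    "DecompositionError",
    "FeatureError",
    "ScalerStateError",
    "DecomposedChannel",
    "FeatureVector",
    "FeatureScaler",
    "synchronize",
    "decompose_gravity_movement",
    "gravity_statistics",
    "movement_statistics",
    "cross_sensor_features",
    "extract_feature_vector",
    "feature_manifest",
    "N_FEATURES",
    "BUTTER_ORDER",
    "BUTTER_CUTOFF_HZ",
    "TARGET_RATE_HZ",
]


class SynchronizationError(ValueError):
    pass


class DecompositionError(ValueError):
    pass


class FeatureError(ValueError):
    pass


class ScalerStateError(RuntimeError):
    pass


BUTTER_ORDER = 4
BUTTER_CUTOFF_HZ = 1.0
TARGET_RATE_HZ = 50.0
N_FEATURES = 161

_GRAV_STATS = ("mean", "median", "sd", "cv", "p25", "p75", "min", "max")
_MOV_STATS = (
    "skew",
    "kurtosis",
    "energy",
    "specmag_mean",
    "specmag_sd",
    "dom_freq",
    "dom_mag",
    "spec_centroid",
)
_CHANNELS = ("s1_x", "s1_y", "s1_z", "s2_x", "s2_y", "s2_z")
_MAGNITUDES = ("s1_mag", "s2_mag")
_CORR_SIGNALS = _CHANNELS + _MAGNITUDES


def build_feature_manifest() -> list[str]:
    """Construct the manifest names in canonical order."""
    names: list[str] = []
    for ch in _CHANNELS:
        names += [f"{ch}_grav_{s}" for s in _GRAV_STATS]
        names += [f"{ch}_mov_{s}" for s in _MOV_STATS]
    for mag in _MAGNITUDES:
        names += [f"{mag}_grav_{s}" for s in _GRAV_STATS]
        names += [f"{mag}_mov_{s}" for s in _MOV_STATS]
    for i in range(len(_CORR_SIGNALS)):
        for j in range(i + 1, len(_CORR_SIGNALS)):
            names.append(f"corr_{_CORR_SIGNALS[i]}_{_CORR_SIGNALS[j]}")
    for axis in ("x", "y", "z"):
        names.append(f"grav_cross_mean_{axis}")
    for mag in _MAGNITUDES:
        names.append(f"{mag}_mean")
    return names


def feature_manifest() -> list[str]:
    """The versioned 161-name manifest, loaded from package data."""
    with resources.files("fedhar").joinpath("data/feature_manifest.json").open() as fh:
        payload = json.load(fh)
    return list(payload["features"])


_MANIFEST = build_feature_manifest()
assert len(_MANIFEST) == N_FEATURES


@dataclass
class DecomposedChannel:
    """Gravity + movement split of one channel; components sum to the input."""

    gravity: np.ndarray
    movement: np.ndarray
    sample_rate: float


@dataclass
class FeatureVector:
    """Ordered 161-element descriptor of one window."""

    values: np.ndarray
    manifest: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.manifest),):
            raise FeatureError("values and manifest lengths differ")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.manifest, self.values.tolist()))


# ---------------------------------------------------------------------------
# Synchronization and decomposition
# ---------------------------------------------------------------------------


def synchronize(streams: list[SensorStream], rate: float = TARGET_RATE_HZ) -> SensorStream:
    """Resample overlapping streams onto one common grid and stack them.

    Linear interpolation onto a ``rate``-Hz grid over the interval where
    all streams overlap; channels are stacked in input order; labels come
    from the first (reference) stream by nearest sample.
    """
    if not streams:
        raise SynchronizationError("no streams to synchronize")
    t_start = max(s.start_time for s in streams)
    t_end = min(s.start_time + (s.n_samples - 1) / s.sample_rate for s in streams)
    if t_end <= t_start:
        raise SynchronizationError("streams have no temporal overlap")
    n = int(np.floor((t_end - t_start) * rate)) + 1
    grid = t_start + np.arange(n) / rate
    rows = []
    for s in streams:
        for ch in s.channels:
            rows.append(np.interp(grid, s.times, ch))
    ref = streams[0]
    idx = np.clip(
        np.round((grid - ref.start_time) * ref.sample_rate).astype(int),
        0,
        ref.n_samples - 1,
    )
    return SensorStream(
        subject_id=ref.subject_id,
        sample_rate=rate,
        channels=np.vstack(rows),
        labels=ref.labels[idx],
        start_time=t_start,
    )


def _butter_sos(sample_rate: float):
    return sp_signal.butter(
        BUTTER_ORDER, BUTTER_CUTOFF_HZ, btype="low", fs=sample_rate, output="sos"
    )


def decompose_gravity_movement(channel, sample_rate: float) -> DecomposedChannel:
    """Zero-phase Butterworth low-pass split into gravity and movement.

    Gravity is the forward-backward (zero-phase) filtered channel, so the
    effective magnitude response is the squared 4th-order Butterworth
    response; movement is the residual channel - gravity.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if sample_rate <= 2.0 * BUTTER_CUTOFF_HZ:
        raise DecompositionError(
            f"sample rate {sample_rate} Hz too low for a {BUTTER_CUTOFF_HZ} Hz cutoff"
        )
    if channel.ndim != 1 or channel.size < 3 * BUTTER_ORDER:
        raise DecompositionError(
            f"channel must be 1-D with >= {3 * BUTTER_ORDER} samples"
        )
    try:
        gravity = sp_signal.sosfiltfilt(_butter_sos(sample_rate), channel)
    except ValueError as err:  # too short for the filter's padding
        raise DecompositionError(str(err)) from err
    return DecomposedChannel(
        gravity=gravity, movement=channel - gravity, sample_rate=sample_rate
    )


def zero_phase_response(freqs_hz, sample_rate: float = TARGET_RATE_HZ) -> np.ndarray:
    """Analytic amplitude gain of the zero-phase gravity path.

    The digital Butterworth magnitude response (evaluated on the unit
    circle), squared because the filter runs forward and backward.
    """
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=np.float64))
    _, h = sp_signal.sosfreqz(
        _butter_sos(sample_rate), worN=2 * np.pi * freqs_hz / sample_rate
    )
    return np.abs(h) ** 2


# ---------------------------------------------------------------------------
# Per-window statistics
# ---------------------------------------------------------------------------


def _population_sd(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def gravity_statistics(window) -> dict[str, float]:
    """Orientation statistics of a gravity-component window."""
    x = np.asarray(window, dtype=np.float64)
    if x.size == 0:
        raise FeatureError("empty window")
    mean = float(x.mean())
    sd = _population_sd(x)
    cv = 0.0 if abs(mean) < 1e-12 else sd / abs(mean)
    return {
        "mean": mean,
        "median": float(np.median(x)),
        "sd": sd,
        "cv": cv,
        "p25": float(np.percentile(x, 25)),
        "p75": float(np.percentile(x, 75)),
        "min": float(x.min()),
        "max": float(x.max()),
    }


def movement_statistics(window, sample_rate: float) -> dict[str, float]:
    """Shape and spectral statistics of a movement-component window."""
    x = np.asarray(window, dtype=np.float64)
    if x.size < 8:
        raise FeatureError("movement window must have >= 8 samples")
    mean = x.mean()
    sd = _population_sd(x)
    if sd > 0:
        z = (x - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    else:
        skew = 0.0
        kurt = 0.0
    energy = float(np.sum(x**2))

    mags = np.abs(np.fft.rfft(x))[1:]  # one-sided, DC excluded
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sample_rate)[1:]
    total = mags.sum()
    if mags.size == 0 or total <= 0.0:
        spec = {
            "specmag_mean": 0.0,
            "specmag_sd": 0.0,
            "dom_freq": 0.0,
            "dom_mag": 0.0,
            "spec_centroid": 0.0,
        }
    else:
        k = int(np.argmax(mags))
        spec = {
            "specmag_mean": float(mags.mean()),
            "specmag_sd": _population_sd(mags),
            "dom_freq": float(freqs[k]),
            "dom_mag": float(mags[k]),
            "spec_centroid": float(np.sum(freqs * mags) / total),
        }
    return {"skew": skew, "kurtosis": kurt, "energy": energy, **spec}


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0 when either series is constant."""
    sa, sb = _population_sd(a), _population_sd(b)
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def cross_sensor_features(axes, magnitudes, gravity_axes) -> dict[str, float]:
    """Correlations among the 8 movement signals plus cross-sensor gravity means.

    axes: the 6 movement-component axis series; magnitudes: the 2
    movement-path vector-magnitude series; gravity_axes: the 6 gravity
    series (sensor 1 then sensor 2).
    """
    axes = [np.asarray(a, dtype=np.float64) for a in axes]
    magnitudes = [np.asarray(m, dtype=np.float64) for m in magnitudes]
    gravity_axes = [np.asarray(g, dtype=np.float64) for g in gravity_axes]
    if len(axes) != 6 or len(magnitudes) != 2 or len(gravity_axes) != 6:
        raise FeatureError("expected 6 axes, 2 magnitudes, 6 gravity series")
    lengths = {a.size for a in axes + magnitudes + gravity_axes}
    if len(lengths) != 1 or lengths.pop() < 2:
        raise FeatureError("all series must share one length >= 2")

    signals = axes + magnitudes
    out: dict[str, float] = {}
    for i in range(len(signals)):
        for j in range(i + 1, len(signals)):
            out[f"corr_{_CORR_SIGNALS[i]}_{_CORR_SIGNALS[j]}"] = _safe_corr(
                signals[i], signals[j]
            )
    for axis_idx, axis in enumerate(("x", "y", "z")):
        out[f"grav_cross_mean_{axis}"] = float(
            (gravity_axes[axis_idx].mean() + gravity_axes[3 + axis_idx].mean()) / 2.0
        )
    return out


# ---------------------------------------------------------------------------
# Full 161-feature extraction
# ---------------------------------------------------------------------------


def extract_feature_vector(segment, sample_rate: float = TARGET_RATE_HZ) -> FeatureVector:
    """Compute the full 161-feature descriptor of one two-sensor window.

    ``segment`` may be a FeatureWindow (with its raw [L x 6] sequence), or
    an ndarray shaped [L x 6] or [6 x L]. Deterministic for fixed input.
    """
    if isinstance(segment, FeatureWindow):
        if segment.sequence is None:
            raise FeatureError("FeatureWindow has no raw sequence attached")
        data = np.asarray(segment.sequence, dtype=np.float64).T
    else:
        data = np.asarray(segment, dtype=np.float64)
        if data.ndim != 2:
            raise FeatureError("segment must be 2-D")
        if data.shape[0] != 6 and data.shape[1] == 6:
            data = data.T
    if data.shape[0] != 6:
        raise FeatureError(
            f"expected 6 channels (two tri-axial sensors), got {data.shape[0]}"
        )

    mag1 = np.linalg.norm(data[0:3], axis=0)
    mag2 = np.linalg.norm(data[3:6], axis=0)

    values: dict[str, float] = {}
    movements: list[np.ndarray] = []
    gravities: list[np.ndarray] = []
    for name, channel in zip(_CHANNELS, data):
        dec = decompose_gravity_movement(channel, sample_rate)
        gravities.append(dec.gravity)
        movements.append(dec.movement)
        for stat, val in gravity_statistics(dec.gravity).items():
            values[f"{name}_grav_{stat}"] = val
        for stat, val in movement_statistics(dec.movement, sample_rate).items():
            values[f"{name}_mov_{stat}"] = val

    mag_movements: list[np.ndarray] = []
    for name, series in zip(_MAGNITUDES, (mag1, mag2)):
        dec = decompose_gravity_movement(series, sample_rate)
        mag_movements.append(dec.movement)
        for stat, val in gravity_statistics(dec.gravity).items():
            values[f"{name}_grav_{stat}"] = val
        for stat, val in movement_statistics(dec.movement, sample_rate).items():
            values[f"{name}_mov_{stat}"] = val

    values.update(cross_sensor_features(movements, mag_movements, gravities))
    values["s1_mag_mean"] = float(mag1.mean())
    values["s2_mag_mean"] = float(mag2.mean())

    vec = np.array([values[name] for name in _MANIFEST], dtype=np.float64)
    return FeatureVector(values=vec, manifest=tuple(_MANIFEST))


def attach_features(windows: list[FeatureWindow], sample_rate: float = TARGET_RATE_HZ):
    """Compute and store the 161-vector on each FeatureWindow in place."""
    for w in windows:
        w.features = extract_feature_vector(w, sample_rate).values
    return windows


# ---------------------------------------------------------------------------
# Min-max scaling
# ---------------------------------------------------------------------------


class FeatureScaler:
    """Per-feature min-max scaler fitted on the training split only.

    transform maps x -> (x - min) / (max - min), clipped to [0, 1];
    features constant on the training split map to 0.
    """

    def __init__(self):
        self.minimum: np.ndarray | None = None
        self.maximum: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.minimum is not None

    def fit(self, training_vectors) -> "FeatureScaler":
        mat = np.asarray(training_vectors, dtype=np.float64)
        if mat.ndim == 1:
            mat = mat[None, :]
        if mat.shape[0] < 1:
            raise ScalerStateError("need at least one training vector")
        self.minimum = mat.min(axis=0)
        self.maximum = mat.max(axis=0)
        return self

    def transform(self, vectors) -> np.ndarray:
        if not self.fitted:
            raise ScalerStateError("scaler has not been fitted")
        arr = np.asarray(vectors, dtype=np.float64)
        span = self.maximum - self.minimum
        safe_span = np.where(span > 0, span, 1.0)
        scaled = (arr - self.minimum) / safe_span
        scaled = np.where(span > 0, scaled, 0.0)
        return np.clip(scaled, 0.0, 1.0)

    def fit_transform(self, vectors) -> np.ndarray:
        return self.fit(vectors).transform(vectors)

    def to_json(self, manifest: list[str] | None = None) -> str:
        if not self.fitted:
            raise ScalerStateError("scaler has not been fitted")
        names = manifest or _MANIFEST[: self.minimum.size]
        return json.dumps(
            {
                name: [float(lo), float(hi)]
                for name, lo, hi in zip(names, self.minimum, self.maximum)
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, payload: str) -> "FeatureScaler":
        table = json.loads(payload)
        scaler = cls()
        scaler.minimum = np.array([lo for lo, _ in table.values()], dtype=np.float64)
        scaler.maximum = np.array([hi for _, hi in table.values()], dtype=np.float64)
        return scaler
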