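"""Synthetic wearable-accelerometer data generator.

Emulates the structure of free-living two-sensor (thigh + lower back)
recordings: per-subject continuous streams at 50 Hz, a handful of
activity classes with strong class imbalance, posture-dependent gravity
orientation and gait-dependent sinusoidal oscillation, plus Gaussian
sensor noise. Every stage of the recognition pipeline is testable
against these streams without external downloads.

The model per activity bout, per channel c:

    a_c(t) = g_c + A * sin(2*pi*f*t + phi_bout + psi_c) + eps,  eps ~ N(0, sd^2)

where g is the unit gravity orientation of the sensor (rotated by a
fixed body-placement rotation for the second sensor), f the gait
oscillation frequency (0 for static postures), and psi_c a fixed
per-axis phase offset that decorrelates the three axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ClientShard, FeatureWindow, SensorStream

__all__ = [
    "ActivityRegime",
    "SimConfig",
    "ConfigurationError",
    "PartitionError",
    "DEFAULT_REGIMES",
    "default_config",
    "generate_subject_stream",
    "generate_dataset",
    "partition_clients",
    "class_frequencies",
]


class ConfigurationError(ValueError):
    """Raised when a simulation config violates an invariant."""


class PartitionError(ValueError):
    """Raised when a client partition cannot be formed."""


NYQUIST_50HZ = 25.0

# Fixed rotation applied to the thigh sensor's gravity orientation to get
# the lower-back sensor's orientation: 90 degrees about the x axis. This
# keeps cross-sensor correlation features non-degenerate, mirroring the
# distinct thigh/back placements of body-worn sensor protocols.
_SENSOR2_ROTATION = np.array(
    [[1.0, 0.0, 0.0],
     [0.0, 0.0, -1.0],
     [0.0, 1.0, 0.0]]
)

# Per-axis phase offsets so the three axes of one sensor are not
# perfectly correlated copies of each other.
_AXIS_PHASE = np.array([0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0])

# Second sensor: attenuated oscillation (the lower back moves less than
# the thigh during gait) and a placement phase lag.
_SENSOR2_AMP_FACTOR = 0.6
_SENSOR2_PHASE_LAG = math.pi / 4.0


@dataclass(frozen=True)
class ActivityRegime:
    """Statistical description of one activity class.

    gravity_orientation: unit 3-vector (g projection on the thigh sensor).
    oscillation_freq: gait frequency in Hz (0 for static postures), below
    the 25 Hz Nyquist limit at 50 Hz sampling.
    oscillation_amp and noise_sd are in g units.
    """

    name: str
    gravity_orientation: tuple[float, float, float]
    oscillation_freq: float
    oscillation_amp: float
    noise_sd: float

    def __post_init__(self):
        vec = np.asarray(self.gravity_orientation, dtype=np.float64)
        if vec.shape != (3,):
            raise ConfigurationError(
                f"regime {self.name!r}: gravity_orientation must be a 3-vector"
            )
        if abs(np.linalg.norm(vec) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"regime {self.name!r}: gravity_orientation must have unit norm, "
                f"got norm {np.linalg.norm(vec):.6f}"
            )
        if not (0.0 <= self.oscillation_freq <= NYQUIST_50HZ / 2.0):
            raise ConfigurationError(
                f"regime {self.name!r}: oscillation_freq must be in [0, 12.5] Hz"
            )
        if self.oscillation_amp < 0:
            raise ConfigurationError(f"regime {self.name!r}: oscillation_amp must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError(f"regime {self.name!r}: noise_sd must be >= 0")


def _unit(x, y, z):
    v = np.array([x, y, z], dtype=np.float64)
    v /= np.linalg.norm(v)
    return tuple(v)


#: Six activity classes typical of free-living thigh/back recordings.
#: Orientations are distinct postures; gait frequencies and amplitudes
#: are in the range reported for walking (~2 Hz), running (~2.8 Hz) and
#: cycling cadence (~1.5 Hz); noise floors ~0.02 g for static wear.
DEFAULT_REGIMES: tuple[ActivityRegime, ...] = (
    ActivityRegime("lying", (0.0, 0.0, 1.0), 0.0, 0.0, 0.02),
    ActivityRegime("sitting", _unit(1.0, 1.0, 0.0), 0.0, 0.0, 0.02),
    ActivityRegime("standing", (0.0, 1.0, 0.0), 0.0, 0.0, 0.02),
    ActivityRegime("walking", _unit(0.0, 0.98, 0.2), 2.0, 0.25, 0.05),
    ActivityRegime("running", _unit(0.0, 0.95, 0.31), 2.8, 0.6, 0.08),
    ActivityRegime("cycling", _unit(0.6, 0.8, 0.0), 1.5, 0.3, 0.05),
)

#: Strongly imbalanced class mix, emulating free-living recordings where
#: dynamic activities such as running and cycling are rare.
DEFAULT_CLASS_MIX: dict[str, float] = {
    "lying": 0.12,
    "sitting": 0.25,
    "standing": 0.18,
    "walking": 0.35,
    "running": 0.05,
    "cycling": 0.05,
}


@dataclass
class SimConfig:
    """Simulation conditions for one synthetic cohort."""

    n_subjects: int = 6
    duration_s: float = 600.0
    sample_rate: float = 50.0
    regimes: tuple[ActivityRegime, ...] = DEFAULT_REGIMES
    bout_length_s: float = 30.0
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be > 0")
        if not self.regimes:
            raise ConfigurationError("regimes must be non-empty")
        if self.bout_length_s <= 0:
            raise ConfigurationError("bout_length_s must be > 0")
        names = {r.name for r in self.regimes}
        if set(self.class_mix) != names:
            raise ConfigurationError(
                f"class_mix keys {sorted(self.class_mix)} do not match regime "
                f"names {sorted(names)}"
            )
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class_mix must sum to 1, got {total!r}")
        if any(p < 0 for p in self.class_mix.values()):
            raise ConfigurationError("class_mix probabilities must be >= 0")

    @property
    def regime_by_name(self) -> dict[str, ActivityRegime]:
        return {r.name: r for r in self.regimes}


def default_config(**overrides) -> SimConfig:
    """The package's standard synthetic cohort, with keyword overrides."""
    return SimConfig(**overrides)


MIN_BOUT_S = 2.0


def _bout_schedule(config: SimConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Alternating activity bouts: (label, n_samples) covering the stream.

    Bout lengths are exponential with mean bout_length_s, truncated to
    >= 2 s; labels are drawn from class_mix (never repeating the
    previous label when more than one class has positive probability).
    """
    total = int(round(config.duration_s * config.sample_rate))
    names = [r.name for r in config.regimes]
    probs = np.array([config.class_mix[n] for n in names])
    schedule: list[tuple[str, int]] = []
    filled = 0
    prev = None
    while filled < total:
        label = names[rng.choice(len(names), p=probs)]
        if prev is not None and label == prev and np.count_nonzero(probs) > 1:
            continue
        length_s = max(rng.exponential(config.bout_length_s), MIN_BOUT_S)
        n = min(int(round(length_s * config.sample_rate)), total - filled)
        if n <= 0:
            n = total - filled
        schedule.append((label, n))
        filled += n
        prev = label
    return schedule


def _subject_rng(config: SimConfig, subject_id: str) -> np.random.Generator:
    # Stable per-subject child seed: independent of generation order.
    digest = sum(ord(c) * (31**i) for i, c in enumerate(str(subject_id))) % (2**31)
    return np.random.default_rng([config.seed, digest])


def generate_subject_stream(config: SimConfig, subject_id: str) -> SensorStream:
    """Generate one subject's labeled two-sensor stream.

    Fully reproducible from (config.seed, subject_id).
    """
    config.validate()
    rng = _subject_rng(config, subject_id)
    total = int(round(config.duration_s * config.sample_rate))
    channels = np.zeros((6, total), dtype=np.float64)
    labels = np.empty(total, dtype=object)
    regimes = config.regime_by_name

    pos = 0
    for label, n in _bout_schedule(config, rng):
        regime = regimes[label]
        t = (pos + np.arange(n)) / config.sample_rate
        phi = rng.uniform(0.0, 2.0 * math.pi)
        g1 = np.asarray(regime.gravity_orientation)
        g2 = _SENSOR2_ROTATION @ g1
        for axis in range(3):
            osc = regime.oscillation_amp * np.sin(
                2.0 * math.pi * regime.oscillation_freq * t + phi + _AXIS_PHASE[axis]
            )
            osc2 = _SENSOR2_AMP_FACTOR * regime.oscillation_amp * np.sin(
                2.0 * math.pi * regime.oscillation_freq * t
                + phi
                + _AXIS_PHASE[axis]
                + _SENSOR2_PHASE_LAG
            )
            channels[axis, pos : pos + n] = g1[axis] + osc
            channels[3 + axis, pos : pos + n] = g2[axis] + osc2
        if regime.noise_sd > 0:
            channels[:, pos : pos + n] += rng.normal(0.0, regime.noise_sd, size=(6, n))
        labels[pos : pos + n] = label
        pos += n

    return SensorStream(
        subject_id=str(subject_id),
        sample_rate=config.sample_rate,
        channels=channels,
        labels=np.asarray(labels.tolist()),
    )


def generate_dataset(config: SimConfig) -> list[SensorStream]:
    """Generate the whole cohort (subjects S00, S01, ...)."""
    return [
        generate_subject_stream(config, f"S{idx:02d}") for idx in range(config.n_subjects)
    ]


# ---------------------------------------------------------------------------
# Client partitioning
# ---------------------------------------------------------------------------


def partition_clients(
    windows: list[FeatureWindow],
    n_clients: int,
    mode: str = "homogeneous",
    skew: float = 0.8,
    seed: int = 0,
) -> list[ClientShard]:
    """Split a window pool into disjoint client shards.

    homogeneous: every client gets (up to rounding) the pool's class
    proportions. heterogeneous: each client is dominated by one class
    (about ``skew`` of its samples), with dominant classes assigned
    round-robin so every class appears on some client; the remainder is
    drawn uniformly from the other classes.

    Shards are disjoint and their union is the input pool for all modes.
    """
    if n_clients < 1:
        raise PartitionError("n_clients must be >= 1")
    if not windows:
        raise PartitionError("window pool is empty")
    if n_clients > len(windows):
        raise PartitionError(
            f"cannot split {len(windows)} windows across {n_clients} clients"
        )
    if mode not in ("homogeneous", "heterogeneous"):
        raise PartitionError(f"unknown partition mode {mode!r}")
    if mode == "heterogeneous" and not (0.5 <= skew < 1.0):
        raise PartitionError("skew must be in [0.5, 1.0)")

    rng = np.random.default_rng([seed, n_clients])
    shards = [ClientShard(client_id=f"client{j:02d}") for j in range(n_clients)]

    by_class: dict[str, list[FeatureWindow]] = {}
    for w in windows:
        by_class.setdefault(w.label, []).append(w)
    classes = sorted(by_class)
    for label in classes:
        perm = rng.permutation(len(by_class[label]))
        by_class[label] = [by_class[label][i] for i in perm]

    if mode == "homogeneous":
        # Per-class round-robin deal: every client ends with the pool's
        # proportions up to rounding.
        for offset, label in enumerate(classes):
            for i, w in enumerate(by_class[label]):
                shards[(i + offset) % n_clients].windows.append(w)
    else:
        quota = [len(windows) // n_clients] * n_clients
        for j in range(len(windows) % n_clients):
            quota[j] += 1
        dominant = [classes[j % len(classes)] for j in range(n_clients)]
        # First pass: dominant-class fills. When a class is dominant on
        # several clients its supply is shared evenly between them.
        holders = {c: dominant.count(c) for c in set(dominant)}
        fair_share = {c: len(by_class[c]) // holders[c] for c in holders}
        for j, shard in enumerate(shards):
            want = int(round(skew * quota[j]))
            take = min(want, fair_share[dominant[j]])
            shard.windows.extend(by_class[dominant[j]][:take])
            del by_class[dominant[j]][:take]
        # Second pass: fill to quota round-robin, each client drawing from
        # its currently largest non-dominant class (its own dominant class
        # only when nothing else is left) so no client is starved into a
        # single-class shard.
        needs = [quota[j] - len(shards[j].windows) for j in range(n_clients)]
        while any(n > 0 for n in needs):
            progressed = False
            for j in range(n_clients):
                if needs[j] <= 0:
                    continue
                candidates = [
                    c for c in classes if c != dominant[j] and by_class[c]
                ]
                if candidates:
                    pick = max(candidates, key=lambda c: len(by_class[c]))
                elif by_class[dominant[j]]:
                    pick = dominant[j]
                else:
                    continue
                shards[j].windows.append(by_class[pick].pop())
                needs[j] -= 1
                progressed = True
            if not progressed:
                break
        # Rounding slack, if any, goes round-robin.
        rest = [w for label in classes for w in by_class[label]]
        for i, w in enumerate(rest):
            shards[i % n_clients].windows.append(w)

    assert sum(s.size for s in shards) == len(windows)
    return shards


def class_frequencies(shards: list[ClientShard]) -> pd.DataFrame:
    """Pooled per-class counts and relative frequencies across shards.

    Frequencies sum to 1; these are the inputs to inverse-frequency
    class weighting.
    """
    if not shards:
        raise ValueError("shards must be non-empty")
    counts: dict[str, int] = {}
    for shard in shards:
        for label, n in shard.class_counts.items():
            counts[label] = counts.get(label, 0) + n
    total = sum(counts.values())
    table = pd.DataFrame(
        {
            "count": pd.Series(counts, dtype=int),
            "frequency": pd.Series({k: v / total for k, v in counts.items()}),
        }
    ).sort_index()
    return table
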