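"""Ordered, named collections of model tensors.

ModelParams is the unit of exchange in the federated simulation: clients
send these to the aggregator, never their data. Aggregation requires
identical name/shape manifests across clients.
"""

from __future__ import annotations

import numpy as np


class ModelParams:
    """An ordered mapping of parameter name -> float64 ndarray."""

    def __init__(self, tensors: dict[str, np.ndarray] | None = None):
        self._tensors: dict[str, np.ndarray] = {}
        if tensors:
            for name, value in tensors.items():
                self[name] = value

    def __setitem__(self, name: str, value):
        self._tensors[name] = np.asarray(value, dtype=np.float64)

    def __getitem__(self, name: str) -> np.ndarray:
        return self._tensors[name]

    def __contains__(self, name: str) -> bool:
        return name in self._tensors

    def __iter__(self):
        return iter(self._tensors)

    def __len__(self):
        return len(self._tensors)

    def items(self):
        return self._tensors.items()

    def keys(self):
        return self._tensors.keys()

    def values(self):
        return self._tensors.values()

    @property
    def manifest(self) -> list[tuple[str, tuple[int, ...]]]:
        """Ordered (name, shape) pairs; aggregation compatibility contract."""
        return [(name, tuple(t.shape)) for name, t in self._tensors.items()]

    @property
    def n_parameters(self) -> int:
        return int(sum(t.size for t in self._tensors.values()))

    def copy(self) -> "ModelParams":
        return ModelParams({k: v.copy() for k, v in self._tensors.items()})

    def allclose(self, other: "ModelParams", rtol=1e-12, atol=1e-12) -> bool:
        if self.manifest != other.manifest:
            return False
        return all(
            np.allclose(self[k], other[k], rtol=rtol, atol=atol) for k in self
        )

    def equal(self, other: "ModelParams") -> bool:
        """Bit-identical comparison."""
        if self.manifest != other.manifest:
            return False
        return all(np.array_equal(self[k], other[k]) for k in self)

    def save(self, path):
        """Checkpoint to a single npz archive with the name manifest."""
        np.savez(path, **self._tensors)

    @classmethod
    def load(cls, path) -> "ModelParams":
        with np.load(path) as archive:
            return cls({k: archive[k] for k in archive.files})

    def __repr__(self):
        return f"ModelParams({len(self)} tensors, {self.n_parameters} parameters)"
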