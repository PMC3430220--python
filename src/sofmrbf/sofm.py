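"""Kohonen self-organizing feature map (SOFM) on a rectangular neuron grid.

The map is used here as a clustering device for molecular descriptors: each
descriptor's standardized profile across molecules is one training sample,
and descriptors that end up sharing a winning neuron form one group.  The
competitive rule is the standard negative-Euclidean-distance one,

    n_i = -||p - w_i|| + b_i ,   winner k = argmax_i n_i ,

with biases fixed at zero (no conscience mechanism).  The winner and every
neuron within the current neighborhood radius (Chebyshev distance on grid
coordinates) move toward the sample,

    w_j <- w_j + eta(t) (p - w_j) ,

while the learning rate and radius decay linearly from their initial values
to zero over the training budget:

    eta(N) = eta0 (1 - N/T),   nc(N) = ceil(nc0 (1 - N/T)).

A recursive decay variant (each step shrinks the previous value) is
available behind ``recursive_decay`` for comparison; it decays
super-linearly and is not the default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SOFMConfig",
    "SOFMModel",
    "Partition",
    "init_sofm",
    "winner",
    "decay",
    "update_weights",
    "train_sofm",
    "assign_and_partition",
]


@dataclass(frozen=True)
class SOFMConfig:
    """Training schedule for the map.

    ``grid_rows x grid_cols`` competitive neurons (default 6 x 4 = 24);
    ``eta0`` initial learning rate in (0, 1]; ``nc0`` initial neighborhood
    radius in grid cells; ``max_steps`` total training iterations; ``seed``
    for weight initialization and sample draws.
    """

    grid_rows: int = 6
    grid_cols: int = 4
    eta0: float = 0.9
    #: initial neighborhood radius.  The default 0 (winner-take-all) suits
    #: the package's primary use, clustering ~12 descriptor profiles on a
    #: 24-neuron map: with far fewer samples than neurons, cooperative
    #: neighborhood updates drag spare neurons into tight clusters and
    #: split them.  Use nc0 >= 1 when samples outnumber neurons and a
    #: topology-preserving map is wanted.
    nc0: int = 0
    max_steps: int = 500
    seed: int = 0
    recursive_decay: bool = False

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if not 0.0 < self.eta0 <= 1.0:
            raise ValueError("eta0 must be in (0, 1]")
        if self.nc0 < 0:
            raise ValueError("nc0 must be non-negative")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")

    @property
    def n_neurons(self) -> int:
        return self.grid_rows * self.grid_cols


def _grid_coordinates(rows: int, cols: int) -> np.ndarray:
    """(row, col) per neuron; neuron 0 is bottom-left, indices grow row-major
    toward the top-right, matching the 1..24 numbering of the 6 x 4 map."""
    coords = [(r, c) for r in range(rows) for c in range(cols)]
    return np.asarray(coords, dtype=int)


@dataclass(frozen=True)
class SOFMModel:
    """Trained (or initial) map: one weight row per competitive neuron."""

    weights: np.ndarray  # (n_neurons, input_dim)
    biases: np.ndarray  # (n_neurons,)
    grid_coords: np.ndarray  # (n_neurons, 2)
    config: SOFMConfig
    steps_trained: int = 0

    @property
    def input_dim(self) -> int:
        return self.weights.shape[1]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": {
                "grid_rows": self.config.grid_rows,
                "grid_cols": self.config.grid_cols,
                "eta0": self.config.eta0,
                "nc0": self.config.nc0,
                "max_steps": self.config.max_steps,
                "seed": self.config.seed,
                "recursive_decay": self.config.recursive_decay,
            },
            "steps_trained": self.steps_trained,
            "weights": self.weights.tolist(),
            "biases": self.biases.tolist(),
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "SOFMModel":
        payload = json.loads(text)
        config = SOFMConfig(**payload["config"])
        weights = np.asarray(payload["weights"], dtype=float)
        return cls(
            weights=weights,
            biases=np.asarray(payload["biases"], dtype=float),
            grid_coords=_grid_coordinates(config.grid_rows, config.grid_cols),
            config=config,
            steps_trained=int(payload["steps_trained"]),
        )


class Partition:
    """Label-invariant grouping of names.

    Two partitions are equal iff they induce the same grouping, regardless
    of which neuron index produced each group.
    """

    def __init__(self, groups: Iterable[Iterable[str]]):
        frozen = frozenset(frozenset(g) for g in groups)
        names: list[str] = [n for g in frozen for n in g]
        if any(len(g) == 0 for g in frozen):
            raise ValueError("empty group in partition")
        if len(names) != len(set(names)):
            raise ValueError("groups are not disjoint")
        self._groups = frozen

    @classmethod
    def from_labels(cls, labels: Sequence[int], names: Sequence[str]) -> "Partition":
        """Group names that share a label (e.g. a winning-neuron index)."""
        if len(labels) != len(names):
            raise ValueError("labels and names must be parallel")
        by_label: dict[int, set[str]] = {}
        for lab, name in zip(labels, names):
            by_label.setdefault(int(lab), set()).add(name)
        return cls(by_label.values())

    @property
    def groups(self) -> frozenset[frozenset[str]]:
        return self._groups

    @property
    def names(self) -> frozenset[str]:
        return frozenset(n for g in self._groups for n in g)

    def group_of(self, name: str) -> frozenset[str]:
        for g in self._groups:
            if name in g:
                return g
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self._groups)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self._groups == other._groups

    def __hash__(self) -> int:
        return hash(self._groups)

    def __repr__(self) -> str:
        parts = sorted("{" + ",".join(sorted(g)) + "}" for g in self._groups)
        return f"Partition({'; '.join(parts)})"


def init_sofm(config: SOFMConfig, input_dim: int, rng: np.random.Generator | None = None) -> SOFMModel:
    """Fresh map: weights uniform in [-0.1, 0.1], biases zero."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    weights = rng.uniform(-0.1, 0.1, size=(config.n_neurons, input_dim))
    return SOFMModel(
        weights=weights,
        biases=np.zeros(config.n_neurons),
        grid_coords=_grid_coordinates(config.grid_rows, config.grid_cols),
        config=config,
        steps_trained=0,
    )


def winner(model: SOFMModel, sample: np.ndarray) -> int:
    """Index of the competitive winner; ties resolve to the lowest index."""
    sample = np.asarray(sample, dtype=float)
    if sample.shape != (model.input_dim,):
        raise ValueError(f"sample has shape {sample.shape}, expected ({model.input_dim},)")
    activation = -np.linalg.norm(model.weights - sample, axis=1) + model.biases
    return int(np.argmax(activation))


def decay(eta0: float, nc0: float, step: int, max_steps: int) -> tuple[float, int]:
    """Learning rate and neighborhood radius after ``step`` of ``max_steps``.

    Both shrink linearly from the initial values to zero; the radius is
    rounded up, so it stays at 1 until the final step.
    """
    if step < 0 or step > max_steps:
        raise ValueError("step must satisfy 0 <= step <= max_steps")
    frac = 1.0 - step / max_steps
    eta = eta0 * frac
    nc = int(math.ceil(nc0 * frac)) if nc0 * frac > 0 else 0
    return eta, nc


def update_weights(
    model: SOFMModel, sample: np.ndarray, k: int, nc: int, eta: float
) -> SOFMModel:
    """Move the winner ``k`` and its grid neighborhood toward ``sample``.

    Neighborhood membership is Chebyshev distance <= ``nc`` on grid
    coordinates; rows outside it are untouched.
    """
    sample = np.asarray(sample, dtype=float)
    if not 0 <= k < model.weights.shape[0]:
        raise ValueError(f"winner index {k} out of range")
    if nc < 0:
        raise ValueError("nc must be non-negative")
    cheb = np.max(np.abs(model.grid_coords - model.grid_coords[k]), axis=1)
    mask = cheb <= nc
    weights = model.weights.copy()
    weights[mask] += eta * (sample - weights[mask])
    return replace(model, weights=weights)


def train_sofm(samples: np.ndarray, config: SOFMConfig) -> SOFMModel:
    """Run the full competitive-learning schedule on ``samples`` (Q x R).

    Each iteration draws one sample at random (seeded), finds the winner,
    updates its neighborhood, and decays the learning rate and radius.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 1:
        raise ValueError("samples must be a non-empty Q x R matrix")
    rng = np.random.default_rng(config.seed)
    model = init_sofm(config, samples.shape[1], rng=rng)
    weights = model.weights.copy()
    coords = model.grid_coords
    eta, nc = config.eta0, config.nc0
    for step in range(1, config.max_steps + 1):
        p = samples[rng.integers(0, samples.shape[0])]
        k = int(np.argmax(-np.linalg.norm(weights - p, axis=1) + model.biases))
        cheb = np.max(np.abs(coords - coords[k]), axis=1)
        mask = cheb <= nc
        weights[mask] += eta * (p - weights[mask])
        if config.recursive_decay:
            frac = 1.0 - step / config.max_steps
            eta = eta * frac
            nc = int(math.ceil(nc * frac)) if nc * frac > 0 else 0
        else:
            eta, nc = decay(config.eta0, config.nc0, step, config.max_steps)
    return replace(model, weights=weights, steps_trained=config.max_steps)


def assign_and_partition(
    model: SOFMModel, samples: np.ndarray, names: Sequence[str]
) -> Partition:
    """Group ``names`` by the winning neuron of the parallel sample rows."""
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] != len(names):
        raise ValueError("names must be parallel to sample rows")
    labels = [winner(model, samples[i]) for i in range(samples.shape[0])]
    return Partition.from_labels(labels, names)
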