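"""Self-organizing map used to partition training data into learning subsets.

The map is a 1 x c line of prototype vectors so that the number of map units
equals the number of clusters requested downstream.  Training is the classic
online rule: draw a sample, find the best-matching unit (BMU, the nearest
prototype in Euclidean distance), and pull every prototype toward the sample
with a Gaussian neighborhood weight around the BMU.  Learning rate decays
linearly to zero and the neighborhood radius linearly to 0.5 grid units over
the run.  All randomness flows from an explicit seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ParameterError


@dataclass
class SOMModel:
    prototypes: np.ndarray  # (c, d)
    grid: np.ndarray  # (c,) unit coordinates on the 1 x c line
    d: int
    trained: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.prototypes.shape[0] != self.grid.shape[0]:
            raise ParameterError("one grid coordinate per prototype required")
        if not np.all(np.isfinite(self.prototypes)):
            raise ParameterError("non-finite prototype")
        if self.prototypes.shape[1] != self.d:
            raise ParameterError("prototype dimension disagrees with d")

    @property
    def n_units(self) -> int:
        return int(self.prototypes.shape[0])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "prototypes": self.prototypes.tolist(),
                    "grid": self.grid.tolist(),
                    "d": self.d,
                    "trained": self.trained,
                    "rng_seed": self.rng_seed,
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "SOMModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            prototypes=np.array(obj["prototypes"], dtype=float),
            grid=np.array(obj["grid"], dtype=float),
            d=int(obj["d"]),
            trained=bool(obj["trained"]),
            rng_seed=int(obj["rng_seed"]),
        )


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-sample BMU index in [0, c)
    c: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.c):
            raise ParameterError("cluster label out of range")

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)


def find_bmu(model: SOMModel, x: np.ndarray) -> int:
    """Index of the prototype nearest to ``x``; ties go to the lowest index."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.d,):
        raise ParameterError(f"expected a length-{model.d} vector, got shape {x.shape}")
    dists = np.linalg.norm(model.prototypes - x, axis=1)
    return int(np.argmin(dists))


def quantization_error(model: SOMModel, data: np.ndarray) -> float:
    """Mean Euclidean distance of each sample to its BMU."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    d2 = np.linalg.norm(data[:, None, :] - model.prototypes[None, :, :], axis=2)
    return float(d2.min(axis=1).mean())


def train_som(
    data: np.ndarray,
    c: int,
    epochs: int = 20,
    lr0: float = 0.5,
    sigma0: float | None = None,
    seed: int = 0,
) -> SOMModel:
    """Train a 1 x c map by seeded online competitive learning.

    Prototypes are initialized by sampling ``c`` distinct data rows.  One
    epoch visits ``n`` randomly drawn samples; over the whole run the
    learning rate decays linearly from ``lr0`` to 0 and the Gaussian
    neighborhood radius from ``sigma0`` (default c/2) to 0.5.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n, d = data.shape
    if n == 0:
        raise ParameterError("empty training data")
    if c < 1:
        raise ParameterError("c must be >= 1")
    if c > n:
        raise ParameterError(f"c={c} exceeds the number of samples n={n}")
    if epochs < 1:
        raise ParameterError("epochs must be >= 1")
    if sigma0 is None:
        sigma0 = max(c / 2.0, 0.5)

    rng = np.random.default_rng(seed)
    init_rows = rng.choice(n, size=c, replace=False)
    prototypes = data[init_rows].copy()
    grid = np.arange(c, dtype=float)

    total = epochs * n
    order = rng.integers(0, n, size=total)
    for t, row in enumerate(order):
        frac = t / total
        lr = lr0 * (1.0 - frac)
        sigma = sigma0 + (0.5 - sigma0) * frac
        x = data[row]
        bmu = int(np.argmin(np.linalg.norm(prototypes - x, axis=1)))
        if frac < 0.9:
            h = np.exp(-((grid - grid[bmu]) ** 2) / (2.0 * sigma**2))
            prototypes += lr * h[:, None] * (x - prototypes)
        else:
            # fine-tuning phase: BMU-only updates let each prototype settle
            # at the centroid of its receptive field, removing the shrinkage
            # bias the Gaussian neighborhood would otherwise leave behind
            prototypes[bmu] += lr * (x - prototypes[bmu])

    return SOMModel(prototypes=prototypes, grid=grid, d=d, trained=True, rng_seed=seed)


def assign_clusters(model: SOMModel, data: np.ndarray) -> ClusterAssignment:
    """BMU index of every sample; deterministic given the model."""
    if not model.trained:
        raise ParameterError("model is not trained")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[1] != model.d:
        raise ParameterError(
            f"data dimension {data.shape[1]} does not match model d={model.d}"
        )
    d2 = np.linalg.norm(data[:, None, :] - model.prototypes[None, :, :], axis=2)
    return ClusterAssignment(labels=d2.argmin(axis=1), c=model.n_units)
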