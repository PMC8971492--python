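"""Self-organizing map overclustering.

An online Kohonen SOM on a rectangular grid partitions cells into
phenotypically homogeneous nodes; batch adjustment is then performed within
each node independently.  The default 8 x 8 grid yields 64 clusters — a
deliberate overclustering, which is what lets the location/scale adjustment
assume near-homogeneous cell populations within each cluster.

Training hyperparameters (10 passes over the data, learning rate decaying
linearly 0.05 -> 0.01, Gaussian neighborhood whose radius shrinks linearly
from half the larger grid dimension to 0.5) are conventional online-SOM
defaults; they are configurable and recorded on the model because the
partition — and hence downstream numbers — depends on them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .dataset import ValidationError
from .normalization import NormalizedMatrix


@dataclass
class SOMModel:
    """Trained map: codebook of node prototypes plus the training recipe."""

    codebook: np.ndarray  # (grid_x * grid_y) x markers
    grid_x: int
    grid_y: int
    rng_seed: int
    training_params: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.grid_x * self.grid_y

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "grid_x": self.grid_x,
                    "grid_y": self.grid_y,
                    "rng_seed": self.rng_seed,
                    "training_params": self.training_params,
                    "codebook": self.codebook.tolist(),
                }
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SOMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            codebook=np.asarray(d["codebook"], dtype=float),
            grid_x=d["grid_x"],
            grid_y=d["grid_y"],
            rng_seed=d["rng_seed"],
            training_params=d["training_params"],
        )


@njit(cache=True)
def _train_loop(codebook, data, order, lrs, sigmas, grid_y):  # pragma: no cover
    n_nodes, m = codebook.shape
    for t in range(order.shape[0]):
        x = data[order[t]]
        best = 0
        best_d = 1e300
        for k in range(n_nodes):
            d = 0.0
            for j in range(m):
                diff = codebook[k, j] - x[j]
                d += diff * diff
            if d < best_d:
                best_d = d
                best = k
        bi = best // grid_y
        bj = best % grid_y
        lr = lrs[t]
        denom = 2.0 * sigmas[t] * sigmas[t]
        for k in range(n_nodes):
            gi = k // grid_y
            gj = k % grid_y
            g2 = (gi - bi) * (gi - bi) + (gj - bj) * (gj - bj)
            w = lr * np.exp(-g2 / denom)
            if w > 1e-12:
                for j in range(m):
                    codebook[k, j] += w * (x[j] - codebook[k, j])


def train_som(
    values: NormalizedMatrix | np.ndarray,
    grid_x: int = 8,
    grid_y: int = 8,
    seed: int = 0,
    epochs: int = 10,
    lr_initial: float = 0.05,
    lr_final: float = 0.01,
) -> SOMModel:
    """Train a SOM; fully deterministic given (values, grid, seed).

    The codebook is initialized from data rows sampled with the seed; the
    presentation order is reshuffled each epoch from the same generator.
    """
    data = values.values if isinstance(values, NormalizedMatrix) else np.asarray(values)
    data = np.ascontiguousarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] == 0 or data.shape[1] == 0:
        raise ValidationError("training data must be a non-empty 2-D matrix")
    n, m = data.shape
    n_nodes = grid_x * grid_y
    if grid_x < 1 or grid_y < 1:
        raise ValidationError("grid dimensions must be positive")
    if n < n_nodes:
        warnings.warn(
            f"{n} cells for {n_nodes} nodes; partition will be sparse",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    init_idx = rng.choice(n, size=n_nodes, replace=n < n_nodes)
    codebook = data[init_idx].copy()

    total = epochs * n
    t = np.arange(total, dtype=float) / max(total - 1, 1)
    lrs = lr_initial + (lr_final - lr_initial) * t
    sigma0 = max(grid_x, grid_y) / 2.0
    sigmas = sigma0 + (0.5 - sigma0) * t
    order = np.concatenate([rng.permutation(n) for _ in range(epochs)])

    _train_loop(codebook, data, order, lrs, sigmas, grid_y)
    if not np.all(np.isfinite(codebook)):
        raise RuntimeError("SOM training produced non-finite codebook")
    return SOMModel(
        codebook=codebook,
        grid_x=grid_x,
        grid_y=grid_y,
        rng_seed=seed,
        training_params={
            "epochs": epochs,
            "lr_initial": lr_initial,
            "lr_final": lr_final,
            "sigma_initial": sigma0,
            "sigma_final": 0.5,
            "neighborhood": "gaussian",
            "topology": "rectangular",
        },
    )


def assign_nodes(
    model: SOMModel, values: NormalizedMatrix | np.ndarray
) -> np.ndarray:
    """Label each cell with its Euclidean-nearest node, 1-based.

    Ties break to the lowest node index.  Labels align row-for-row with the
    input matrix.
    """
    data = values.values if isinstance(values, NormalizedMatrix) else np.asarray(values)
    if data.shape[1] != model.codebook.shape[1]:
        raise ValidationError(
            f"data has {data.shape[1]} markers, codebook {model.codebook.shape[1]}"
        )
    cb = model.codebook
    cb_sq = np.einsum("ij,ij->i", cb, cb)
    labels = np.empty(data.shape[0], dtype=np.int64)
    chunk = 65536
    for lo in range(0, data.shape[0], chunk):
        block = data[lo : lo + chunk]
        d2 = cb_sq[None, :] - 2.0 * block @ cb.T  # + ||x||^2, constant per row
        labels[lo : lo + block.shape[0]] = np.argmin(d2, axis=1)
    return labels + 1


def partition(
    values: NormalizedMatrix | np.ndarray,
    grid_x: int = 8,
    grid_y: int = 8,
    seed: int = 0,
    **train_kwargs,
) -> tuple[SOMModel, np.ndarray]:
    """Train and assign in one step; returns (model, 1-based labels)."""
    model = train_som(values, grid_x=grid_x, grid_y=grid_y, seed=seed, **train_kwargs)
    return model, assign_nodes(model, values)
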