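"""Per-batch marker normalization used to make batches co-clusterable.

Two methods are offered, mirroring the two regimes of cross-batch
variability:

* ``scale`` — per-batch Z-scores; appropriate when batches come from the
  same instrument/panel and differ modestly.
* ``rank`` — per-batch average-tie ranks scaled to (0, 1]; robust to
  arbitrary monotone distortions, appropriate for cross-instrument or
  cross-platform integration.

Normalized values feed the SOM partition only; the correction itself always
operates on the original ArcSinh-scale expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .dataset import CytometryDataset, ValidationError


@dataclass
class NormalizedMatrix:
    """Normalized values row-aligned with the source dataset."""

    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        if self.method not in ("scale", "rank"):
            raise ValidationError(f"unknown normalization method {self.method!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _batch_slices(batches: np.ndarray):
    for b in np.unique(batches.astype(str)):
        yield np.flatnonzero(batches.astype(str) == b)


def normalize_zscore(dataset: CytometryDataset) -> NormalizedMatrix:
    """Z-score each marker within each batch (sd with n-1 denominator).

    Markers that are constant within a batch — including batches of a
    single cell — map to zeros there.
    """
    if dataset.n_cells == 0:
        raise ValidationError("empty dataset")
    out = np.zeros_like(dataset.expression)
    for rows in _batch_slices(dataset.batches):
        block = dataset.expression[rows]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1) if len(rows) > 1 else np.zeros(block.shape[1])
        safe = np.where(sd > 0, sd, 1.0)
        out[rows] = np.where(sd > 0, (block - mu) / safe, 0.0)
    return NormalizedMatrix(values=out, method="scale")


def normalize_rank(dataset: CytometryDataset) -> NormalizedMatrix:
    """Replace each marker by its within-batch average-tie rank / n.

    Output lies in (0, 1] and is invariant to any strictly increasing
    transform of a batch's marker, which is what makes rank normalization
    suitable for cross-platform integration.
    """
    if dataset.n_cells == 0:
        raise ValidationError("empty dataset")
    out = np.zeros_like(dataset.expression)
    for rows in _batch_slices(dataset.batches):
        block = dataset.expression[rows]
        out[rows] = rankdata(block, axis=0, method="average") / len(rows)
    return NormalizedMatrix(values=out, method="rank")


def normalize(dataset: CytometryDataset, method: str) -> NormalizedMatrix:
    if method == "scale":
        return normalize_zscore(dataset)
    if method == "rank":
        return normalize_rank(dataset)
    raise ValidationError(f"unknown normalization method {method!r}")
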