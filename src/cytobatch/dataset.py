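"""In-memory containers for multi-sample cytometry expression data.

The central object is :class:`CytometryDataset`: a cells x markers matrix on
the ArcSinh scale together with per-cell metadata (sample, batch, optional
condition).  All pipeline stages operate on this container and preserve cell
order, so row ``i`` refers to the same cell everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ("sample_id", "batch_id", "condition", "original_index")


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass
class RawSample:
    """A single sample's raw event matrix as read from an FCS file.

    Parameters
    ----------
    events
        Raw channel intensities, one row per event (events x channels).
    channel_names
        Canonical channel keys (FCS short parameter names, ``$PnN``).
    marker_names
        Optional display names (FCS stain names, ``$PnS``); aligned with
        ``channel_names``.
    source_path
        Where the sample was read from, if anywhere.
    """

    events: np.ndarray
    channel_names: list[str]
    marker_names: list[str] | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2:
            raise ValidationError("events must be a 2-D matrix")
        if self.events.shape[1] != len(self.channel_names):
            raise ValidationError(
                f"{self.events.shape[1]} columns but "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")
        if self.events.size and not np.all(np.isfinite(self.events)):
            raise ValidationError("event intensities must be finite")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]


@dataclass
class CytometryDataset:
    """Cells x markers expression on the ArcSinh scale plus cell metadata.

    ``cell_meta`` is a DataFrame aligned row-for-row with ``expression`` and
    carries at least ``sample_id``, ``batch_id``, ``condition`` (may be all
    None) and ``original_index`` (stable identity of each cell within its
    source sample).  ``is_imputed`` is a cells x markers boolean mask set by
    panel merging; imputed entries may be NaN (the missing-value sentinel)
    when too few donor cells were available.
    """

    expression: np.ndarray
    marker_names: list[str]
    cell_meta: pd.DataFrame
    transform_record: dict = field(default_factory=dict)
    is_imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        if self.expression.ndim != 2:
            raise ValidationError("expression must be a 2-D matrix")
        if self.expression.shape[1] != len(self.marker_names):
            raise ValidationError("marker name count must match column count")
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValidationError("marker names must be unique")
        if len(self.cell_meta) != self.expression.shape[0]:
            raise ValidationError("cell_meta must have one row per cell")
        self.cell_meta = self.cell_meta.reset_index(drop=True)
        for col in META_COLUMNS:
            if col not in self.cell_meta.columns:
                if col == "condition":
                    self.cell_meta[col] = None
                elif col == "original_index":
                    self.cell_meta[col] = np.arange(len(self.cell_meta))
                else:
                    raise ValidationError(f"cell_meta missing column {col!r}")
        if self.cell_meta["batch_id"].isna().any():
            raise ValidationError("every cell must have a batch_id")
        self.validate(allow_missing=self.is_imputed is not None)

    # -- invariants ---------------------------------------------------------

    def validate(self, allow_missing: bool = False) -> None:
        """Check value finiteness; NaN allowed only at imputed positions."""
        finite = np.isfinite(self.expression)
        if finite.all():
            return
        if not allow_missing:
            raise ValidationError("expression contains non-finite values")
        bad = ~finite
        if np.isinf(self.expression[bad]).any():
            raise ValidationError("expression contains infinite values")
        if self.is_imputed is None or np.any(bad & ~self.is_imputed):
            raise ValidationError(
                "NaN values outside the imputed mask are not allowed"
            )

    # -- basic accessors ----------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_markers(self) -> int:
        return self.expression.shape[1]

    @property
    def batches(self) -> np.ndarray:
        return self.cell_meta["batch_id"].to_numpy()

    @property
    def conditions(self) -> np.ndarray:
        return self.cell_meta["condition"].to_numpy()

    def batch_ids(self) -> list:
        """Distinct batch labels in first-appearance order."""
        return list(pd.unique(self.cell_meta["batch_id"]))

    def has_conditions(self) -> bool:
        return self.cell_meta["condition"].notna().any()

    def copy(self) -> "CytometryDataset":
        return CytometryDataset(
            expression=self.expression.copy(),
            marker_names=list(self.marker_names),
            cell_meta=self.cell_meta.copy(),
            transform_record=dict(self.transform_record),
            is_imputed=None if self.is_imputed is None else self.is_imputed.copy(),
        )

    def subset(self, rows: np.ndarray) -> "CytometryDataset":
        """Row subset preserving metadata alignment."""
        return CytometryDataset(
            expression=self.expression[rows],
            marker_names=list(self.marker_names),
            cell_meta=self.cell_meta.iloc[np.atleast_1d(rows)].reset_index(drop=True),
            transform_record=dict(self.transform_record),
            is_imputed=None if self.is_imputed is None else self.is_imputed[rows],
        )

    def marker_index(self, marker: str) -> int:
        try:
            return self.marker_names.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in dataset") from None

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: marker columns followed by metadata columns."""
        df = pd.DataFrame(self.expression, columns=self.marker_names)
        for col in META_COLUMNS:
            df[col] = self.cell_meta[col].to_numpy()
        return df

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, transform_record: dict | None = None
    ) -> "CytometryDataset":
        markers = [c for c in df.columns if c not in META_COLUMNS]
        meta = pd.DataFrame(
            {
                col: df[col].to_numpy()
                if col in df.columns
                else ([None] * len(df) if col == "condition" else np.arange(len(df)))
                for col in META_COLUMNS
            }
        )
        if "sample_id" not in df.columns or "batch_id" not in df.columns:
            raise ValidationError("table needs sample_id and batch_id columns")
        return cls(
            expression=df[markers].to_numpy(dtype=float),
            marker_names=markers,
            cell_meta=meta,
            transform_record=transform_record or {},
        )


def concatenate(datasets: list[CytometryDataset]) -> CytometryDataset:
    """Stack datasets sharing the same marker set (same order required)."""
    if not datasets:
        raise ValidationError("nothing to concatenate")
    names = datasets[0].marker_names
    for ds in datasets[1:]:
        if ds.marker_names != names:
            raise ValidationError("marker sets differ between datasets")
    masks = None
    if any(ds.is_imputed is not None for ds in datasets):
        masks = np.vstack(
            [
                ds.is_imputed
                if ds.is_imputed is not None
                else np.zeros(ds.expression.shape, dtype=bool)
                for ds in datasets
            ]
        )
    return CytometryDataset(
        expression=np.vstack([ds.expression for ds in datasets]),
        marker_names=list(names),
        cell_meta=pd.concat([ds.cell_meta for ds in datasets], ignore_index=True),
        transform_record=dict(datasets[0].transform_record),
        is_imputed=masks,
    )
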