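"""End-to-end batch correction.

Order of operations: validate the study design, normalize per batch (for
clustering only), partition cells with a SOM, run the empirical Bayes
adjustment per cluster on the *original* ArcSinh values, then cap each
marker to the global range of the input.  Corrected output preserves cell
count, order, marker names and metadata exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataset import CytometryDataset, ValidationError
from .empirical_bayes import ConfoundedDesignError, combat_cluster
from .normalization import normalize
from .som_partition import assign_nodes, train_som


@dataclass
class CorrectionConfig:
    """Knobs of the correction workflow.

    ``norm_method`` is ``"scale"`` (per-batch Z-scores) for similar batches
    or ``"rank"`` for cross-platform integration.  ``covariate`` names a
    ``cell_meta`` column whose effect must be preserved (e.g., condition).
    ``mean_only`` restricts the adjustment to batch locations.
    """

    norm_method: str = "scale"
    grid_x: int = 8
    grid_y: int = 8
    covariate: str | None = None
    seed: int = 0
    mean_only: bool = False
    cap: bool = True

    def __post_init__(self) -> None:
        if self.norm_method not in ("scale", "rank"):
            raise ValidationError(f"invalid norm_method {self.norm_method!r}")
        if self.grid_x < 2 or self.grid_y < 2:
            raise ValidationError("grid dimensions must be >= 2")


@dataclass
class DesignReport:
    passed: bool
    n_batches: int
    messages: list[str] = field(default_factory=list)
    offending_batches: list = field(default_factory=list)


class DesignError(ValueError):
    """The batch/condition design cannot be corrected."""


def check_design(
    dataset: CytometryDataset,
    covariate: str | None = None,
    raise_on_fail: bool = True,
) -> DesignReport:
    """Validate that batch effects are estimable and not confounded.

    Requires at least two batches.  With a covariate, at least one of each
    batch's conditions must also be present in some other batch; a batch
    whose conditions appear nowhere else is fully confounded with its
    condition and cannot be corrected without destroying the biology.
    """
    batch_ids = dataset.batch_ids()
    messages: list[str] = []
    offending: list = []
    passed = True
    if len(batch_ids) < 2:
        passed = False
        messages.append(f"need >= 2 batches, found {len(batch_ids)}")
    if covariate is not None and passed:
        if covariate not in dataset.cell_meta.columns:
            raise ValidationError(f"covariate column {covariate!r} not in cell_meta")
        col = dataset.cell_meta[covariate]
        if col.isna().any():
            passed = False
            messages.append(f"covariate {covariate!r} has missing values")
        else:
            by_batch = {
                b: set(col[dataset.cell_meta["batch_id"] == b]) for b in batch_ids
            }
            for b in batch_ids:
                others = set().union(
                    *(by_batch[o] for o in batch_ids if o != b)
                )
                if not by_batch[b] & others:
                    passed = False
                    offending.append(b)
                    messages.append(
                        f"batch {b!r} shares no condition with any other batch "
                        f"(its conditions: {sorted(by_batch[b])})"
                    )
    report = DesignReport(
        passed=passed,
        n_batches=len(batch_ids),
        messages=messages,
        offending_batches=offending,
    )
    if raise_on_fail and not passed:
        raise DesignError("; ".join(messages))
    return report


def create_partition(dataset: CytometryDataset, config: CorrectionConfig) -> np.ndarray:
    """Normalize per batch, train the SOM, return 1-based node labels.

    Labels refer to rows of the original expression matrix; the normalized
    values exist only for this clustering step.
    """
    norm = normalize(dataset, config.norm_method)
    model = train_som(
        norm, grid_x=config.grid_x, grid_y=config.grid_y, seed=config.seed
    )
    return assign_nodes(model, norm)


def batch_correct(
    dataset: CytometryDataset,
    labels: np.ndarray,
    config: CorrectionConfig,
) -> tuple[CytometryDataset, list[dict]]:
    """Apply the per-cluster adjustment and cap to the input range.

    Clusters are processed in ascending node index; they are statistically
    independent, so the order is cosmetic.  Capping uses each marker's
    global min/max over the whole input dataset.
    """
    labels = np.asarray(labels)
    if len(labels) != dataset.n_cells:
        raise ValidationError("labels not aligned with dataset rows")
    covariates = (
        dataset.cell_meta[config.covariate].to_numpy()
        if config.covariate is not None
        else None
    )
    corrected = dataset.expression.copy()
    cluster_log: list[dict] = []
    for node in np.unique(labels):
        rows = np.flatnonzero(labels == node)
        cov = covariates[rows] if covariates is not None else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            y_star, rep = combat_cluster(
                dataset.expression[rows],
                dataset.batches[rows],
                covariates=cov,
                mean_only=config.mean_only,
            )
        corrected[rows] = y_star
        cluster_log.append(
            {
                "cluster_id": int(node),
                "n_cells": int(len(rows)),
                "corrected": rep["corrected"],
                "warnings": rep["warnings"],
            }
        )
    if config.cap:
        lo = dataset.expression.min(axis=0)
        hi = dataset.expression.max(axis=0)
        corrected = np.clip(corrected, lo, hi)
    out = dataset.copy()
    out.expression = corrected
    return out, cluster_log


def correct(
    dataset: CytometryDataset, config: CorrectionConfig
) -> tuple[CytometryDataset, dict]:
    """Design check -> SOM partition -> per-cluster adjustment -> capping.

    Returns the corrected dataset and a run report (config, seed, cluster
    sizes, skipped clusters, warnings) sufficient to reproduce the run.
    """
    check_design(dataset, config.covariate)
    labels = create_partition(dataset, config)
    corrected, cluster_log = batch_correct(dataset, labels, config)
    skipped = [c["cluster_id"] for c in cluster_log if not c["corrected"]]
    report = {
        "config": asdict(config),
        "n_cells": dataset.n_cells,
        "n_markers": dataset.n_markers,
        "batches": {str(b): int(n) for b, n in
                    dataset.cell_meta["batch_id"].value_counts().items()},
        "n_clusters": int(len(np.unique(labels))),
        "cluster_sizes": {int(c["cluster_id"]): c["n_cells"] for c in cluster_log},
        "skipped_clusters": skipped,
        "warnings": [w for c in cluster_log for w in c["warnings"]],
    }
    return corrected, report


def correct_two_step(
    dataset: CytometryDataset,
    panel_column: str,
    config: CorrectionConfig,
) -> tuple[CytometryDataset, dict]:
    """Co-correct across panels/datasets by treating the panel as the batch.

    Relabels ``batch_id`` from ``panel_column`` and runs :func:`correct`;
    used after per-panel correction when integrating two panels on their
    overlapping markers.
    """
    relabeled = dataset.copy()
    relabeled.cell_meta = relabeled.cell_meta.copy()
    relabeled.cell_meta["batch_id"] = dataset.cell_meta[panel_column].to_numpy()
    corrected, report = correct(relabeled, config)
    corrected.cell_meta["batch_id"] = dataset.cell_meta["batch_id"].to_numpy()
    report["batch_variable"] = panel_column
    return corrected, report
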