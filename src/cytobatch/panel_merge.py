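"""Cross-panel marker imputation and single-channel salvage.

Two datasets stained with different antibody panels are merged by
co-clustering their cells on the overlapping markers with a SOM, then
filling each cell's missing markers from a single donor cell drawn (with
replacement) from the *other* dataset within the same node, plus Gaussian
noise whose per-marker standard deviation is the kernel bandwidth of the
node's donor population.  This simulates a draw from a multi-dimensional
kernel density estimate of the donors: drawing one donor for all missing
markers jointly is what preserves their co-expression structure — markers
are never imputed independently.

Nodes with fewer donors than ``min_donors`` (default 50) are considered
unreliable and receive the missing-value sentinel (NaN) instead.  Imputed
values are flagged in an explicit per-cell x per-marker mask; they are
suitable for visualization and clustering, not for differential-expression
inference, and the FCS writer refuses to export sentinels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import CytometryDataset, ValidationError, concatenate
from .som_partition import assign_nodes, train_som


@dataclass
class MergePlan:
    """Which markers overlap, which need imputing, and how to cluster."""

    overlap_markers: list[str]
    missing_in_A: list[str]
    missing_in_B: list[str]
    grid_x: int = 8
    grid_y: int = 8
    min_donors: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.overlap_markers:
            raise ValidationError("no overlapping markers: imputation impossible")
        if self.min_donors < 1:
            raise ValidationError("min_donors must be >= 1")


def find_marker_overlap(
    markers_A: list[str],
    markers_B: list[str],
    grid_x: int = 8,
    grid_y: int = 8,
    min_donors: int = 50,
    seed: int = 0,
) -> MergePlan:
    """Set intersection/differences by canonical marker key (sorted)."""
    sa, sb = set(markers_A), set(markers_B)
    if not sa & sb:
        raise ValidationError("panels share no markers: imputation impossible")
    return MergePlan(
        overlap_markers=sorted(sa & sb),
        missing_in_A=sorted(sb - sa),
        missing_in_B=sorted(sa - sb),
        grid_x=grid_x,
        grid_y=grid_y,
        min_donors=min_donors,
        seed=seed,
    )


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb kernel bandwidth for one marker.

    ``0.9 min(sd, IQR/1.34) n^(-1/5)``; zero for degenerate samples.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        return 0.0
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def _impute_block(
    recipients: np.ndarray,
    donor_values: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fill (n_recipients x n_missing) from donors: one donor per recipient
    plus per-marker bandwidth noise computed on the donor set."""
    n_rec = len(recipients)
    draws = rng.integers(0, donor_values.shape[0], size=n_rec)
    out = donor_values[draws].astype(float)
    for j in range(donor_values.shape[1]):
        bw = silverman_bandwidth(donor_values[:, j])
        if bw > 0:
            out[:, j] += rng.normal(0.0, bw, size=n_rec)
    return out


def impute_across_panels(
    ds_A: CytometryDataset,
    ds_B: CytometryDataset,
    plan: MergePlan,
) -> CytometryDataset:
    """Merge two panels into one dataset over the union of markers.

    Both datasets are expected to be batch-corrected on the overlapping
    markers already (the clustering here uses the corrected overlap
    expression directly, without re-normalization).  A single SOM is
    trained on the pooled overlap expression; imputation is node-wise as
    described in the module docstring.  Measured values are never touched,
    and each panel's per-node cell counts are unchanged by construction.
    """
    for m in plan.overlap_markers:
        ds_A.marker_index(m)
        ds_B.marker_index(m)
    cols_A = [ds_A.marker_index(m) for m in plan.overlap_markers]
    cols_B = [ds_B.marker_index(m) for m in plan.overlap_markers]
    pooled = np.vstack(
        [ds_A.expression[:, cols_A], ds_B.expression[:, cols_B]]
    )
    model = train_som(pooled, grid_x=plan.grid_x, grid_y=plan.grid_y, seed=plan.seed)
    labels = assign_nodes(model, pooled)
    n_A = ds_A.n_cells
    labels_A, labels_B = labels[:n_A], labels[n_A:]

    all_markers = sorted(set(ds_A.marker_names) | set(ds_B.marker_names))
    rng = np.random.default_rng(plan.seed)

    def build(ds, own_labels, donor_ds, donor_labels, missing):
        n = ds.n_cells
        expr = np.full((n, len(all_markers)), np.nan)
        mask = np.zeros((n, len(all_markers)), dtype=bool)
        for j, m in enumerate(all_markers):
            if m in ds.marker_names:
                expr[:, j] = ds.expression[:, ds.marker_index(m)]
        if missing:
            donor_cols = [donor_ds.marker_index(m) for m in missing]
            miss_cols = [all_markers.index(m) for m in missing]
            for node in np.unique(own_labels):
                rec_rows = np.flatnonzero(own_labels == node)
                donor_rows = np.flatnonzero(donor_labels == node)
                mask[np.ix_(rec_rows, miss_cols)] = True
                if len(donor_rows) < plan.min_donors:
                    continue  # leave NaN sentinel
                donor_vals = donor_ds.expression[np.ix_(donor_rows, donor_cols)]
                expr[np.ix_(rec_rows, miss_cols)] = _impute_block(
                    rec_rows, donor_vals, rng
                )
        meta = ds.cell_meta.copy()
        return expr, mask, meta

    expr_A, mask_A, meta_A = build(ds_A, labels_A, ds_B, labels_B, plan.missing_in_A)
    expr_B, mask_B, meta_B = build(ds_B, labels_B, ds_A, labels_A, plan.missing_in_B)
    meta_A["panel"] = "A"
    meta_B["panel"] = "B"
    merged = CytometryDataset(
        expression=np.vstack([expr_A, expr_B]),
        marker_names=all_markers,
        cell_meta=pd.concat([meta_A, meta_B], ignore_index=True),
        transform_record=dict(ds_A.transform_record),
        is_imputed=np.vstack([mask_A, mask_B]),
    )
    return merged


def salvage_channel(
    dataset: CytometryDataset,
    marker: str,
    bad_batches: list,
    grid_x: int = 8,
    grid_y: int = 8,
    seed: int = 0,
    min_donors: int = 50,
) -> CytometryDataset:
    """Replace one mis-stained marker in selected batches by imputation.

    Same mechanism as panel merging, but donors are cells from the *good*
    batches of the same dataset: clustering uses all markers except the
    salvaged one, and only the bad batches' values of that marker change.
    """
    col = dataset.marker_index(marker)
    batches = dataset.batches.astype(str)
    bad = {str(b) for b in bad_batches}
    unknown = bad - set(batches)
    if unknown:
        raise ValidationError(f"unknown batches: {sorted(unknown)}")
    if not bad:
        return dataset.copy()
    if bad >= set(batches):
        raise ValidationError("all batches are bad: no donors available")

    other_cols = [j for j in range(dataset.n_markers) if j != col]
    model = train_som(
        dataset.expression[:, other_cols], grid_x=grid_x, grid_y=grid_y, seed=seed
    )
    labels = assign_nodes(model, dataset.expression[:, other_cols])
    is_bad = np.isin(batches, sorted(bad))

    out = dataset.copy()
    mask = np.zeros(dataset.expression.shape, dtype=bool)
    rng = np.random.default_rng(seed)
    for node in np.unique(labels[is_bad]):
        rec_rows = np.flatnonzero((labels == node) & is_bad)
        donor_rows = np.flatnonzero((labels == node) & ~is_bad)
        mask[rec_rows, col] = True
        if len(donor_rows) < min_donors:
            out.expression[rec_rows, col] = np.nan
            continue
        donor_vals = dataset.expression[donor_rows, col][:, None]
        out.expression[rec_rows, col] = _impute_block(rec_rows, donor_vals, rng)[:, 0]
    out.is_imputed = mask
    out.validate(allow_missing=True)
    return out
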