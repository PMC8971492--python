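"""Synthetic cytometry data with known populations, batch and condition
effects.

Cells are drawn from a Gaussian mixture over markers on the ArcSinh scale:
each population has a mean vector (markers are "positive" ~2-4.5 or
"negative" ~0-0.6, the bimodality typical of ArcSinh-transformed antibody
signal), condition membership shifts population *abundances* (not marker
levels), and each batch applies a per-marker location/scale distortion —
additive shift ~ Normal(0, shift_sd) and multiplicative scale
exp(Normal(0, scale_sd)) — exactly the effect family the empirical Bayes
model assumes.  Optional zero-inflation zeroes a fraction of values before
distortion, stressing the model outside its assumptions.

Distortions are centered across batches by default (shifts sum to zero,
log-scales sum to zero, per marker), so the dataset-level location/scale is
preserved and recovery against the undistorted ground truth is well-posed.

Everything is deterministic given the config seed; the ground truth
(population labels, drawn distortions) is returned alongside the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import CytometryDataset, ValidationError
from .fcs_io import inverse_arcsinh, write_fcs


def _default_abundances(n_populations: int) -> np.ndarray:
    w = 2.0 ** -np.arange(n_populations)
    return w / w.sum()


@dataclass
class SimulationConfig:
    """Study-condition parameters for the generator.

    Defaults describe a modest CyTOF-like experiment: 4 populations over
    12 markers, 2 batches, within-population marker noise sd 0.35 ArcSinh
    units, batch shifts drawn with sd 0.3 and log-scales with sd 0.1.
    ``condition_abundances`` maps condition name -> per-population
    frequency vector; by default a single unnamed condition with
    geometrically decreasing abundances (includes a rare population).
    """

    n_populations: int = 4
    n_markers: int = 12
    n_batches: int = 2
    cells_per_batch: int = 5000
    population_means: np.ndarray | None = None
    condition_abundances: dict[str, np.ndarray] | None = None
    batch_shift_sd: float = 0.3
    batch_scale_sd: float = 0.1
    noise_sd: float = 0.35
    zero_inflation: float = 0.0
    center_distortions: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_shift_sd, self.batch_scale_sd, self.noise_sd) < 0:
            raise ValidationError("standard deviations must be non-negative")
        if not 0 <= self.zero_inflation <= 1:
            raise ValidationError("zero_inflation must be a probability")
        if self.condition_abundances is not None:
            for name, ab in self.condition_abundances.items():
                ab = np.asarray(ab, dtype=float)
                if len(ab) != self.n_populations or abs(ab.sum() - 1) > 1e-8:
                    raise ValidationError(
                        f"abundances for condition {name!r} must be "
                        f"{self.n_populations} frequencies summing to 1"
                    )


@dataclass
class SimulationTruth:
    """Ground truth aligned with the generated dataset."""

    population: np.ndarray              # per-cell population index
    condition: np.ndarray               # per-cell condition (or None)
    shift: np.ndarray                   # batches x markers additive shifts
    scale: np.ndarray                   # batches x markers multiplicative scales
    population_means: np.ndarray        # populations x markers
    abundances: dict[str, np.ndarray] = field(default_factory=dict)


def _draw_population_means(rng, n_populations, n_markers) -> np.ndarray:
    positive = rng.random((n_populations, n_markers)) < 0.4
    means = np.where(
        positive,
        rng.uniform(2.0, 4.5, (n_populations, n_markers)),
        rng.uniform(0.0, 0.6, (n_populations, n_markers)),
    )
    return means


def draw_batch_distortions(
    rng: np.random.Generator,
    n_batches: int,
    n_markers: int,
    shift_sd: float,
    scale_sd: float,
    center: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    shift = rng.normal(0.0, shift_sd, (n_batches, n_markers)) if shift_sd else (
        np.zeros((n_batches, n_markers))
    )
    log_scale = rng.normal(0.0, scale_sd, (n_batches, n_markers)) if scale_sd else (
        np.zeros((n_batches, n_markers))
    )
    if center and n_batches > 1:
        shift -= shift.mean(axis=0)
        log_scale -= log_scale.mean(axis=0)
    return shift, np.exp(log_scale)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[CytometryDataset, SimulationTruth]:
    """Generate a dataset plus its ground truth; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    P, M, B = config.n_populations, config.n_markers, config.n_batches
    means = (
        np.asarray(config.population_means, dtype=float)
        if config.population_means is not None
        else _draw_population_means(rng, P, M)
    )
    if means.shape != (P, M):
        raise ValidationError(f"population_means must be {P} x {M}")
    abundances = config.condition_abundances or {None: _default_abundances(P)}
    abundances = {k: np.asarray(v, dtype=float) for k, v in abundances.items()}
    shift, scale = draw_batch_distortions(
        rng, B, M, config.batch_shift_sd, config.batch_scale_sd,
        config.center_distortions,
    )

    conditions = list(abundances)
    per_cond = np.full(len(conditions), config.cells_per_batch // len(conditions))
    per_cond[: config.cells_per_batch - per_cond.sum()] += 1

    blocks, meta_rows, pops_all, conds_all = [], [], [], []
    marker_names = [f"M{j + 1:02d}" for j in range(M)]
    for b in range(B):
        for cond, n_c in zip(conditions, per_cond):
            pops = rng.choice(P, size=n_c, p=abundances[cond])
            x = means[pops] + rng.normal(0.0, config.noise_sd, (n_c, M))
            if config.zero_inflation > 0:
                x[rng.random((n_c, M)) < config.zero_inflation] = 0.0
            x = x * scale[b] + shift[b]
            blocks.append(x)
            pops_all.append(pops)
            conds_all.append(np.full(n_c, cond, dtype=object))
            sid = f"batch{b + 1}" + (f"_{cond}" if cond is not None else "")
            meta_rows.append(
                pd.DataFrame(
                    {
                        "sample_id": sid,
                        "batch_id": f"batch{b + 1}",
                        "condition": cond,
                        "original_index": np.arange(n_c),
                    }
                )
            )
    dataset = CytometryDataset(
        expression=np.vstack(blocks),
        marker_names=marker_names,
        cell_meta=pd.concat(meta_rows, ignore_index=True),
        transform_record={"cofactor": 5.0, "derandomized": False, "simulated": True},
    )
    truth = SimulationTruth(
        population=np.concatenate(pops_all),
        condition=np.concatenate(conds_all),
        shift=shift,
        scale=scale,
        population_means=means,
        abundances=abundances,
    )
    return dataset, truth


def apply_batch_effects(
    dataset: CytometryDataset,
    shift: np.ndarray | None = None,
    scale: np.ndarray | None = None,
    shift_sd: float | None = None,
    scale_sd: float | None = None,
    seed: int = 0,
    center: bool = True,
) -> tuple[CytometryDataset, dict]:
    """Inject location/scale distortions into an existing dataset.

    Either pass explicit ``shift``/``scale`` matrices (batches x markers,
    batch rows in the dataset's first-appearance batch order) or sds from
    which they are drawn with ``seed``.  Returns the distorted dataset and
    the applied spec.
    """
    batch_ids = dataset.batch_ids()
    B, M = len(batch_ids), dataset.n_markers
    if shift is None and scale is None:
        rng = np.random.default_rng(seed)
        shift, scale = draw_batch_distortions(
            rng, B, M, shift_sd or 0.0, scale_sd or 0.0, center
        )
    shift = np.zeros((B, M)) if shift is None else np.asarray(shift, dtype=float)
    scale = np.ones((B, M)) if scale is None else np.asarray(scale, dtype=float)
    if shift.shape != (B, M) or scale.shape != (B, M):
        raise ValidationError(f"distortion matrices must be {B} x {M}")
    out = dataset.copy()
    batches = dataset.batches
    for i, b in enumerate(batch_ids):
        rows = np.flatnonzero(batches == b)
        out.expression[rows] = out.expression[rows] * scale[i] + shift[i]
    return out, {"shift": shift, "scale": scale, "batch_order": batch_ids}


def write_fixture_fcs(dataset: CytometryDataset, directory: str | Path) -> list[Path]:
    """Write one FCS file per sample plus a sample-sheet CSV.

    Expression is mapped back to raw intensities with the recorded cofactor
    so that re-assembly through the standard ingestion path round-trips.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cofactor = dataset.transform_record.get("cofactor", 5.0)
    raw = inverse_arcsinh(dataset.expression, cofactor)
    paths, sheet_rows = [], []
    for sid, rows in dataset.cell_meta.groupby("sample_id", sort=False).groups.items():
        rows = np.asarray(rows)
        path = directory / f"{sid}.fcs"
        write_fcs(raw[rows], path, channel_names=list(dataset.marker_names))
        meta = dataset.cell_meta.iloc[rows[0]]
        sheet_rows.append(
            {
                "sample_id": sid,
                "batch_id": meta["batch_id"],
                "condition": meta["condition"],
                "filename": path.name,
                "cofactor": cofactor,
            }
        )
        paths.append(path)
    sheet = directory / "samples.csv"
    pd.DataFrame(sheet_rows).to_csv(sheet, index=False)
    return paths + [sheet]
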