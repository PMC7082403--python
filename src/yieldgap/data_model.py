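"""Core record types, CSV ingestion/validation, and plot-level light interception.

Light interception (fPAR) is the fraction of photosynthetically active
radiation intercepted by the orchard canopy, measured by paired PAR sensors
below and above the canopy::

    fPAR = 1 - PAR_below / PAR_above

Plot-level light interception is the arithmetic mean of the per-tree fPAR
values sampled along the row.  Internally light interception is always a
fraction in [0, 1]; reports and bin labels convert to percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("yieldgap")

#: fractional tolerance for below-canopy readings exceeding the above-canopy
#: reference before the pair is treated as inconsistent rather than noise
FPAR_NOISE_TOLERANCE = 0.05

#: column order of plots.csv
PLOT_COLUMNS = [
    "plot_id",
    "orchard_id",
    "year",
    "latitude",
    "longitude",
    "cultivar_id",
    "planting_year",
    "row_spacing_m",
    "tree_spacing_m",
    "light_interception",
    "yield_kernel_lbs_acre",
]


class SchemaError(ValueError):
    """A required column is missing or mis-typed in an input file."""


class UniquenessError(ValueError):
    """Duplicate (plot_id, year) keys in a dataset."""


class MeasurementInconsistencyError(ValueError):
    """A below-canopy PAR reading exceeds the above-canopy reference beyond
    sensor-noise tolerance."""


@dataclass(frozen=True)
class TreePARMeasurement:
    """One paired PAR reading for a single tree (any consistent flux unit)."""

    tree_id: str
    par_below: float
    par_above: float

    def __post_init__(self) -> None:
        if self.par_above <= 0:
            raise ValueError(f"par_above must be positive, got {self.par_above}")
        if self.par_below < 0:
            raise ValueError(f"par_below must be non-negative, got {self.par_below}")


@dataclass(frozen=True)
class PlotRecord:
    """One plot-year observation: orchard identity, age, cultivar, spacing,
    measured light interception (fraction) and kernel yield (lbs/acre)."""

    plot_id: str
    orchard_id: str
    year: int
    latitude: float
    longitude: float
    cultivar_id: int
    planting_year: int
    row_spacing_m: float
    tree_spacing_m: float
    light_interception: float
    yield_kernel_lbs_acre: float

    @property
    def age(self) -> int:
        return self.year - self.planting_year

    def validate(self) -> None:
        if self.age < 0:
            raise ValueError(f"{self.plot_id}/{self.year}: negative age {self.age}")
        if not 0.0 <= self.light_interception <= 1.0:
            raise ValueError(
                f"{self.plot_id}/{self.year}: light interception "
                f"{self.light_interception} outside [0, 1]"
            )
        if self.yield_kernel_lbs_acre < 0:
            raise ValueError(
                f"{self.plot_id}/{self.year}: negative yield "
                f"{self.yield_kernel_lbs_acre}"
            )


@dataclass
class Dataset:
    """A validated collection of plot-year records plus free-form provenance."""

    plots: list[PlotRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.plots:
            raise ValueError("Dataset must contain at least one plot record")
        keys = [(p.plot_id, p.year) for p in self.plots]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise UniquenessError(f"duplicate (plot_id, year) keys: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.plots)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one row per plot-year (adds derived ``age``)."""
        df = pd.DataFrame([vars(p) | {"age": p.age} for p in self.plots])
        return df[PLOT_COLUMNS + ["age"]]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict | None = None) -> "Dataset":
        plots = [
            PlotRecord(
                plot_id=str(r.plot_id),
                orchard_id=str(r.orchard_id),
                year=int(r.year),
                latitude=float(r.latitude),
                longitude=float(r.longitude),
                cultivar_id=int(r.cultivar_id),
                planting_year=int(r.planting_year),
                row_spacing_m=float(r.row_spacing_m),
                tree_spacing_m=float(r.tree_spacing_m),
                light_interception=float(r.light_interception),
                yield_kernel_lbs_acre=float(r.yield_kernel_lbs_acre),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(plots=plots, provenance=provenance or {})


def compute_fpar(par_below_readings: Sequence[float], par_above: float) -> float:
    """Fractional PAR intercepted by the canopy: ``1 - mean(below)/above``.

    Readings whose mean exceeds ``par_above`` by at most 5% are attributed to
    sensor noise and clipped to fPAR = 0; larger excursions raise
    :class:`MeasurementInconsistencyError`.
    """
    if par_above <= 0:
        raise ValueError(f"par_above must be positive, got {par_above}")
    readings = np.asarray(par_below_readings, dtype=float)
    if readings.size == 0:
        raise ValueError("at least one below-canopy reading is required")
    if np.any(readings < 0):
        raise ValueError("below-canopy readings must be non-negative")
    mean_below = float(readings.mean())
    if mean_below > par_above * (1.0 + FPAR_NOISE_TOLERANCE):
        raise MeasurementInconsistencyError(
            f"mean below-canopy PAR {mean_below:.1f} exceeds above-canopy "
            f"{par_above:.1f} by more than {FPAR_NOISE_TOLERANCE:.0%}"
        )
    return float(np.clip(1.0 - mean_below / par_above, 0.0, 1.0))


def aggregate_plot_li(tree_fpars: Sequence[float]) -> float:
    """Plot-level light interception: mean of the per-tree fPAR values."""
    fpars = np.asarray(tree_fpars, dtype=float)
    if fpars.size == 0:
        raise ValueError("cannot aggregate an empty list of tree fPAR values")
    if np.any((fpars < 0) | (fpars > 1)):
        raise ValueError("tree fPAR values must lie in [0, 1]")
    return float(fpars.mean())


def compute_plot_li_from_par(par_csv_path: str | Path) -> pd.DataFrame:
    """Aggregate a raw PAR-transect table to plot-level light interception.

    Expects columns ``plot_id,year,tree_id,par_below,par_above``; returns one
    row per (plot_id, year) with the mean per-tree fPAR.
    """
    df = pd.read_csv(par_csv_path)
    required = {"plot_id", "year", "tree_id", "par_below", "par_above"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"par.csv missing columns: {sorted(missing)}")
    rows = []
    for (plot_id, year), grp in df.groupby(["plot_id", "year"], sort=True):
        fpars = [
            compute_fpar([b], a) for b, a in zip(grp["par_below"], grp["par_above"])
        ]
        rows.append(
            {"plot_id": plot_id, "year": int(year), "light_interception": aggregate_plot_li(fpars)}
        )
    return pd.DataFrame(rows)


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Row-level validation; returns (valid rows, n rejected)."""
    numeric_cols = [c for c in PLOT_COLUMNS if c not in ("plot_id", "orchard_id")]
    coerced = df.copy()
    for col in numeric_cols:
        coerced[col] = pd.to_numeric(coerced[col], errors="coerce")
    ok = coerced[numeric_cols].notna().all(axis=1)
    ok &= coerced["light_interception"].between(0.0, 1.0)
    ok &= coerced["yield_kernel_lbs_acre"] >= 0.0
    ok &= (coerced["year"] - coerced["planting_year"]) >= 0
    rejected = int((~ok).sum())
    if rejected:
        for idx in df.index[~ok][:20]:
            logger.warning("plots.csv row %s rejected by validation", idx)
        logger.warning("rejected %d invalid rows during load", rejected)
    return coerced.loc[ok.fillna(False)], rejected


def load_dataset(plot_csv_path: str | Path) -> Dataset:
    """Load and validate plots.csv into a :class:`Dataset`.

    Invalid rows are rejected with warnings (load degrades gracefully);
    missing mandatory columns and duplicate (plot_id, year) keys abort.
    ``age`` is always derived as ``year - planting_year``.
    """
    path = Path(plot_csv_path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"plots.csv missing mandatory columns: {missing}")
    valid, rejected = _validate_rows(df)
    if valid.empty:
        raise ValueError(f"{path}: no valid rows after validation")
    logger.info("loaded %d plot rows (%d rejected) from %s", len(valid), rejected, path)
    return Dataset.from_frame(
        valid[PLOT_COLUMNS],
        provenance={"source": str(path), "n_rows": len(valid), "n_rejected": rejected},
    )


def write_dataset(dataset: Dataset, plot_csv_path: str | Path) -> Path:
    """Write a dataset back to the plots.csv schema (round-trips with
    :func:`load_dataset`)."""
    path = Path(plot_csv_path)
    df = dataset.to_frame()[PLOT_COLUMNS]
    df.to_csv(path, index=False)
    return path
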