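"""Climate feature engineering from gridded monthly and daily weather.

Turns PRISM-style monthly records (precipitation, Tmax/Tmin/Tmean, VPDmax)
and Daymet-style daily records (Tmax, SRAD, daylight hours) into the
plot-year feature table used by the yield models:

* monthly means for every variable, current and previous year
  (``tmean_m06_cur``, ``srad_m09_prev``, ...),
* seasonal means with meteorological seasons where the winter of year Y is
  Dec(Y−1)/Jan(Y)/Feb(Y) (``vpdmax_summer_cur``, ...),
* monthly extreme-hot-day counts, where a hot day exceeds that calendar
  month's 90th-percentile daily Tmax over the reference decade
  (``hotdays_m06_cur``, ...),
* long-term (reference-period) seasonal and annual climatology per cell
  (``ltm_srad_annual``, ...),
* the biological columns carried over from the plot records.

Orchards are joined to climate cells by nearest coordinates.  Rows with any
missing climate (in particular the first year, which has no previous-year
lag) are dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .data_model import Dataset

logger = logging.getLogger("yieldgap")

MONTHLY_COLUMN_MAP = {
    "ppt_mm": "ppt",
    "tmax_c": "tmax",
    "tmin_c": "tmin",
    "tmean_c": "tmean",
    "vpdmax_hpa": "vpdmax",
}
MONTHLY_VARS = tuple(MONTHLY_COLUMN_MAP.values())
DAILY_VARS = ("srad", "dayl")

#: Table-1 style variable grouping used by the cross-correlation screen
VARIABLE_CATEGORIES = {
    "ppt": "precipitation",
    "tmax": "temperature",
    "tmin": "temperature",
    "tmean": "temperature",
    "vpdmax": "vpd",
    "srad": "radiation",
    "dayl": "radiation",
    "hotdays": "extremes",
}

BIO_COLUMNS = [
    "latitude",
    "longitude",
    "cultivar_id",
    "age",
    "row_spacing_m",
    "tree_spacing_m",
    "light_interception",
]
KEY_COLUMNS = ["plot_id", "orchard_id", "year"]
TARGET_COLUMN = "yield_kernel_lbs_acre"


class InsufficientDataError(ValueError):
    """Not enough records to compute a threshold or climatology."""


class ConfigurationError(ValueError):
    """A required precomputed input (e.g. a threshold) is missing."""


@dataclass(frozen=True)
class SeasonDefinition:
    """Mapping season name -> month list.  December belongs to the *following*
    year's winter, so seasons are contiguous in time."""

    seasons: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "winter": (12, 1, 2),
            "spring": (3, 4, 5),
            "summer": (6, 7, 8),
            "fall": (9, 10, 11),
        }
    )

    def __post_init__(self) -> None:
        months = sorted(m for ms in self.seasons.values() for m in ms)
        if months != list(range(1, 13)):
            raise ValueError("season months must partition 1..12")

    def season_of(self, month: int) -> str:
        for name, months in self.seasons.items():
            if month in months:
                return name
        raise ValueError(f"month {month} not in any season")

    def season_year(self, year: int, month: int) -> int:
        """December is assigned to the following year's winter."""
        return year + 1 if month == 12 else year

    def names(self) -> list[str]:
        return list(self.seasons)


DEFAULT_SEASONS = SeasonDefinition()


def _normalize_monthly(monthly: pd.DataFrame) -> pd.DataFrame:
    """Accept either raw CSV column names (ppt_mm, ...) or short names."""
    df = monthly.rename(columns=MONTHLY_COLUMN_MAP)
    return df


def feature_category(column: str) -> str:
    """Category of a feature column for the cross-correlation screen.

    Long-term climatology columns form their own categories: they carry
    between-site (spatial) variation, while the current/previous-year columns
    carry interannual anomalies, so the within-category redundancy rule
    should not let a static site attribute displace a year-specific stressor.
    """
    if column.startswith("ltm_"):
        var = column[4:].split("_")[0]
        return f"climatology-{VARIABLE_CATEGORIES.get(var, 'other')}"
    var = column.split("_")[0]
    return VARIABLE_CATEGORIES.get(var, "biological")


# ---------------------------------------------------------------------------
# aggregation primitives
# ---------------------------------------------------------------------------

def seasonal_aggregate(
    monthly: pd.DataFrame,
    seasons: SeasonDefinition = DEFAULT_SEASONS,
    value_cols: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Unweighted seasonal means per (cell, season-year).

    A cell-year-season is reported only when all of its months are present;
    incomplete seasons are omitted and counted in the log.
    """
    df = _normalize_monthly(monthly)
    if value_cols is None:
        value_cols = [c for c in df.columns if c not in ("cell_id", "year", "month")]
    value_cols = list(value_cols)
    df = df.copy()
    df["season"] = df["month"].map(seasons.season_of)
    df["season_year"] = [
        seasons.season_year(y, m) for y, m in zip(df["year"], df["month"])
    ]
    expected = {name: len(months) for name, months in seasons.seasons.items()}
    grouped = df.groupby(["cell_id", "season_year", "season"], sort=True)
    agg = grouped[value_cols].mean()
    counts = grouped["month"].count()
    complete = counts == counts.index.get_level_values("season").map(expected)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("omitted %d incomplete cell-year-seasons", n_dropped)
    out = agg[complete.to_numpy()].reset_index().rename(columns={"season_year": "year"})
    return out


def monthly_means_from_daily(daily: pd.DataFrame) -> pd.DataFrame:
    """Monthly means of the daily variables (srad, dayl) per cell."""
    df = daily.copy()
    dt = pd.to_datetime(df["date"])
    df["year"] = dt.dt.year
    df["month"] = dt.dt.month
    out = (
        df.groupby(["cell_id", "year", "month"], sort=True)[["srad_wm2", "dayl_hours"]]
        .mean()
        .reset_index()
        .rename(columns={"srad_wm2": "srad", "dayl_hours": "dayl"})
    )
    return out


def derive_hot_thresholds(
    daily: pd.DataFrame, reference_years: tuple[int, int]
) -> pd.DataFrame:
    """Per (cell, month) hot-day threshold: the 90th percentile
    (linear-interpolation quantile) of daily Tmax pooled over the reference
    years."""
    df = daily.copy()
    dt = pd.to_datetime(df["date"])
    df["year"] = dt.dt.year
    df["month"] = dt.dt.month
    y0, y1 = reference_years
    ref = df[(df["year"] >= y0) & (df["year"] <= y1)]
    rows = []
    for (cell, month), grp in ref.groupby(["cell_id", "month"], sort=True):
        if len(grp) < 30:
            raise InsufficientDataError(
                f"cell {cell} month {month}: only {len(grp)} pooled days "
                f"in reference span {y0}-{y1} (need >= 30)"
            )
        rows.append(
            {
                "cell_id": cell,
                "month": int(month),
                "threshold_c": float(np.percentile(grp["tmax_c"], 90.0)),
            }
        )
    return pd.DataFrame(rows)


def count_hot_days(daily: pd.DataFrame, thresholds: pd.DataFrame) -> pd.DataFrame:
    """Monthly count of days with Tmax strictly above the month's threshold."""
    df = daily.copy()
    dt = pd.to_datetime(df["date"])
    df["year"] = dt.dt.year
    df["month"] = dt.dt.month
    cells_missing = set(df["cell_id"]) - set(thresholds["cell_id"])
    if cells_missing:
        raise ConfigurationError(f"no hot-day thresholds for cells: {sorted(cells_missing)}")
    merged = df.merge(thresholds, on=["cell_id", "month"], how="left", validate="m:1")
    if merged["threshold_c"].isna().any():
        missing = merged.loc[merged["threshold_c"].isna(), ["cell_id", "month"]]
        raise ConfigurationError(
            f"missing thresholds for cell-months: {missing.drop_duplicates().values.tolist()[:5]}"
        )
    merged["hot"] = merged["tmax_c"] > merged["threshold_c"]
    out = (
        merged.groupby(["cell_id", "year", "month"], sort=True)["hot"]
        .sum()
        .astype(int)
        .reset_index()
        .rename(columns={"hot": "hotdays"})
    )
    return out


def long_term_climatology(
    monthly: pd.DataFrame,
    reference_years: tuple[int, int],
    seasons: SeasonDefinition = DEFAULT_SEASONS,
    min_years: int = 8,
) -> pd.DataFrame:
    """Per-cell reference-period means at seasonal and annual granularity.

    Accepts any monthly-format table (cell_id, year, month, value columns);
    output columns are ``ltm_{var}_{season}`` and ``ltm_{var}_annual``.
    """
    df = _normalize_monthly(monthly)
    value_cols = [c for c in df.columns if c not in ("cell_id", "year", "month")]
    y0, y1 = reference_years
    ref = df[(df["year"] >= y0) & (df["year"] <= y1)]
    years_per_cell = ref.groupby("cell_id")["year"].nunique()
    sparse = years_per_cell[years_per_cell < min_years]
    if not sparse.empty:
        raise InsufficientDataError(
            f"cells with < {min_years} reference years: {sorted(sparse.index)}"
        )
    seasonal = seasonal_aggregate(df, seasons, value_cols)
    seasonal = seasonal[(seasonal["year"] >= y0) & (seasonal["year"] <= y1)]
    season_ltm = seasonal.groupby(["cell_id", "season"], sort=True)[value_cols].mean()
    annual_ltm = ref.groupby("cell_id", sort=True)[value_cols].mean()

    out = pd.DataFrame(index=annual_ltm.index)
    for var in value_cols:
        for season in seasons.names():
            col = season_ltm[var].unstack("season")
            if season in col.columns:
                out[f"ltm_{var}_{season}"] = col[season]
        out[f"ltm_{var}_annual"] = annual_ltm[var]
    return out.reset_index()


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def map_orchards_to_cells(
    orchards: pd.DataFrame, cells: pd.DataFrame
) -> pd.DataFrame:
    """Nearest-cell assignment on (latitude, longitude); ties broken by the
    lexicographically lowest cell_id."""
    cells = cells.sort_values("cell_id").reset_index(drop=True)
    oc = orchards[["orchard_id", "latitude", "longitude"]].drop_duplicates("orchard_id")
    d2 = (
        (oc["latitude"].to_numpy()[:, None] - cells["latitude"].to_numpy()[None, :]) ** 2
        + (oc["longitude"].to_numpy()[:, None] - cells["longitude"].to_numpy()[None, :]) ** 2
    )
    nearest = d2.argmin(axis=1)  # argmin returns the first (lowest id) on ties
    return pd.DataFrame(
        {"orchard_id": oc["orchard_id"].to_numpy(), "cell_id": cells["cell_id"].to_numpy()[nearest]}
    )


def _pivot_monthly(df: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    wide = df.pivot_table(
        index=["cell_id", "year"], columns="month", values=value_cols, aggfunc="mean"
    )
    wide.columns = [f"{var}_m{int(m):02d}" for var, m in wide.columns]
    return wide


def _pivot_seasonal(df: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    wide = df.pivot_table(
        index=["cell_id", "year"], columns="season", values=value_cols, aggfunc="mean"
    )
    wide.columns = [f"{var}_{season}" for var, season in wide.columns]
    return wide


def build_feature_table(
    dataset: Dataset,
    monthly: pd.DataFrame,
    daily: pd.DataFrame,
    cells: pd.DataFrame,
    seasons: SeasonDefinition = DEFAULT_SEASONS,
    reference_years: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Assemble the plot-year feature table and its column manifest.

    Returns ``(features, manifest)`` where ``manifest`` maps every generated
    column name to a short recipe string.  Rows with incomplete climate
    (notably the first year, which lacks the previous-year lag) are dropped
    with a logged count.  Output row and column order is deterministic.
    """
    plots = dataset.to_frame()
    if reference_years is None:
        reference_years = (int(plots["year"].min()), int(plots["year"].max()))

    cell_map = map_orchards_to_cells(plots, cells)
    plots = plots.merge(cell_map, on="orchard_id", how="left", validate="m:1")

    mon = _normalize_monthly(monthly)[["cell_id", "year", "month", *MONTHLY_VARS]]
    dmon = monthly_means_from_daily(daily)
    allmon = mon.merge(dmon, on=["cell_id", "year", "month"], how="outer")
    all_vars = list(MONTHLY_VARS) + list(DAILY_VARS)

    monthly_wide = _pivot_monthly(allmon, all_vars)

    seas = seasonal_aggregate(allmon, seasons, all_vars)
    seasonal_wide = _pivot_seasonal(seas, all_vars)

    thresholds = derive_hot_thresholds(daily, reference_years)
    hot = count_hot_days(daily, thresholds)
    hot_wide = _pivot_monthly(hot.rename(columns={"hotdays": "hotdays_"}), ["hotdays_"])
    hot_wide.columns = [c.replace("hotdays__", "hotdays_") for c in hot_wide.columns]

    per_year = monthly_wide.join(seasonal_wide, how="outer").join(hot_wide, how="outer")

    ltm = long_term_climatology(
        allmon,
        reference_years,
        seasons,
        min_years=min(8, reference_years[1] - reference_years[0] + 1),
    ).set_index("cell_id")

    cur = per_year.copy()
    cur.columns = [f"{c}_cur" for c in cur.columns]
    prev = per_year.copy()
    prev.columns = [f"{c}_prev" for c in prev.columns]
    prev = prev.reset_index()
    prev["year"] = prev["year"] + 1  # previous-year values keyed to the feature year
    prev = prev.set_index(["cell_id", "year"])

    out = (
        plots.set_index(["cell_id", "year"])
        .join(cur, how="left")
        .join(prev, how="left")
        .reset_index()
    )
    out = out.merge(ltm.reset_index(), on="cell_id", how="left")

    climate_cols = (
        [f"{c}_cur" for c in per_year.columns]
        + [f"{c}_prev" for c in per_year.columns]
        + list(ltm.columns)
    )
    ordered = KEY_COLUMNS + [TARGET_COLUMN] + BIO_COLUMNS + sorted(climate_cols)
    out = out[ordered]

    n_before = len(out)
    out = out.dropna(axis=0, how="any").reset_index(drop=True)
    n_dropped = n_before - len(out)
    if n_dropped:
        logger.info(
            "dropped %d plot-years with incomplete climate (of %d)", n_dropped, n_before
        )
    out = out.sort_values(["plot_id", "year"]).reset_index(drop=True)

    manifest: dict[str, str] = {}
    for col in ordered:
        if col in KEY_COLUMNS:
            manifest[col] = "key"
        elif col == TARGET_COLUMN:
            manifest[col] = "target: dry kernel yield, lbs/acre"
        elif col in BIO_COLUMNS:
            manifest[col] = "biological plot attribute"
        elif col.startswith("ltm_"):
            manifest[col] = (
                f"long-term mean over {reference_years[0]}-{reference_years[1]}"
            )
        elif col.startswith("hotdays_"):
            manifest[col] = (
                "count of days with Tmax above the month's 90th-percentile "
                f"threshold ({reference_years[0]}-{reference_years[1]} reference)"
            )
        else:
            lag = "current year" if col.endswith("_cur") else "previous year"
            manifest[col] = f"mean over the period in the name, {lag}"
    return out, manifest


def climate_feature_columns(features: pd.DataFrame) -> list[str]:
    """All engineered climate columns (monthly/seasonal/hotdays/long-term)."""
    fixed = set(KEY_COLUMNS + [TARGET_COLUMN] + BIO_COLUMNS)
    return [c for c in features.columns if c not in fixed]
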