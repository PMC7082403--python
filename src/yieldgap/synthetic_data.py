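"""Synthetic orchard / climate / yield generator.

The real 10-year field dataset behind this analysis (33 orchards, ~7,900
plot-year records of measured light interception and kernel yield across
California's Central Valley) is proprietary.  This module generates data with
the same structure so that every downstream stage — feature engineering,
frontier estimation, yield-gap modelling — runs and is testable end to end,
and so that parameter-recovery tests have a known ground truth.

Generative model
----------------
* Orchards sit on a latitude gradient (~35.0–39.5 °N); southern sites are
  warmer with higher summer vapour-pressure deficit, mirroring the regional
  climatology of the Central Valley.
* Light interception saturates with tree age,
  ``LI = li_max * (1 - exp(-li_rate * age))`` (≈ plateau by age 7), plus a
  small long-term-radiation perturbation and measurement noise.
* Potential yield is linear through the origin in LI percent with slope
  ``frontier_slope_true`` (default 57.9 lbs/acre per LI point).
* Actual yield is the potential times a multiplicative gap
  ``g = base * g_age * g_winter * g_vpd * g_srad * exp(eps)`` capped at 1.05,
  with hinge-shaped stress terms: a young-orchard ramp below ``age_maturity``
  (5 yr), a warm-winter penalty above 10 °C winter mean temperature, a dry-air
  penalty above 40 hPa summer maximum VPD, and a small low-April-radiation
  penalty below 450 W m⁻².  ``eps`` is Gaussian (lognormal multiplier), so
  yields stay non-negative and spread grows with the mean.

Everything is reproducible from ``(SimConfig, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import Dataset, PlotRecord

logger = logging.getLogger("yieldgap")

# dominant cultivar first (integer codes follow the field convention where
# 18 = Non-pareil, 17 = Monterey, 2 = Aldrich, 5 = Butte, 7 = Carmel)
CULTIVAR_IDS = (18, 17, 2, 5, 7)
CULTIVAR_PROBS = (0.55, 0.15, 0.12, 0.10, 0.08)


class LinkageError(KeyError):
    """Climate is missing for an orchard-year that has plot records."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study; defaults are the study conditions.

    Units: temperatures °C, VPD hPa, radiation W m⁻² (daylight average),
    yield lbs/acre, light interception as a fraction.
    """

    n_orchards: int = 33
    plots_per_orchard_year: int = 24
    year_start: int = 2009
    year_end: int = 2018
    seed: int = 0

    # frontier
    frontier_slope_true: float = 57.9  # lbs/acre per LI percentage point

    # light interception growth curve
    li_max: float = 0.80
    li_rate: float = 0.35  # per year
    li_noise_sd: float = 0.03
    li_climate_coef: float = 3e-4  # LI fraction per W m-2 of long-term SRAD anomaly

    # multiplicative yield-gap model
    base_gap: float = 0.90  # management shortfall common to all plots
    age_maturity: float = 5.0  # years; gap ramp ends here
    age_effect: float = 0.15  # max fractional loss at age 0
    winter_t_threshold: float = 10.0  # °C
    winter_effect: float = 0.08  # fractional loss per °C above threshold
    vpd_threshold: float = 40.0  # hPa
    vpd_effect: float = 0.012  # fractional loss per hPa above threshold
    srad_threshold: float = 450.0  # W m-2, April
    srad_effect: float = 0.05  # fractional loss per 100 W m-2 deficit
    gap_noise_sd: float = 0.10  # lognormal sigma of the residual gap
    gap_cap: float = 1.05  # a few plots are allowed above the frontier

    # climate variability (interannual anomaly scale per season)
    interannual_t_sd: float = 1.3  # °C
    interannual_vpd_sd: float = 3.0  # hPa
    interannual_srad_sd: float = 20.0  # W m-2

    # geography
    lat_min: float = 35.0
    lat_max: float = 39.5
    age_min: int = 1
    age_max: int = 22

    def __post_init__(self) -> None:
        if self.n_orchards <= 0 or self.plots_per_orchard_year <= 0:
            raise ValueError("counts must be positive")
        if not 0 < self.li_max <= 1:
            raise ValueError("li_max must lie in (0, 1]")
        if self.gap_noise_sd < 0:
            raise ValueError("gap_noise_sd must be non-negative")
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")

    @classmethod
    def frontier_only(cls, **overrides) -> "SimConfig":
        """A degenerate configuration with every gap effect and noise source
        disabled: every yield sits exactly on the frontier."""
        params = dict(
            base_gap=1.0,
            age_effect=0.0,
            winter_effect=0.0,
            vpd_effect=0.0,
            srad_effect=0.0,
            gap_noise_sd=0.0,
            li_noise_sd=0.0,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class SimTruth:
    """Ground truth retained for parameter-recovery tests."""

    config: SimConfig
    gap_multipliers: np.ndarray  # per plot-year, aligned with the Dataset
    deterministic_gap: np.ndarray
    winter_tmean: np.ndarray
    summer_vpdmax: np.ndarray
    april_srad: np.ndarray

    def to_json_dict(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        return {
            "config": cfg,
            "frontier_slope_true": self.config.frontier_slope_true,
            "seed": self.config.seed,
        }


@dataclass
class SimulationResult:
    dataset: Dataset
    monthly: pd.DataFrame
    daily: pd.DataFrame
    cells: pd.DataFrame
    truth: SimTruth


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, order-insensitive streams per stage
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# orchards
# ---------------------------------------------------------------------------

def simulate_orchards(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place orchards on the latitude gradient and draw plot-year skeletons.

    Returns ``(orchards, skeleton)``: orchard registry (one climate cell per
    orchard) and plot-year rows without LI or yield.  Ages are drawn uniformly
    on [age_min, age_max] for every plot-year so all tree ages are observed in
    every year; plot ids are year-tagged, so (plot_id, year) is unique and
    ``age = year - planting_year`` holds row-wise.
    """
    rng = _rng(config, 1)
    n = config.n_orchards
    lats = np.linspace(config.lat_min, config.lat_max, n) + rng.normal(0, 0.05, n)
    lats = np.clip(lats, config.lat_min, config.lat_max)
    # Central Valley tilts east as it runs south
    lons = -121.9 + 0.64 * (config.lat_max - lats) + rng.normal(0, 0.1, n)
    orchards = pd.DataFrame(
        {
            "orchard_id": [f"o{i:02d}" for i in range(n)],
            "cell_id": [f"c{i:02d}" for i in range(n)],
            "latitude": np.round(lats, 5),
            "longitude": np.round(lons, 5),
        }
    )

    years = np.arange(config.year_start, config.year_end + 1)
    k = config.plots_per_orchard_year
    rows = []
    for oi in range(n):
        for year in years:
            ages = rng.integers(config.age_min, config.age_max + 1, size=k)
            cultivars = rng.choice(CULTIVAR_IDS, size=k, p=CULTIVAR_PROBS)
            row_sp = np.clip(rng.normal(6.7, 0.3, k), 5.5, 8.0)
            tree_sp = np.clip(rng.normal(5.5, 0.4, k), 4.0, 7.0)
            for p in range(k):
                rows.append(
                    {
                        "plot_id": f"o{oi:02d}_{year}_p{p:02d}",
                        "orchard_id": f"o{oi:02d}",
                        "cell_id": f"c{oi:02d}",
                        "year": int(year),
                        "latitude": orchards.latitude[oi],
                        "longitude": orchards.longitude[oi],
                        "cultivar_id": int(cultivars[p]),
                        "planting_year": int(year - ages[p]),
                        "age": int(ages[p]),
                        "row_spacing_m": round(float(row_sp[p]), 2),
                        "tree_spacing_m": round(float(tree_sp[p]), 2),
                    }
                )
    skeleton = pd.DataFrame(rows)
    logger.info("simulated %d orchards, %d plot-year skeletons", n, len(skeleton))
    return orchards, skeleton


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

def _seasonal_cos(month: np.ndarray, peak_month: float) -> np.ndarray:
    return np.cos(2.0 * np.pi * (month - peak_month) / 12.0)


def simulate_climate(
    config: SimConfig, orchards: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate monthly (PRISM-style) and daily (Daymet-style) weather per cell.

    Climate covers ``[year_start - 1, year_end]`` so that the first plot
    year's current-year winter (which reaches into the preceding December)
    is computable.  Seasonal cycles are sinusoids shifted by latitude
    (southern cells warmer, drier air, slightly more radiation) plus
    interannual, monthly and daily noise.  ``tmin <= tmean <= tmax`` holds by
    construction in every cell-month.
    """
    rng = _rng(config, 2)
    cells = orchards[["cell_id", "latitude", "longitude"]].sort_values("cell_id")
    lat = cells["latitude"].to_numpy()
    nc = len(cells)
    years = np.arange(config.year_start - 1, config.year_end + 1)
    ny = len(years)
    months = np.arange(1, 13)

    # latitude-driven baselines
    tbase = 19.75 - 0.78 * (lat - 35.0)  # annual mean temperature
    tamp = 9.3
    vbase = 31.6 - 2.22 * (lat - 35.0)  # VPDmax annual mean
    vamp = 18.0
    sbase = 425.0 + 5.0 * (37.25 - lat)  # SRAD annual mean (south sunnier)
    samp = 195.0

    # interannual anomalies per (cell, year, season): year-to-year swings in
    # e.g. winter temperature and summer VPD are of the same order as the
    # north-south spatial gradient in this region, and anomalies of different
    # seasons within a year are essentially independent
    season_idx = np.array([0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3, 0])  # Jan..Dec
    t_anom = rng.normal(0.0, config.interannual_t_sd, (nc, ny, 4))[:, :, season_idx]
    v_anom = rng.normal(0.0, config.interannual_vpd_sd, (nc, ny, 4))[:, :, season_idx]
    s_anom = rng.normal(0.0, config.interannual_srad_sd, (nc, ny, 4))[:, :, season_idx]
    p_factor = rng.lognormal(0.0, 0.3, (nc, ny))

    shape = (nc, ny, 12)
    m = months[None, None, :]
    tmean = (
        tbase[:, None, None]
        + tamp * _seasonal_cos(m, 7.0)
        + t_anom
        + rng.normal(0.0, 0.7, shape)
    )
    spread_hi = np.abs(7.5 + rng.normal(0.0, 0.5, shape))
    spread_lo = np.abs(7.5 + rng.normal(0.0, 0.5, shape))
    tmax = tmean + spread_hi
    tmin = tmean - spread_lo
    vpdmax = np.clip(
        vbase[:, None, None]
        + vamp * _seasonal_cos(m, 7.0)
        + v_anom
        + rng.normal(0.0, 1.2, shape),
        0.5,
        None,
    )
    srad_m = np.clip(
        sbase[:, None, None]
        + samp * _seasonal_cos(m, 6.5)
        + s_anom
        + rng.normal(0.0, 12.0, shape),
        30.0,
        None,
    )
    ppt = np.clip(
        (60.0 * _seasonal_cos(m, 1.0) + 40.0) * p_factor[:, :, None]
        + rng.normal(0.0, 8.0, shape),
        0.0,
        None,
    )

    cell_ids = cells["cell_id"].to_numpy()
    ci, yi, mi = np.meshgrid(np.arange(nc), np.arange(ny), np.arange(12), indexing="ij")
    monthly = pd.DataFrame(
        {
            "cell_id": cell_ids[ci.ravel()],
            "year": years[yi.ravel()],
            "month": months[mi.ravel()],
            "ppt_mm": np.round(ppt.ravel(), 2),
            "tmax_c": np.round(tmax.ravel(), 3),
            "tmin_c": np.round(tmin.ravel(), 3),
            "tmean_c": np.round(tmean.ravel(), 3),
            "vpdmax_hpa": np.round(vpdmax.ravel(), 3),
        }
    )

    # daily series anchored to the monthly values
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    nd = len(dates)
    y_idx = dates.year.to_numpy() - years[0]
    m_idx = dates.month.to_numpy() - 1
    doy = dates.dayofyear.to_numpy()

    tmax_daily = tmax[:, y_idx, m_idx] + rng.normal(0.0, 3.0, (nc, nd))
    srad_daily = np.clip(srad_m[:, y_idx, m_idx] + rng.normal(0.0, 35.0, (nc, nd)), 10.0, None)
    dayl_amp = 2.0 + 0.25 * (lat - 35.0)
    dayl = 12.0 + dayl_amp[:, None] * np.sin(2.0 * np.pi * (doy[None, :] - 80.0) / 365.25)

    daily = pd.DataFrame(
        {
            "cell_id": np.repeat(cell_ids, nd),
            "date": np.tile(dates.strftime("%Y-%m-%d"), nc),
            "tmax_c": np.round(tmax_daily.ravel(), 3),
            "srad_wm2": np.round(srad_daily.ravel(), 2),
            "dayl_hours": np.round(dayl.ravel(), 4),
        }
    )
    logger.info(
        "simulated climate for %d cells, %d monthly and %d daily rows",
        nc, len(monthly), len(daily),
    )
    return monthly, daily


# ---------------------------------------------------------------------------
# yields
# ---------------------------------------------------------------------------

def _hinge(x: np.ndarray, threshold: float, above: bool) -> np.ndarray:
    return np.maximum(0.0, (x - threshold) if above else (threshold - x))


def _cell_year_drivers(
    monthly: pd.DataFrame, daily: pd.DataFrame
) -> tuple[pd.Series, pd.Series, pd.Series, pd.Series]:
    """Winter Tmean, summer VPDmax, April SRAD per (cell, year), and long-term
    mean SRAD per cell — the quantities the gap model reads."""
    mo = monthly.copy()
    # winter of year Y: Dec(Y-1), Jan(Y), Feb(Y)
    season_year = mo["year"] + (mo["month"] == 12).astype(int)
    winter = (
        mo[mo["month"].isin([12, 1, 2])]
        .assign(syear=season_year[mo["month"].isin([12, 1, 2])])
        .groupby(["cell_id", "syear"])["tmean_c"]
        .mean()
    )
    winter.index = winter.index.set_names(["cell_id", "year"])
    summer_vpd = (
        mo[mo["month"].isin([6, 7, 8])].groupby(["cell_id", "year"])["vpdmax_hpa"].mean()
    )
    da = daily.copy()
    dt = pd.to_datetime(da["date"])
    da["year"] = dt.dt.year
    da["month"] = dt.dt.month
    april_srad = da[da["month"] == 4].groupby(["cell_id", "year"])["srad_wm2"].mean()
    ltm_srad = da.groupby("cell_id")["srad_wm2"].mean()
    return winter, summer_vpd, april_srad, ltm_srad


def simulate_yields(
    skeleton: pd.DataFrame,
    monthly: pd.DataFrame,
    daily: pd.DataFrame,
    config: SimConfig,
) -> tuple[Dataset, SimTruth]:
    """Assign light interception and kernel yield to every plot-year skeleton
    row using the frontier × multiplicative-gap model."""
    rng = _rng(config, 3)
    winter, summer_vpd, april_srad, ltm_srad = _cell_year_drivers(monthly, daily)

    keys = list(zip(skeleton["cell_id"], skeleton["year"]))
    for cell, year in dict.fromkeys(keys):
        if (cell, year) not in winter.index or (cell, year) not in summer_vpd.index:
            orchard = skeleton.loc[skeleton["cell_id"] == cell, "orchard_id"].iloc[0]
            raise LinkageError(f"no climate for orchard {orchard} (cell {cell}) year {year}")

    age = skeleton["age"].to_numpy(dtype=float)
    w = winter.loc[keys].to_numpy()
    v = summer_vpd.loc[keys].to_numpy()
    s = april_srad.loc[keys].to_numpy()
    ls = ltm_srad.loc[skeleton["cell_id"]].to_numpy()

    li_det = config.li_max * (1.0 - np.exp(-config.li_rate * age))
    li = li_det + config.li_climate_coef * (ls - 425.0)
    if config.li_noise_sd > 0:
        li = li + rng.normal(0.0, config.li_noise_sd, len(li))
    li = np.clip(li, 0.05, 0.90)

    # concave ramp: the penalty fades fastest just before maturity, so the
    # dominant yield-gap transition sits at the maturity age itself
    g_age = 1.0 - config.age_effect * np.sqrt(
        np.minimum(_hinge(age, config.age_maturity, above=False) / config.age_maturity, 1.0)
    )
    g_winter = 1.0 - config.winter_effect * _hinge(w, config.winter_t_threshold, above=True)
    g_vpd = 1.0 - config.vpd_effect * _hinge(v, config.vpd_threshold, above=True)
    g_srad = 1.0 - config.srad_effect * _hinge(s, config.srad_threshold, above=False) / 100.0
    g_det = config.base_gap * g_age * g_winter * g_vpd * g_srad
    eps = rng.normal(0.0, config.gap_noise_sd, len(li)) if config.gap_noise_sd > 0 else 0.0
    g = np.clip(g_det * np.exp(eps), 1e-6, config.gap_cap)

    potential = config.frontier_slope_true * li * 100.0
    yields = potential * g

    df = skeleton.drop(columns=["cell_id", "age"]).copy()
    df["light_interception"] = li
    df["yield_kernel_lbs_acre"] = yields
    dataset = Dataset.from_frame(
        df,
        provenance={"source": "yieldgap.synthetic_data", "seed": config.seed},
    )
    truth = SimTruth(
        config=config,
        gap_multipliers=g,
        deterministic_gap=g_det,
        winter_tmean=w,
        summer_vpdmax=v,
        april_srad=s,
    )
    return dataset, truth


def simulate_all(config: SimConfig) -> SimulationResult:
    """Run the three generation stages and return every artifact."""
    orchards, skeleton = simulate_orchards(config)
    monthly, daily = simulate_climate(config, orchards)
    dataset, truth = simulate_yields(skeleton, monthly, daily, config)
    cells = orchards[["cell_id", "latitude", "longitude"]].copy()
    return SimulationResult(dataset, monthly, daily, cells, truth)


def write_simulated(result: SimulationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write plots.csv, monthly_climate.csv, daily_weather.csv, cells.csv and
    sim_truth.json; byte-identical for identical (config, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .data_model import write_dataset

    paths = {
        "plots": out / "plots.csv",
        "monthly": out / "monthly_climate.csv",
        "daily": out / "daily_weather.csv",
        "cells": out / "cells.csv",
        "truth": out / "sim_truth.json",
    }
    write_dataset(result.dataset, paths["plots"])
    result.monthly.to_csv(paths["monthly"], index=False)
    result.daily.to_csv(paths["daily"], index=False)
    result.cells.to_csv(paths["cells"], index=False)
    paths["truth"].write_text(
        json.dumps(result.truth.to_json_dict(), indent=2, sort_keys=True)
    )
    return paths
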