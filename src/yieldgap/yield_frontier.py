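"""Boundary-line (frontier) analysis of yield vs. light interception.

The yield potential at a given light interception is estimated by

1. binning all plot-year samples by LI percent into half-open 5%-wide bins,
2. taking, within each sufficiently populated bin, the upper decile of
   samples by yield as a proxy for the attainable maximum,
3. averaging LI and yield over that decile, and
4. fitting a zero-intercept line to the bin means:
   ``slope = sum(x*y) / sum(x**2)`` (the closed-form one-parameter
   least-squares estimator), with x in LI percent.

The normalized yield ``y_n = y_o / y_p`` (observed over potential) is the
gap statistic: values near 1 are plots at their light-limited potential,
values above 1 (kept, not clipped) are the few plots that beat the fitted
frontier.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import Dataset

logger = logging.getLogger("yieldgap")

DEFAULT_BIN_WIDTH_PCT = 5.0
DEFAULT_MIN_BIN_COUNT = 20


@dataclass
class LIBin:
    """One half-open light-interception bin [lower, upper) in percent."""

    lower_pct: float
    upper_pct: float
    member_ids: list[int]  # positional indices into the dataset
    decile_ids: list[int] = field(default_factory=list)
    mean_li_pct: float = float("nan")  # upper-decile mean LI
    mean_yield: float = float("nan")  # upper-decile mean yield

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


@dataclass
class FrontierModel:
    """Zero-intercept yield-potential line over LI-bin upper-decile means."""

    slope: float  # lbs/acre per LI percentage point
    r2_binmeans: float
    n_bins_used: int
    min_bin_count: int
    width_pct: float
    bins: list[LIBin] = field(default_factory=list)
    intercept: float = 0.0  # fixed by construction

    def to_json_dict(self) -> dict:
        return {
            "slope_lbs_acre_per_li_pct": self.slope,
            "intercept": self.intercept,
            "r2_binmeans": self.r2_binmeans,
            "n_bins_used": self.n_bins_used,
            "min_bin_count": self.min_bin_count,
            "width_pct": self.width_pct,
            "bins": [
                {
                    "lower_pct": b.lower_pct,
                    "upper_pct": b.upper_pct,
                    "n_members": b.n_members,
                    "n_decile": len(b.decile_ids),
                    "decile_mean_li_pct": b.mean_li_pct,
                    "decile_mean_yield": b.mean_yield,
                }
                for b in self.bins
            ],
        }


def bin_by_li(dataset: Dataset, width_pct: float = DEFAULT_BIN_WIDTH_PCT) -> list[LIBin]:
    """Assign every plot-year to a half-open LI bin [k*w, (k+1)*w) percent.

    Empty bins are omitted; a sample with LI exactly on a boundary belongs to
    the upper bin.
    """
    if width_pct <= 0:
        raise ValueError(f"bin width must be positive, got {width_pct}")
    li_pct = np.array([p.light_interception * 100.0 for p in dataset.plots])
    k = np.floor(li_pct / width_pct).astype(int)
    bins: dict[int, LIBin] = {}
    for idx, kk in enumerate(k):
        b = bins.get(kk)
        if b is None:
            b = LIBin(lower_pct=kk * width_pct, upper_pct=(kk + 1) * width_pct, member_ids=[])
            bins[kk] = b
        b.member_ids.append(idx)
    return [bins[kk] for kk in sorted(bins)]


def select_upper_decile(bin_: LIBin, yields: np.ndarray) -> list[int]:
    """The ceil(0.1*n) members with highest yield.

    Ties at the cutoff are resolved by stable record order (earlier records
    first), i.e. sort by (-yield, position) and truncate.
    """
    n = bin_.n_members
    m = math.ceil(0.1 * n)
    members = np.asarray(bin_.member_ids)
    order = sorted(range(n), key=lambda i: (-yields[members[i]], i))
    return [int(members[i]) for i in order[:m]]


def fit_frontier(
    bins: list[LIBin],
    dataset: Dataset,
    min_bin_count: int = DEFAULT_MIN_BIN_COUNT,
    width_pct: float = DEFAULT_BIN_WIDTH_PCT,
) -> FrontierModel:
    """Fit the zero-intercept potential line to the bin upper-decile means.

    Bins with fewer than ``min_bin_count`` members are excluded (so the
    decile holds at least a couple of samples); at least 3 usable bins are
    required.
    """
    yields = np.array([p.yield_kernel_lbs_acre for p in dataset.plots])
    li_pct = np.array([p.light_interception * 100.0 for p in dataset.plots])
    used: list[LIBin] = []
    for b in bins:
        if b.n_members < min_bin_count:
            logger.info(
                "bin [%.0f, %.0f) excluded: %d members < %d",
                b.lower_pct, b.upper_pct, b.n_members, min_bin_count,
            )
            continue
        b.decile_ids = select_upper_decile(b, yields)
        b.mean_li_pct = float(li_pct[b.decile_ids].mean())
        b.mean_yield = float(yields[b.decile_ids].mean())
        used.append(b)
    if len(used) < 3:
        raise ValueError(
            f"only {len(used)} usable bins (need >= 3); lower min_bin_count or widen bins"
        )
    x = np.array([b.mean_li_pct for b in used])
    y = np.array([b.mean_yield for b in used])
    slope = float(np.sum(x * y) / np.sum(x * x))
    resid = y - slope * x
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    logger.info(
        "frontier: slope=%.2f lbs/acre per %%LI over %d bins (R2=%.3f)",
        slope, len(used), r2,
    )
    return FrontierModel(
        slope=slope,
        r2_binmeans=r2,
        n_bins_used=len(used),
        min_bin_count=min_bin_count,
        width_pct=width_pct,
        bins=bins,
    )


def estimate_frontier(
    dataset: Dataset,
    width_pct: float = DEFAULT_BIN_WIDTH_PCT,
    min_bin_count: int = DEFAULT_MIN_BIN_COUNT,
    cultivar_id: int | None = None,
) -> FrontierModel:
    """Bin + decile + fit in one call, optionally restricted to one cultivar
    (the dominant-cultivar stratum is analysed separately in the field)."""
    if cultivar_id is not None:
        plots = [p for p in dataset.plots if p.cultivar_id == cultivar_id]
        if not plots:
            raise ValueError(f"no plots with cultivar_id {cultivar_id}")
        dataset = Dataset(plots=plots, provenance=dict(dataset.provenance))
    bins = bin_by_li(dataset, width_pct)
    return fit_frontier(bins, dataset, min_bin_count, width_pct)


def predict_potential(model: FrontierModel, li: float | np.ndarray) -> float | np.ndarray:
    """Potential yield (lbs/acre) at light interception ``li`` (fraction)."""
    li_arr = np.asarray(li, dtype=float)
    if np.any(li_arr <= 0):
        raise ValueError("light interception must be positive to define a potential")
    out = model.slope * li_arr * 100.0
    return float(out) if np.isscalar(li) or out.ndim == 0 else out


def normalize_yield(y_o: float | np.ndarray, y_p: float | np.ndarray) -> float | np.ndarray:
    """Normalized yield y_n = y_o / y_p; values above 1 are preserved."""
    y_p_arr = np.asarray(y_p, dtype=float)
    y_o_arr = np.asarray(y_o, dtype=float)
    if np.any(y_p_arr <= 0):
        raise ValueError("potential yield must be positive")
    if np.any(y_o_arr < 0):
        raise ValueError("observed yield must be non-negative")
    out = y_o_arr / y_p_arr
    return float(out) if out.ndim == 0 else out


def compute_gaps(dataset: Dataset, model: FrontierModel) -> pd.DataFrame:
    """Per plot-year gap records: observed, potential and normalized yield."""
    rows = []
    for p in dataset.plots:
        y_p = predict_potential(model, p.light_interception)
        rows.append(
            {
                "plot_id": p.plot_id,
                "year": p.year,
                "y_o": p.yield_kernel_lbs_acre,
                "y_p": y_p,
                "y_n": normalize_yield(p.yield_kernel_lbs_acre, y_p),
            }
        )
    return pd.DataFrame(rows)


def write_frontier(model: FrontierModel, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(model.to_json_dict(), indent=2, sort_keys=True))
    return path
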