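"""Per-habitat nectar-sugar phenology curves from floral survey records.

Survey counts of open floral units are converted to grams of sugar per
m^2 per 24 h via per-species sugar production values, then smoothed over
day-of-year with a penalized regression spline whose smoothing parameter
is chosen by generalized cross-validation (GCV).  Tree counts taken in a
5 m vertical column are scaled to the full tree height first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.gam.smooth_basis import BSplines

DEFAULT_GRID = np.arange(60, 305)  # March-October flowering season
MIN_DATES = 8

__all__ = [
    "PhenologyCurve",
    "scale_tree_count",
    "record_sugar_density",
    "records_sugar_density",
    "fit_phenology",
    "normalize_curve",
]


@dataclass
class PhenologyCurve:
    """Daily nectar sugar production of one habitat, with uncertainty band.

    ``value`` is g sugar m^-2 day^-1 at each day of ``grid``; ``se`` is the
    pointwise standard error of the fitted mean.
    """

    habitat: str
    grid: np.ndarray
    value: np.ndarray
    se: np.ndarray
    n_obs: int = 0

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        self.value = np.asarray(self.value, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if not (len(self.grid) == len(self.value) == len(self.se)):
            raise ValueError("grid, value and se must have equal length")
        if np.any(self.value < 0) or np.any(self.se < 0):
            raise ValueError("curve values and se must be non-negative")

    def annual_integral(self) -> float:
        """g sugar m^-2 over the grid (trapezoid rule)."""
        return float(np.trapezoid(self.value, self.grid))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.grid, "value": self.value, "se": self.se}
        )


def scale_tree_count(floral_units: float, plant_height: float) -> float:
    """Scale a 5 m-column floral count up to the full tree height.

    Counts for trees and shrubs cover only a 5 m vertical column above the
    quadrat; the count is multiplied by ``plant_height / 5``.
    """
    if floral_units < 0:
        raise ValueError("floral_units must be >= 0")
    if plant_height < 5:
        raise ValueError("column scaling applies only to plants >= 5 m tall")
    return floral_units * (plant_height / 5.0)


def _trait_lookup(traits: pd.DataFrame) -> pd.Series:
    if "species_id" in traits.columns:
        traits = traits.set_index("species_id")
    return traits["sugar_per_floral_unit"]


def record_sugar_density(record, traits: pd.DataFrame) -> float:
    """g sugar m^-2 day^-1 contributed by a single survey record.

    ``record`` is a mapping with at least species_id, floral_units and
    sampled_area_m2; column-capped tree counts are height-scaled first.
    """
    sugar = _trait_lookup(traits)
    sp = record["species_id"]
    if sp not in sugar.index:
        raise KeyError(f"species {sp!r} missing from trait table")
    units = float(record["floral_units"])
    if record.get("column_capped", False):
        units = scale_tree_count(units, float(record["plant_height_m"]))
    return units / float(record["sampled_area_m2"]) * float(sugar.loc[sp])


def records_sugar_density(records: pd.DataFrame, traits: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`record_sugar_density` over a survey table."""
    sugar = _trait_lookup(traits)
    missing = sorted(set(records["species_id"]) - set(sugar.index))
    if missing:
        raise KeyError(f"species missing from trait table: {missing}")
    units = records["floral_units"].astype(float).to_numpy()
    if "column_capped" in records.columns:
        capped = records["column_capped"].fillna(False).to_numpy(dtype=bool)
        if capped.any():
            h = records["plant_height_m"].to_numpy(dtype=float)
            if np.any(h[capped] < 5):
                raise ValueError("column-capped records need plant height >= 5 m")
            units = np.where(capped, units * h / 5.0, units)
    area = records["sampled_area_m2"].to_numpy(dtype=float)
    rate = sugar.loc[records["species_id"]].to_numpy(dtype=float)
    return pd.Series(units / area * rate, index=records.index, name="sugar_density")


def _day_of_year(dates: pd.Series) -> np.ndarray:
    return pd.to_datetime(dates).dt.dayofyear.to_numpy()


def _per_date_means(records: pd.DataFrame, traits: pd.DataFrame):
    """Collapse a habitat's records to per-date mean total sugar density.

    Duplicate rows of the same (site, quadrat, date, species) are averaged,
    species are summed within a sampling unit, and sampling units are
    averaged within a date — so the fit depends only on per-date means and
    relative weights (and is invariant to record order and duplication).
    """
    df = records.copy()
    df["sugar_density"] = records_sugar_density(df, traits)
    df["doy"] = _day_of_year(df["date"])
    if "quadrat" not in df.columns:
        df["quadrat"] = np.arange(len(df))
    dedup = (
        df.groupby(["site", "quadrat", "doy", "species_id"], sort=True)["sugar_density"]
        .mean()
        .reset_index()
    )
    per_unit = (
        dedup.groupby(["site", "quadrat", "doy"], sort=True)["sugar_density"]
        .sum()
        .reset_index()
    )
    per_date = per_unit.groupby("doy", sort=True)["sugar_density"].agg(["mean", "count"])
    return per_date.index.to_numpy(float), per_date["mean"].to_numpy(), per_date[
        "count"
    ].to_numpy(float)


def fit_phenology(
    records: pd.DataFrame,
    traits: pd.DataFrame,
    habitat: str | None = None,
    grid: np.ndarray = DEFAULT_GRID,
    df: int = 24,
    lam_grid: np.ndarray | None = None,
) -> PhenologyCurve:
    """Fit a GCV-penalized regression spline to a habitat's sugar densities.

    All sites are pooled; the sole smooth term is day-of-year, with a
    cubic B-spline basis of ``df`` functions and the smoothing parameter
    minimizing GCV over ``lam_grid``.  Predictions are clipped at zero.
    """
    if habitat is not None:
        records = records[records["habitat"] == habitat]
    elif "habitat" in records.columns and records["habitat"].nunique() > 1:
        raise ValueError("records span several habitats; pass habitat=")
    name = habitat or (
        records["habitat"].iloc[0] if "habitat" in records.columns and len(records) else "?"
    )

    x, y, w = _per_date_means(records, traits)
    if len(x) < MIN_DATES:
        raise ValueError(
            f"need at least {MIN_DATES} distinct survey dates, got {len(x)}"
        )
    grid = np.asarray(grid, dtype=float)
    n_obs = int(w.sum())
    if np.all(y == 0):
        z = np.zeros(len(grid))
        return PhenologyCurve(name, grid.astype(int), z, z.copy(), n_obs)

    w = w / w.mean()  # relative weights only: duplication-invariant
    lo = min(grid.min(), x.min())
    hi = max(grid.max(), x.max())
    bs = BSplines(
        x[:, None],
        df=[min(df, len(x) - 1)],
        degree=[3],
        include_intercept=True,
        knot_kwds=[dict(lower_bound=lo, upper_bound=hi)],
    )
    X, S = bs.basis, bs.penalty_matrices[0]
    XtW = X.T * w
    A0, b = XtW @ X, XtW @ y
    n = len(x)
    if lam_grid is None:
        lam_grid = 10.0 ** np.linspace(-6, 8, 57)
    best = (np.inf, None, None, None)
    for lam in lam_grid:
        Ainv = np.linalg.inv(A0 + lam * S)
        beta = Ainv @ b
        edf = float(np.einsum("ij,jk,ki->", X, Ainv, XtW))
        rss = float(np.sum(w * (y - X @ beta) ** 2))
        gcv = n * rss / (n - edf) ** 2
        if gcv < best[0]:
            best = (gcv, beta, edf, Ainv)
    _, beta, edf, Ainv = best
    Xg = bs.transform(grid[:, None])
    mu = Xg @ beta
    sigma2 = float(np.sum(w * (y - X @ beta) ** 2)) / max(n - edf, 1.0)
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, sigma2 * Ainv, Xg), 0.0))
    return PhenologyCurve(name, grid.astype(int), np.maximum(mu, 0.0), se, n_obs)


def normalize_curve(curve: PhenologyCurve) -> PhenologyCurve:
    """Rescale a curve to unit maximum (shape only, as for plotting)."""
    peak = curve.value.max()
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero curve")
    return PhenologyCurve(
        curve.habitat, curve.grid, curve.value / peak, curve.se / peak, curve.n_obs
    )
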