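"""Landscape nectar budgets: supply aggregation, garden share, deficits.

Habitat phenology curves (g sugar m^-2 day^-1) are scaled by habitat
areas to give a landscape supply curve, divided by a daily bumblebee
population to give per-bee supply, and compared against a per-bee sugar
requirement to find 'hunger gap' intervals — with and without the garden
contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from nectarscape.phenology import PhenologyCurve
from nectarscape.synthetic import GARDEN, month_of_day

__all__ = [
    "LandscapeComposition",
    "BeePopulationModel",
    "DemandCurve",
    "DeficitReport",
    "aggregate_landscape",
    "garden_fraction",
    "bee_population",
    "per_bee_supply",
    "find_deficits",
    "default_population_models",
    "default_demand",
]


@dataclass
class LandscapeComposition:
    """Habitat areas (m^2) inside one landscape cell."""

    landscape_id: str
    areas: dict[str, float]
    cell_area: float = 1.0e6

    def __post_init__(self):
        if any(a < 0 for a in self.areas.values()):
            raise ValueError("areas must be >= 0")
        if sum(self.areas.values()) > self.cell_area * (1 + 1e-9):
            raise ValueError("areas exceed the cell area")


@dataclass
class BeePopulationModel:
    """Colony density/size and monthly activity weights for one species.

    ``monthly_weights`` are 12 relative-abundance values in [0, 1] with
    max 1 (BeeWalk-style monthly phenology, applied as a step function).
    """

    species: str
    colony_density: float  # colonies per km^2
    colony_size: float  # individuals per colony at peak
    monthly_weights: Sequence[float]

    def __post_init__(self):
        w = np.asarray(self.monthly_weights, dtype=float)
        if w.shape != (12,):
            raise ValueError("monthly_weights needs 12 values")
        if w.min() < 0 or w.max() > 1 or not np.isclose(w.max(), 1.0):
            raise ValueError("weights must lie in [0, 1] with max 1")
        if self.colony_density <= 0 or self.colony_size <= 0:
            raise ValueError("density and size must be > 0")
        self.monthly_weights = w


@dataclass
class DemandCurve:
    """Daily sugar requirement of an individual bumblebee.

    ``base_requirement`` (g sugar bee^-1 day^-1) covers a worker's resting
    and foraging costs; over ``queen_window`` (day-of-year, inclusive) the
    requirement is multiplied by ``spring_queen_multiplier`` to represent
    the elevated demands of nest-founding queens in early spring.  The
    shipped defaults are implementer-supplied values within published
    physiological ranges.
    """

    base_requirement: float = 0.12
    spring_queen_multiplier: float = 3.0
    queen_window: tuple[int, int] = (60, 120)

    def requirement(self, days) -> np.ndarray:
        days = np.asarray(days)
        req = np.full(days.shape, self.base_requirement, dtype=float)
        lo, hi = self.queen_window
        req[(days >= lo) & (days <= hi)] *= self.spring_queen_multiplier
        if np.any(req <= 0):
            raise ValueError("requirement must be > 0 everywhere")
        return req


@dataclass
class DeficitReport:
    """Maximal runs of days when per-bee supply falls below requirement."""

    scenario: str
    intervals: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_days(self) -> int:
        return sum(b - a + 1 for a, b, _ in self.intervals)


def aggregate_landscape(
    curves: Mapping[str, PhenologyCurve],
    comp: LandscapeComposition,
    include_gardens: bool = True,
) -> PhenologyCurve:
    """Landscape supply curve: sum of area x per-m^2 habitat curves.

    Returns g sugar day^-1 for the whole cell; standard errors propagate
    as the root-sum-square of area-scaled curve standard errors (habitat
    fits are independent).
    """
    grid = None
    total = var = None
    for habitat, area in sorted(comp.areas.items()):
        if area <= 0:
            continue
        if not include_gardens and habitat == GARDEN:
            continue
        if habitat not in curves:
            if habitat in ("arable", "urban_other"):
                continue  # conventionally nectarless unless a curve is given
            raise KeyError(f"no phenology curve for habitat {habitat!r}")
        c = curves[habitat]
        if grid is None:
            grid = np.asarray(c.grid)
            total = np.zeros(len(grid))
            var = np.zeros(len(grid))
        elif not np.array_equal(grid, c.grid):
            raise ValueError("habitat curves must share one day grid")
        total += area * c.value
        var += (area * c.se) ** 2
    if grid is None:
        raise ValueError("composition has no habitat with positive area")
    name = f"{comp.landscape_id}:{'with' if include_gardens else 'without'}_gardens"
    return PhenologyCurve(name, grid, total, np.sqrt(var))


def garden_fraction(
    curves: Mapping[str, PhenologyCurve], comp: LandscapeComposition
) -> pd.DataFrame:
    """Daily fraction of landscape nectar supply provided by gardens.

    Days with zero total supply yield NaN (undefined, never 0).  The
    returned frame carries the delta-method s.e. and a boolean column
    marking days where gardens provide the majority (> 50%) of supply.
    """
    with_g = aggregate_landscape(curves, comp, include_gardens=True)
    without_g = aggregate_landscape(curves, comp, include_gardens=False)
    g_area = comp.areas.get(GARDEN, 0.0)
    if g_area > 0:
        gc = curves[GARDEN]
        gval, gse = g_area * gc.value, g_area * gc.se
    else:
        gval = np.zeros(len(with_g.grid))
        gse = np.zeros(len(with_g.grid))
    total = with_g.value
    rest, rest_se = without_g.value, without_g.se
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, gval / total, np.nan)
        var = (rest * gse) ** 2 + (gval * rest_se) ** 2
        se = np.where(total > 0, np.sqrt(var) / total**2, np.nan)
    return pd.DataFrame(
        {
            "day": with_g.grid,
            "fraction": frac,
            "se": se,
            "majority_garden": np.where(np.isnan(frac), False, frac > 0.5),
        }
    )


def default_population_models() -> list[BeePopulationModel]:
    """Typical colony densities/sizes and monthly activity of the three
    commonest UK farmland bumblebees.  Numbers are implementer-supplied
    defaults within published ranges, not measured values."""
    return [
        BeePopulationModel(
            "B_terrestris",
            29.0,
            300.0,
            [0, 0, 0.05, 0.2, 0.45, 0.7, 1.0, 0.9, 0.5, 0.15, 0, 0],
        ),
        BeePopulationModel(
            "B_pascuorum",
            68.0,
            100.0,
            [0, 0, 0.03, 0.12, 0.4, 0.7, 1.0, 0.95, 0.55, 0.15, 0, 0],
        ),
        BeePopulationModel(
            "B_lapidarius",
            117.0,
            150.0,
            [0, 0, 0.02, 0.1, 0.35, 0.7, 1.0, 0.85, 0.4, 0.1, 0, 0],
        ),
    ]


def default_demand() -> DemandCurve:
    return DemandCurve()


def bee_population(
    models: Sequence[BeePopulationModel], cell_area_km2: float = 1.0, grid=None
) -> PhenologyCurve:
    """Daily bumblebee head count in the cell (step function by month)."""
    if not models:
        raise ValueError("at least one population model required")
    if grid is None:
        grid = np.arange(60, 305)
    grid = np.asarray(grid)
    months = month_of_day(grid)
    bees = np.zeros(len(grid))
    for m in models:
        bees += (
            m.colony_density
            * cell_area_km2
            * m.colony_size
            * m.monthly_weights[months - 1]
        )
    return PhenologyCurve("bees", grid, bees, np.zeros(len(grid)))


def per_bee_supply(supply: PhenologyCurve, bees: PhenologyCurve):
    """Pointwise supply / bees: g sugar bee^-1 day^-1.

    Days with zero bees are excluded from the returned curve and listed in
    the second return value — division by zero is never silent.
    """
    if not np.array_equal(supply.grid, bees.grid):
        raise ValueError("supply and bee curves must share one day grid")
    ok = bees.value > 0
    excluded = np.asarray(supply.grid)[~ok]
    grid = np.asarray(supply.grid)[ok]
    val = supply.value[ok] / bees.value[ok]
    se = supply.se[ok] / bees.value[ok]
    return PhenologyCurve("per_bee", grid, val, se), excluded


def find_deficits(
    per_bee: PhenologyCurve, demand: DemandCurve, scenario: str = ""
) -> DeficitReport:
    """Maximal consecutive-day runs where per-bee supply < requirement.

    Each interval carries its maximum shortfall (g bee^-1 day^-1).  The
    grid must be consecutive days (a daily grid), so runs are well defined.
    """
    days = np.asarray(per_bee.grid)
    if len(days) == 0:
        return DeficitReport(scenario)
    if np.any(np.diff(days) != 1):
        raise ValueError("find_deficits requires a consecutive daily grid")
    req = demand.requirement(days)
    short = req - per_bee.value
    deficit = short > 0
    intervals = []
    i = 0
    n = len(days)
    while i < n:
        if deficit[i]:
            j = i
            while j + 1 < n and deficit[j + 1]:
                j += 1
            intervals.append((int(days[i]), int(days[j]), float(short[i : j + 1].max())))
            i = j + 1
        else:
            i += 1
    return DeficitReport(scenario, intervals)
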