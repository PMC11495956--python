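"""Daily-timestep bumblebee colony simulator on discrete nectar patches.

Model sketch.  Each model year, a cohort of queens emerges in spring
(Normal around 1 April, truncated to the season), forages solo until it
either accumulates a founding energy threshold within a fixed search
window (founding a colony at its location) or dies.  Colonies send
workers on foraging trips; a trip's destination patch is drawn with
probability proportional to an exponential distance-detection kernel
times the patch's current nectar stock, its yield is capped by the crop
capacity and by what the patch still holds, and its cost is flight time
plus a handling time that grows with corolla depth and with depletion.
Colony energy drives brood initiation (capped by worker care capacity);
brood matures to workers after a fixed development time; after the
August switch date surplus goes into new queens (gynes).  A colony whose
energy runs out dies and stays dead.  Patch stocks replenish each day to
that day's production (area x per-m^2 phenology curve) — standing crop
is one day's secretion.  Surviving new queens, thinned by overwinter
survival and capped, found the next year's cohort.

Sugar is conserved exactly within each foraging day: the summed stock
decrease equals the summed gross intake of colonies and queens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from nectarscape.abm.config import AbmConfig
from nectarscape.synthetic import GARDEN, MONTH_STARTS, CELL_AREA_M2

TREATMENTS = (
    "garden",
    "no_garden",
    "pasture_replacement",
    "garden_with_pasture_phenology",
)

_QUEEN_STATES = ("hibernating", "searching", "founded", "dead")


@dataclass
class Patch:
    """One forage patch: a homogeneous area with a daily nectar curve."""

    patch_id: str
    x: float
    y: float
    area: float  # m^2
    habitat: str
    nectar_curve: np.ndarray  # g sugar m^-2 day^-1, length 365
    corolla_depth: float = 5.0  # mm
    sugar_concentration: float = 40.0  # g per 100 ml
    stock: float = 0.0  # g sugar currently standing

    def __post_init__(self):
        self.nectar_curve = np.asarray(self.nectar_curve, dtype=float)
        if self.nectar_curve.shape != (365,):
            raise ValueError("nectar_curve must have 365 daily values")
        if np.any(self.nectar_curve < 0):
            raise ValueError("nectar_curve must be non-negative")

    def annual_integral(self) -> float:
        """g sugar m^-2 yr^-1."""
        return float(self.nectar_curve.sum())


@dataclass
class Colony:
    """Snapshot view of one colony's state."""

    colony_id: int
    nest_location: tuple[float, float]
    energy_store: float
    workers: int
    brood: int
    new_queens_produced: int
    alive: bool
    founding_day: int


@dataclass
class QueenAgent:
    """Snapshot view of one spring queen."""

    emergence_day: int
    energy: float
    state: str


@dataclass
class TreatmentSpec:
    """A rule applied to garden patches only."""

    name: str

    def __post_init__(self):
        if self.name not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.name!r}; one of {TREATMENTS}")


@dataclass
class SimResult:
    """Five population endpoints, averaged over simulated years."""

    monthly_colony_density: np.ndarray  # colonies km^-2, sampled day 15 each month
    max_colonies_per_year: float
    total_bees_per_year: float
    new_queens_per_year: float
    spring_queen_survival: float  # percent
    years: int
    seed: int


def apply_treatment(
    patches: Sequence[Patch],
    spec: TreatmentSpec,
    pasture_curve: np.ndarray | None = None,
) -> list[Patch]:
    """Transform garden patches according to the treatment rule.

    * ``garden`` — identity (the very same patch objects are returned);
    * ``no_garden`` — garden nectar curves set to zero;
    * ``pasture_replacement`` — garden curves replaced by the pasture curve;
    * ``garden_with_pasture_phenology`` — garden curves replaced by the
      pasture curve rescaled so each patch keeps its own annual per-m^2
      sugar integral (same quantity, pasture timing).

    Non-garden patches are never modified.
    """
    if spec.name == "garden":
        return list(patches)
    needs_pasture = spec.name in ("pasture_replacement", "garden_with_pasture_phenology")
    if needs_pasture:
        pasture_curve = np.asarray(pasture_curve, dtype=float)
        p_int = float(pasture_curve.sum())
        if spec.name == "garden_with_pasture_phenology" and p_int <= 0:
            raise ValueError("pasture curve has zero annual integral")
    out = []
    for p in patches:
        if p.habitat != GARDEN:
            out.append(p)
            continue
        if spec.name == "no_garden":
            curve = np.zeros(365)
        elif spec.name == "pasture_replacement":
            curve = pasture_curve.copy()
        else:  # garden_with_pasture_phenology
            curve = pasture_curve * (p.annual_integral() / p_int)
        out.append(
            Patch(
                p.patch_id,
                p.x,
                p.y,
                p.area,
                p.habitat,
                curve,
                p.corolla_depth,
                p.sugar_concentration,
            )
        )
    return out


def build_patches(
    patch_table: pd.DataFrame,
    curves: Mapping[str, np.ndarray],
    corolla: Mapping[str, float] | None = None,
    concentration: Mapping[str, float] | None = None,
) -> list[Patch]:
    """Patch objects from a patch table plus per-habitat daily curves.

    Habitats missing from ``curves`` (e.g. arable, urban_other) get a zero
    curve — they hold no nectar but still occupy space.
    """
    corolla = corolla or {}
    concentration = concentration or {}
    zero = np.zeros(365)
    out = []
    for row in patch_table.itertuples(index=False):
        c = curves.get(row.habitat)
        curve = np.asarray(c, dtype=float) if c is not None else zero
        out.append(
            Patch(
                row.patch_id,
                float(row.x_m),
                float(row.y_m),
                float(row.area_m2),
                row.habitat,
                curve.copy(),
                float(corolla.get(row.habitat, 5.0)),
                float(concentration.get(row.habitat, 40.0)),
            )
        )
    return out


class World:
    """Mutable simulation state for one model year.

    Holds the patch arrays, the spring-queen cohort and the colony arrays;
    :func:`daily_forage` and :func:`daily_colony_update` advance it by one
    day each.  Colony slots are preallocated (each queen founds at most
    one colony) and vectorized across agents.
    """

    def __init__(self, patches: Sequence[Patch], config: AbmConfig):
        self.config = config
        self.patches = list(patches)
        n = len(self.patches)
        self.px = np.array([p.x for p in self.patches])
        self.py = np.array([p.y for p in self.patches])
        self.parea = np.array([p.area for p in self.patches])
        # g day^-1 per patch per day-of-year (area-scaled production)
        self.production = np.array(
            [p.nectar_curve * p.area for p in self.patches]
        ).reshape(n, 365)
        # handling time scales with corolla depth relative to the reference
        self.handling_min = config.handling_base_min * np.array(
            [p.corolla_depth / config.reference_corolla_mm for p in self.patches]
        )
        self.stock = np.zeros(n)
        self.day = 0
        self._alloc_colonies(0)
        self._init_queens(np.zeros(0))

    # -- cohort / colony setup --------------------------------------------

    def _alloc_colonies(self, cap: int) -> None:
        n = len(self.patches)
        self.c_n = 0
        self.c_x = np.zeros(cap)
        self.c_y = np.zeros(cap)
        self.c_energy = np.zeros(cap)
        self.c_workers = np.zeros(cap, dtype=int)
        self.c_alive = np.zeros(cap, dtype=bool)
        self.c_founding_day = np.zeros(cap, dtype=int)
        self.c_new_queens = np.zeros(cap, dtype=int)
        self.c_workers_produced = np.zeros(cap, dtype=int)
        self.c_worker_brood = np.zeros((cap, self.config.development_days), dtype=int)
        self.c_gyne_brood = np.zeros((cap, self.config.development_days), dtype=int)
        self.c_dist = np.zeros((cap, n))
        self.c_det = np.zeros((cap, n))

    def _init_queens(self, emergence_days: np.ndarray, x=None, y=None) -> None:
        nq = len(emergence_days)
        self.q_emergence = np.asarray(emergence_days, dtype=int)
        self.q_energy = np.zeros(nq)
        self.q_state = np.zeros(nq, dtype=np.int8)  # index into _QUEEN_STATES
        self.q_x = np.zeros(nq) if x is None else np.asarray(x, dtype=float)
        self.q_y = np.zeros(nq) if y is None else np.asarray(y, dtype=float)
        self.q_dist = np.hypot(
            self.q_x[:, None] - self.px[None, :], self.q_y[:, None] - self.py[None, :]
        )
        self.q_det = np.exp(-self.q_dist / self.config.detection_scale_m)

    def start_year(self, n_queens: int, rng: np.random.Generator) -> None:
        cfg = self.config
        lo, hi = cfg.emergence_window
        days = rng.normal(cfg.emergence_mean_day, cfg.emergence_sd_days, n_queens)
        r = 950.0 * np.sqrt(rng.uniform(size=n_queens))
        th = rng.uniform(0, 2 * np.pi, n_queens)
        self._init_queens(
            np.clip(np.round(days), lo, hi), r * np.cos(th), r * np.sin(th)
        )
        self._alloc_colonies(n_queens)
        self.day = self.config.season_start

    def _grow_colonies(self) -> None:
        extra = max(8, len(self.c_x) // 2)
        n = len(self.patches)
        for name, shape in (
            ("c_x", (extra,)),
            ("c_y", (extra,)),
            ("c_energy", (extra,)),
        ):
            setattr(self, name, np.concatenate([getattr(self, name), np.zeros(shape)]))
        for name in ("c_workers", "c_founding_day", "c_new_queens", "c_workers_produced"):
            setattr(
                self,
                name,
                np.concatenate([getattr(self, name), np.zeros(extra, dtype=int)]),
            )
        self.c_alive = np.concatenate([self.c_alive, np.zeros(extra, dtype=bool)])
        dev = self.config.development_days
        self.c_worker_brood = np.vstack(
            [self.c_worker_brood, np.zeros((extra, dev), dtype=int)]
        )
        self.c_gyne_brood = np.vstack(
            [self.c_gyne_brood, np.zeros((extra, dev), dtype=int)]
        )
        self.c_dist = np.vstack([self.c_dist, np.zeros((extra, n))])
        self.c_det = np.vstack([self.c_det, np.zeros((extra, n))])

    def add_colony(
        self, x: float, y: float, energy: float = 0.0, workers: int = 0
    ) -> int:
        """Place a colony directly (used at founding and in tests)."""
        if self.c_n == len(self.c_x):
            self._grow_colonies()
        i = self.c_n
        self.c_x[i], self.c_y[i] = x, y
        self.c_energy[i] = energy
        self.c_workers[i] = workers
        self.c_alive[i] = True
        self.c_founding_day[i] = self.day
        self.c_dist[i] = np.hypot(self.px - x, self.py - y)
        self.c_det[i] = np.exp(-self.c_dist[i] / self.config.detection_scale_m)
        self.c_n += 1
        return i

    def _found_colony(self, qi: int) -> None:
        i = self.add_colony(
            float(self.q_x[qi]), float(self.q_y[qi]), float(self.q_energy[qi])
        )
        self.c_dist[i] = self.q_dist[qi]
        self.c_det[i] = self.q_det[qi]

    # -- views -------------------------------------------------------------

    def colonies(self) -> list[Colony]:
        out = []
        for i in range(self.c_n):
            out.append(
                Colony(
                    i,
                    (float(self.c_x[i]), float(self.c_y[i])),
                    float(self.c_energy[i]),
                    int(self.c_workers[i]),
                    int(self.c_worker_brood[i].sum() + self.c_gyne_brood[i].sum()),
                    int(self.c_new_queens[i]),
                    bool(self.c_alive[i]),
                    int(self.c_founding_day[i]),
                )
            )
        return out

    def queens(self) -> list[QueenAgent]:
        return [
            QueenAgent(int(d), float(e), _QUEEN_STATES[s])
            for d, e, s in zip(self.q_emergence, self.q_energy, self.q_state)
        ]

    @property
    def n_alive(self) -> int:
        return int(self.c_alive[: self.c_n].sum())

    # -- daily steps --------------------------------------------------------

    def replenish(self) -> None:
        """Set stocks to the day's production (standing crop = one day)."""
        self.stock = self.production[:, self.day - 1].copy()


def daily_forage(world: World, rng: np.random.Generator) -> float:
    """One day of foraging for all searching queens and live colonies.

    Each forager makes ``trips_per_forager`` trips; destination patches
    are drawn from a multinomial with probability proportional to
    detection(distance) x stock.  A trip collects min(crop capacity,
    remaining stock share); trip cost is flight plus handling time (longer
    on deep corollas and depleted patches) at per-minute sugar rates.
    Returns the total gross sugar removed (equals the stock decrease).
    """
    cfg = world.config
    world.last_gross_total = world.last_removed_total = 0.0
    alive = world.c_alive[: world.c_n]
    col_idx = np.flatnonzero(alive)
    q_idx = np.flatnonzero(world.q_state == 1)  # searching

    # foragers per agent: workers (queen forages while colony has none)
    col_foragers = np.maximum(world.c_workers[: world.c_n][col_idx], 1)
    foragers = np.concatenate([col_foragers, np.ones(len(q_idx), dtype=int)])
    if len(foragers) == 0:
        return 0.0

    det = np.concatenate([world.c_det[col_idx], world.q_det[q_idx]], axis=0)
    dist = np.concatenate([world.c_dist[col_idx], world.q_dist[q_idx]], axis=0)

    open_patch = world.stock > cfg.stock_eps
    if not open_patch.any():
        return 0.0
    weights = det[:, open_patch] * world.stock[open_patch]
    wsum = weights.sum(axis=1)
    active = wsum > 0
    if not active.any():
        return 0.0
    p = weights[active] / wsum[active, None]
    trips = foragers[active] * cfg.trips_per_forager
    visits = rng.multinomial(trips, p)

    demand = visits * cfg.crop_capacity
    patch_demand = demand.sum(axis=0)
    stock_open = world.stock[open_patch]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(patch_demand > 0, np.minimum(1.0, stock_open / patch_demand), 0.0)
    gross = demand @ ratio  # per-agent intake
    removed = patch_demand * ratio
    world.stock[open_patch] = stock_open - removed
    # conservation diagnostics: summed intake == summed stock decrease
    world.last_gross_total = float(gross.sum())
    world.last_removed_total = float(removed.sum())

    # costs: flight both ways plus handling, scaled by depletion scarcity
    travel_min = 2.0 * dist[np.ix_(active, open_patch)] / cfg.flight_speed_m_min
    scarcity = 2.0 - ratio  # depleted patches take up to twice as long
    handling = world.handling_min[open_patch] * scarcity
    cost = (visits * (travel_min * cfg.flight_cost_g_min + handling * cfg.handling_cost_g_min)).sum(
        axis=1
    )
    net = gross - cost

    n_col = len(col_idx)
    act = np.flatnonzero(active)
    col_part = act[act < n_col]
    q_part = act[act >= n_col]
    world.c_energy[col_idx[col_part]] += net[act < n_col]
    if len(q_part):
        world.q_energy[q_idx[q_part - n_col]] += net[act >= n_col]
    return float(removed.sum())


def daily_colony_update(world: World, rng: np.random.Generator) -> None:
    """Queen state transitions, colony maintenance, brood and mortality."""
    cfg = world.config
    day = world.day

    # queens: emerge, pay costs, found or die
    emerging = (world.q_state == 0) & (world.q_emergence <= day)
    world.q_state[emerging] = 1
    world.q_energy[emerging] = cfg.queen_initial_energy
    searching = world.q_state == 1
    world.q_energy[searching] -= cfg.queen_daily_cost
    founding = searching & (world.q_energy >= cfg.founding_energy)
    for qi in np.flatnonzero(founding):
        world.q_state[qi] = 2
        world._found_colony(qi)
    dying = (
        searching
        & ~founding
        & (
            (world.q_energy < 0)
            | (day - world.q_emergence >= cfg.queen_search_days)
        )
    )
    world.q_state[dying] = 3

    n = world.c_n
    if n == 0:
        return
    alive = world.c_alive[:n]
    workers = world.c_workers[:n]
    wq = world.c_worker_brood[:n]
    gq = world.c_gyne_brood[:n]
    brood = wq.sum(axis=1) + gq.sum(axis=1)

    # maintenance
    upkeep = (
        workers * cfg.worker_daily_cost
        + brood * cfg.brood_daily_cost
        + cfg.colony_queen_daily_cost
    )
    world.c_energy[:n][alive] -= upkeep[alive]

    # starvation: dead colonies are inert and never recover
    dead = alive & (world.c_energy[:n] < 0)
    if dead.any():
        world.c_alive[:n][dead] = False
        world.c_workers[:n][dead] = 0
        wq[dead] = 0
        gq[dead] = 0
    alive = world.c_alive[:n]

    # brood maturation (queue position 0 matures today)
    matured_workers = wq[:, 0].copy()
    matured_gynes = gq[:, 0].copy()
    wq[:, :-1] = wq[:, 1:]
    wq[:, -1] = 0
    gq[:, :-1] = gq[:, 1:]
    gq[:, -1] = 0
    new_workers = np.where(alive, matured_workers, 0)
    world.c_workers[:n] = np.minimum(
        world.c_workers[:n] + new_workers, cfg.max_workers
    )
    world.c_workers_produced[:n] += new_workers
    gynes = np.where(alive, matured_gynes, 0)
    world.c_new_queens[:n] += gynes

    # worker senescence
    w = world.c_workers[:n]
    deaths = rng.binomial(w, min(1.0, 1.0 / cfg.worker_lifespan_days))
    world.c_workers[:n] = w - deaths

    # egg laying from surplus energy, capped by care capacity
    reserve = cfg.reserve_days * (
        world.c_workers[:n] * cfg.worker_daily_cost + cfg.colony_queen_daily_cost
    )
    surplus = world.c_energy[:n] - reserve
    care_cap = np.minimum(
        cfg.max_eggs_per_day,
        2.0 + cfg.brood_care_per_worker * world.c_workers[:n],
    )
    is_gyne_season = cfg.queen_switch_day < day <= cfg.queen_rearing_end_day
    if day > cfg.queen_rearing_end_day:
        eggs = np.zeros(n, dtype=int)  # laying over; colonies wind down
        cost = 0.0
    else:
        cost = cfg.gyne_cost if is_gyne_season else cfg.egg_cost
        if is_gyne_season:
            care_cap = np.minimum(care_cap, cfg.max_gynes_per_day)
        eggs = np.clip(np.floor(surplus / cost), 0, care_cap).astype(int)
        eggs[~alive] = 0
    if is_gyne_season:
        gq[:, -1] += eggs
    else:
        wq[:, -1] += eggs
    world.c_energy[:n] -= eggs * cost
    # nectar storage is bounded by honeypot capacity: colonies cannot bank
    # the mid-summer glut to fund autumn queen rearing
    np.minimum(world.c_energy[:n], cfg.max_energy_store, out=world.c_energy[:n])


def run_simulation(
    patches: Sequence[Patch],
    treatment: TreatmentSpec | str,
    config: AbmConfig | None = None,
    seed: int = 0,
    pasture_curve: np.ndarray | None = None,
    cell_area_km2: float = CELL_AREA_M2 / 1e6,
) -> SimResult:
    """Run the colony model for ``config.years`` years under one treatment.

    Year 1 starts with ``config.initial_queens`` queens; each later year
    starts with the surviving new queens of the previous year (binomial
    overwinter survival, capped at ``max_queen_carryover``).  Endpoints
    are averaged over years.  Deterministic given ``seed``.
    """
    config = config or AbmConfig()
    if config.years <= 0:
        raise ValueError("years must be > 0")
    if isinstance(treatment, str):
        treatment = TreatmentSpec(treatment)
    if pasture_curve is None:
        pasture = [p for p in patches if p.habitat == "pasture"]
        pasture_curve = pasture[0].nectar_curve if pasture else np.zeros(365)
    patches = apply_treatment(patches, treatment, pasture_curve)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    world = World(patches, config)

    sample_days = [int(MONTH_STARTS[m]) + 14 for m in range(12)]  # 15th of month
    monthly = np.zeros((config.years, 12))
    max_colonies = np.zeros(config.years)
    total_bees = np.zeros(config.years)
    new_queens = np.zeros(config.years)
    survival = np.zeros(config.years)

    n_queens = config.initial_queens
    for year in range(config.years):
        if n_queens <= 0:
            break
        world.start_year(n_queens, rng)
        for day in range(config.season_start, config.season_end + 1):
            world.day = day
            world.replenish()
            daily_forage(world, rng)
            daily_colony_update(world, rng)
            if day in sample_days:
                monthly[year, sample_days.index(day)] += world.n_alive
            max_colonies[year] = max(max_colonies[year], world.n_alive)
        emerged = len(world.q_state)
        founded = int((world.q_state == 2).sum())
        survival[year] = 100.0 * founded / emerged if emerged else 0.0
        queens_made = int(world.c_new_queens[: world.c_n].sum())
        new_queens[year] = queens_made
        total_bees[year] = int(world.c_workers_produced[: world.c_n].sum()) + queens_made
        n_queens = min(
            int(rng.binomial(queens_made, config.overwinter_survival)),
            config.max_queen_carryover,
        )

    return SimResult(
        monthly_colony_density=monthly.mean(axis=0) / cell_area_km2,
        max_colonies_per_year=float(max_colonies.mean()),
        total_bees_per_year=float(total_bees.mean()),
        new_queens_per_year=float(new_queens.mean()),
        spring_queen_survival=float(survival.mean()),
        years=config.years,
        seed=seed,
    )
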