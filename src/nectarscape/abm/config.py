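"""All numeric constants of the colony simulator, in one documented place.

The engine is a structurally faithful but simplified single-species
(*Bombus terrestris*) colony model; its constants are not measured values
but defaults chosen to give multi-year colony persistence on landscapes
with intact gardens.  Energies are grams of sucrose-equivalent sugar;
distances metres; times days unless noted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml


@dataclass
class AbmConfig:
    # --- annual cycle -----------------------------------------------------
    years: int = 5
    season_start: int = 60  # 1 March
    season_end: int = 304  # 31 October
    initial_queens: int = 500  # founding cohort, year 1
    max_queen_carryover: int | None = None  # default: initial_queens
    overwinter_survival: float = 0.3  # new queen -> next-spring queen

    # --- queen emergence and founding ------------------------------------
    emergence_mean_day: float = 91.0  # 1 April
    emergence_sd_days: float = 28.0
    emergence_window: tuple[int, int] = (60, 150)  # truncation of the draw
    queen_search_days: int = 21  # days to reach founding energy, else death
    queen_initial_energy: float = 0.2
    founding_energy: float = 1.0  # energy needed to found a colony
    queen_daily_cost: float = 0.06

    # --- foraging ---------------------------------------------------------
    trips_per_forager: int = 10  # trips per forager per day (time budget)
    crop_capacity: float = 0.06  # g sugar per full crop load
    detection_scale_m: float = 400.0  # exponential detection kernel e^{-d/L}
    flight_speed_m_min: float = 300.0
    flight_cost_g_min: float = 6.0e-4  # sugar burned per minute of flight
    handling_cost_g_min: float = 1.5e-4
    handling_base_min: float = 3.0  # handling time at reference corolla
    reference_corolla_mm: float = 5.0
    stock_eps: float = 1.0e-3  # patches below this stock are not worth a trip

    # --- colony economy ---------------------------------------------------
    worker_daily_cost: float = 0.012
    brood_daily_cost: float = 0.006
    colony_queen_daily_cost: float = 0.05
    reserve_days: float = 2.0  # energy held back before brood investment
    egg_cost: float = 0.05  # upfront investment per worker egg
    gyne_cost: float = 0.5  # upfront investment per new-queen egg
    development_days: int = 14
    max_eggs_per_day: int = 8
    max_gynes_per_day: int = 6  # queen-rearing care limit per colony
    brood_care_per_worker: float = 0.5  # extra eggs/day each worker can tend
    max_workers: int = 250
    max_energy_store: float = 75.0  # honeypot capacity: days, not months
    worker_lifespan_days: float = 30.0
    queen_switch_day: int = 213  # 1 August: eggs become gynes after this
    queen_rearing_end_day: int = 258  # mid-September: laying stops

    def __post_init__(self):
        if self.years <= 0:
            raise ValueError("years must be > 0")
        if self.max_queen_carryover is None:
            self.max_queen_carryover = self.initial_queens

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AbmConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "emergence_window" in data:
            data["emergence_window"] = tuple(data["emergence_window"])
        return cls(**data)
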