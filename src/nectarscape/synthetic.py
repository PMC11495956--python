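"""Synthetic floral surveys, bee transects, landscapes and landcover rasters.

Every downstream stage of the package is exercisable on data from this
module, which emulates a Southwest-UK farmland/garden study system with
known ground truth:

* farmland habitats (pasture, woodland, hedgerow, field margin) are
  species-poor, with bloom windows clustered into a spring and a summer
  pulse, so the farmland nectar curve is bimodal with troughs in early
  spring and late summer;
* gardens are species-rich (56 species by default) with bloom peaks
  spread March-October, giving a low but flat nectar curve;
* quadrat counts are negative-binomial overdispersed; transect counts
  are Poisson with a seasonal garden:farmland activity ratio;
* model landscapes are 1 km-radius discs (3.14 km^2) with garden cover
  between 0.2% and 5.9%;
* landcover rasters cluster urban cells into settlements.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

DAYS = np.arange(1, 366)
SEASON_START, SEASON_END = 60, 304  # 1 Mar .. 31 Oct, 365-day year

FARMLAND_HABITATS = ("pasture", "woodland", "hedgerow", "field_margin")
GARDEN = "garden"

#: Month -> first day-of-year (365-day year, no leap handling).
MONTH_STARTS = np.array([1, 32, 60, 91, 121, 152, 182, 213, 244, 274, 305, 335])


def month_of_day(day):
    """Month (1-12) containing each day-of-year (1-365)."""
    return np.searchsorted(MONTH_STARTS, np.asarray(day), side="right")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SpeciesSpec:
    """Trait record for one (abstract) flowering species.

    ``sugar_per_floral_unit`` is grams of sucrose-equivalent sugar secreted
    per open floral unit per 24 h; ``peak_density`` is open floral units
    per m^2 of its habitat at the bloom peak.
    """

    species_id: str
    sugar_per_floral_unit: float
    bloom_peak_day: float
    bloom_sd: float
    peak_density: float
    corolla_depth: float = 5.0
    sugar_concentration: float = 40.0

    def __post_init__(self):
        if self.sugar_per_floral_unit <= 0:
            raise ValueError("sugar_per_floral_unit must be > 0")
        if not 1 <= self.bloom_peak_day <= 365:
            raise ValueError("bloom_peak_day must be in [1, 365]")
        if self.bloom_sd <= 0:
            raise ValueError("bloom_sd must be > 0")
        if self.peak_density < 0:
            raise ValueError("peak_density must be >= 0")

    def density(self, day):
        """Expected floral units per m^2 on each day (Gaussian bloom kernel)."""
        day = np.asarray(day, dtype=float)
        return self.peak_density * np.exp(
            -0.5 * ((day - self.bloom_peak_day) / self.bloom_sd) ** 2
        )

    def sugar_density(self, day):
        """Expected g sugar m^-2 day^-1 on each day."""
        return self.density(day) * self.sugar_per_floral_unit


@dataclass
class HabitatProfile:
    """Species mix of one habitat with a count-overdispersion parameter."""

    habitat: str
    species: list[SpeciesSpec]
    weights: np.ndarray
    dispersion: float = 1.5

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.species):
            raise ValueError("one weight per species required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    def true_curve(self, days=DAYS):
        """Noiseless g sugar m^-2 day^-1 for this habitat."""
        out = np.zeros(len(days))
        for sp in self.species:
            out += sp.sugar_density(days)
        return out

    def trait_table(self) -> pd.DataFrame:
        return species_trait_table(self.species)


@dataclass
class SyntheticTruth:
    """Ground truth attached to a synthetic dataset."""

    true_curves: dict[str, np.ndarray] = field(default_factory=dict)
    true_ratio_profile: pd.DataFrame | None = None
    landscape_specs: list | None = None

    def curve(self, habitat: str) -> np.ndarray:
        return self.true_curves[habitat]


def species_trait_table(species: Sequence[SpeciesSpec]) -> pd.DataFrame:
    rows = [
        {
            "species_id": sp.species_id,
            "sugar_per_floral_unit": sp.sugar_per_floral_unit,
            "corolla_depth": sp.corolla_depth,
            "sugar_concentration": sp.sugar_concentration,
        }
        for sp in species
    ]
    return pd.DataFrame(rows).set_index("species_id")


# ---------------------------------------------------------------------------
# species pools

# Peak total floral density (units m^-2) by habitat.  Hedgerows and margins
# are dense but short-lived; pasture is poor; gardens moderate but long-lived.
_HABITAT_DENSITY = {
    "pasture": 14.0,
    "woodland": 45.0,
    "hedgerow": 150.0,
    "field_margin": 80.0,
    GARDEN: 95.0,
}
# Farmland bloom pulses: (spring window, summer window) for peak day draws.
_SPRING_WINDOW = (105.0, 138.0)
_SUMMER_WINDOW = (170.0, 200.0)
# Ivy-like autumn bloom in hedgerows: real farmland keeps a weak late
# nectar source, so the August-October trough is low but not absolute zero.
_AUTUMN_WINDOW = (238.0, 258.0)
_AUTUMN_SHARE = 0.08
# Habitat -> which pulse its species flower in.
_HABITAT_PULSE = {
    "woodland": "spring",
    "hedgerow": "spring",
    "pasture": "summer",
    "field_margin": "summer",
}


def gen_species_pool(
    n_farmland: int = 8, n_garden: int = 56, seed: int = 0
) -> dict[str, HabitatProfile]:
    """Draw the species pool and return one :class:`HabitatProfile` per habitat.

    Farmland habitats share ``n_farmland`` species whose bloom peaks fall in
    either a spring (late April-May) or a summer (July) pulse, producing a
    bimodal farmland curve with troughs in March and August-October.  The
    garden habitat holds ``n_garden`` species with peaks spread over the
    whole March-October season, producing a comparatively flat curve.
    """
    if n_farmland < 1 or n_garden < 1:
        raise ValueError("n_farmland and n_garden must be >= 1")
    rng = np.random.default_rng(seed)

    profiles: dict[str, HabitatProfile] = {}
    # assign farmland species to habitats cyclically
    by_habitat: dict[str, list[SpeciesSpec]] = {h: [] for h in FARMLAND_HABITATS}
    shares: dict[str, list[float]] = {h: [] for h in FARMLAND_HABITATS}
    # when the pool is big enough, an extra ivy-like autumn bloomer is
    # appended to hedgerows at a small fixed share (real farmland keeps a
    # weak late nectar source)
    n_total = n_farmland + (1 if n_farmland >= 4 else 0)
    for i in range(n_total):
        autumn = i == n_farmland
        if autumn:
            habitat = "hedgerow"
            lo, hi = _AUTUMN_WINDOW
            sd_lo, sd_hi = 22.0, 28.0
            share = _AUTUMN_SHARE * float(rng.uniform(0.8, 1.2))
        else:
            habitat = FARMLAND_HABITATS[i % len(FARMLAND_HABITATS)]
            lo, hi = (
                _SPRING_WINDOW
                if _HABITAT_PULSE[habitat] == "spring"
                else _SUMMER_WINDOW
            )
            sd_lo, sd_hi = 8.0, 12.0
            share = rng.uniform(0.5, 1.0)
        shares[habitat].append(share)
        by_habitat[habitat].append(
            SpeciesSpec(
                species_id=f"farm_sp{i:02d}",
                sugar_per_floral_unit=float(rng.lognormal(np.log(2.0e-3), 0.4)),
                bloom_peak_day=float(rng.uniform(lo, hi)),
                bloom_sd=float(rng.uniform(sd_lo, sd_hi)),
                peak_density=np.nan,  # filled below once shares are known
                corolla_depth=float(rng.uniform(1.0, 12.0)),
                sugar_concentration=float(rng.uniform(30.0, 55.0)),
            )
        )
    for habitat in FARMLAND_HABITATS:
        specs, shr = by_habitat[habitat], np.asarray(shares[habitat], dtype=float)
        if not specs:  # n_farmland < 4: leave habitat with a token zero species
            specs = [
                SpeciesSpec(
                    species_id=f"{habitat}_none",
                    sugar_per_floral_unit=1e-6,
                    bloom_peak_day=180.0,
                    bloom_sd=20.0,
                    peak_density=0.0,
                )
            ]
            shr = np.array([1.0])
        w = shr / shr.sum()
        specs = [
            SpeciesSpec(
                species_id=sp.species_id,
                sugar_per_floral_unit=sp.sugar_per_floral_unit,
                bloom_peak_day=sp.bloom_peak_day,
                bloom_sd=sp.bloom_sd,
                peak_density=float(_HABITAT_DENSITY[habitat] * wi),
                corolla_depth=sp.corolla_depth,
                sugar_concentration=sp.sugar_concentration,
            )
            for sp, wi in zip(specs, w)
        ]
        profiles[habitat] = HabitatProfile(habitat, specs, w)

    g_shares = rng.uniform(0.3, 1.0, n_garden)
    g_w = g_shares / g_shares.sum()
    garden_species = [
        SpeciesSpec(
            species_id=f"garden_sp{i:02d}",
            sugar_per_floral_unit=float(rng.lognormal(np.log(2.0e-3), 0.5)),
            bloom_peak_day=float(rng.uniform(60.0, 295.0)),
            bloom_sd=float(rng.uniform(18.0, 32.0)),
            peak_density=float(_HABITAT_DENSITY[GARDEN] * g_w[i]),
            corolla_depth=float(rng.uniform(2.0, 15.0)),
            sugar_concentration=float(rng.uniform(30.0, 55.0)),
        )
        for i in range(n_garden)
    ]
    profiles[GARDEN] = HabitatProfile(GARDEN, garden_species, g_w)
    return profiles


def default_schedule() -> dict[str, np.ndarray]:
    """Survey dates (day-of-year): farmland weekly, gardens monthly."""
    weekly = np.arange(SEASON_START, SEASON_END + 1, 7)
    monthly = np.array([74, 105, 135, 166, 196, 227, 258, 288])  # ~15th Mar-Oct
    sched = {h: weekly for h in FARMLAND_HABITATS}
    sched[GARDEN] = monthly
    return sched


def _doy_to_date(doy: int, year: int = 2017) -> str:
    ts = pd.Timestamp(year, 1, 1) + pd.Timedelta(days=int(doy) - 1)
    return ts.strftime("%Y-%m-%d")


def gen_floral_surveys(
    profiles: Mapping[str, HabitatProfile],
    schedule: Mapping[str, np.ndarray] | None = None,
    quadrats_per_visit: int = 60,
    n_gardens: int = 59,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate quadrat/garden floral surveys and return records plus truth.

    Farmland habitats are surveyed with ``quadrats_per_visit`` 1 m^2
    quadrats per visit (split over three farm sites); each garden is
    surveyed whole, with its own sampled area (mean 156.4 m^2).  Counts are
    negative-binomial around the Gaussian bloom-kernel mean.  Woodland
    species are treated as trees: counts cover a 5 m vertical column and
    carry a plant height, so downstream column scaling is exercised.
    """
    if schedule is None:
        schedule = default_schedule()
    if any(len(np.asarray(d)) == 0 for d in schedule.values()):
        raise ValueError("empty survey schedule")
    for dates in schedule.values():
        d = np.asarray(dates)
        if d.min() < 1 or d.max() > 365:
            raise ValueError("schedule dates must lie within one calendar year")
    if quadrats_per_visit < 1:
        raise ValueError("quadrats_per_visit must be >= 1")
    rng = np.random.default_rng(seed)

    garden_areas = np.clip(
        rng.lognormal(np.log(156.4) - 0.45**2 / 2, 0.45, n_gardens), 31.3, 407.7
    )

    rows = []
    for habitat in sorted(schedule):
        profile = profiles[habitat]
        k = profile.dispersion
        is_garden = habitat == GARDEN
        for doy in np.asarray(schedule[habitat]):
            date = _doy_to_date(int(doy), 2019 if is_garden else 2017)
            if is_garden:
                units_area = [(f"garden{g:02d}", garden_areas[g]) for g in range(n_gardens)]
            else:
                units_area = [
                    (f"farm{q % 3 + 1}", 1.0) for q in range(quadrats_per_visit)
                ]
            for q, (site, area) in enumerate(units_area):
                for sp in profile.species:
                    tree = habitat == "woodland"
                    height = float(rng.uniform(6.0, 18.0)) if tree else np.nan
                    mu = sp.density(doy) * area
                    if tree:
                        mu *= 5.0 / height  # counts cover the 5 m column only
                    if mu > 0:
                        count = int(rng.negative_binomial(k, k / (k + mu)))
                    else:
                        count = 0
                    rows.append(
                        (
                            site,
                            habitat,
                            date,
                            q,
                            sp.species_id,
                            count,
                            area,
                            tree,
                            height,
                        )
                    )
    records = pd.DataFrame(
        rows,
        columns=[
            "site",
            "habitat",
            "date",
            "quadrat",
            "species_id",
            "floral_units",
            "sampled_area_m2",
            "column_capped",
            "plant_height_m",
        ],
    )
    truth = SyntheticTruth(
        true_curves={h: profiles[h].true_curve() for h in schedule}
    )
    return records, truth


def all_trait_table(profiles: Mapping[str, HabitatProfile]) -> pd.DataFrame:
    return pd.concat([p.trait_table() for p in profiles.values()])


# ---------------------------------------------------------------------------
# transects

BUMBLEBEE_SPECIES = ("B_terrestris", "B_pascuorum", "B_lapidarius", "B_pratorum")

#: Farmland encounter rate, bees km^-1, by month (BeeWalk-like seasonality).
_FARMLAND_RATE = {3: 0.5, 4: 1.5, 5: 3.0, 6: 5.0, 7: 6.0, 8: 4.0, 9: 2.0, 10: 0.5}

#: True garden:farmland activity ratio by month: high in early spring and
#: late summer, near parity mid-summer.
DEFAULT_RATIO_PROFILE = {3: 3.0, 4: 2.2, 5: 1.4, 6: 1.1, 7: 1.2, 8: 4.0, 9: 6.0, 10: 9.0}

_SPECIES_RATE_SCALE = {
    "B_terrestris": 1.0,
    "B_pascuorum": 0.8,
    "B_lapidarius": 0.7,
    "B_pratorum": 0.35,
}


def default_ratio_profile() -> pd.DataFrame:
    """True monthly garden:farmland ratios, one row per species."""
    df = pd.DataFrame(
        {sp: DEFAULT_RATIO_PROFILE for sp in BUMBLEBEE_SPECIES}
    ).T
    df.index.name = "species"
    return df


def gen_transect_records(
    true_ratio_profile: pd.DataFrame | None = None,
    farmland_km_per_month: float = 493.0 / 8,
    garden_km_per_month: float = 168.0 / 8,
    n_ambiguous: int = 99,
    male_fraction: float = 0.12,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate BeeWalk-style transect records.

    Farmland counts per ~1 km section are Poisson with the stated per-km
    rate; garden counts use rate x true ratio.  Male records and
    agricultural-primary/garden-secondary sections are included so the
    downstream filters have something to remove.
    """
    if true_ratio_profile is None:
        true_ratio_profile = default_ratio_profile()
    if (true_ratio_profile.values <= 0).any():
        raise ValueError("ratios must be > 0")
    if farmland_km_per_month <= 0 or garden_km_per_month <= 0:
        raise ValueError("effort must be > 0")
    rng = np.random.default_rng(seed)

    rows = []
    section = 0
    for month, base in _FARMLAND_RATE.items():
        date = _doy_to_date(int(MONTH_STARTS[month - 1]) + 14, 2018)
        for habitat, km_total in (
            ("farmland", farmland_km_per_month),
            ("garden", garden_km_per_month),
        ):
            n_sections = max(1, int(round(km_total)))
            lengths = np.full(n_sections, km_total / n_sections)
            for length in lengths:
                section += 1
                for sp in true_ratio_profile.index:
                    rate = base * _SPECIES_RATE_SCALE.get(sp, 1.0)
                    if habitat == "garden":
                        rate *= float(true_ratio_profile.loc[sp, month])
                    count = int(rng.poisson(rate * length))
                    queens = int(rng.binomial(count, 0.3 if month <= 4 else 0.05))
                    # zero-count rows are kept: surveyed effort must be
                    # counted even when no bees were seen
                    rows.append(
                        (date, habitat, None, length, sp, "worker", count - queens, section)
                    )
                    if queens > 0:
                        rows.append(
                            (date, habitat, None, length, sp, "queen", queens, section)
                        )
                    males = int(rng.poisson(rate * length * male_fraction))
                    if males > 0 and month >= 7:
                        rows.append(
                            (date, habitat, None, length, sp, "male", males, section)
                        )
    # ambiguous sections: primarily agricultural, secondarily garden
    months = list(_FARMLAND_RATE)
    for i in range(n_ambiguous):
        m = months[i % len(months)]
        date = _doy_to_date(int(MONTH_STARTS[m - 1]) + 14, 2018)
        sp = BUMBLEBEE_SPECIES[i % 4]
        section += 1
        rows.append(
            (date, "agricultural", "garden", 1.0, sp, "worker", 1 + int(rng.poisson(2.0)), section)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "date",
            "primary_habitat",
            "secondary_habitat",
            "length_km",
            "species",
            "caste",
            "count",
            "section_id",
        ],
    )


# ---------------------------------------------------------------------------
# landscapes

CELL_AREA_M2 = np.pi * 1000.0**2  # 1 km-radius disc, ~3.14 km^2

#: Garden cover (%) of the 12 model landscapes.  Synthetic stand-in for the
#: real landscape compositions (which are not shipped with the package),
#: constructed to honour the printed constraints: minimum 0.2%, maximum
#: 5.9%, mean exactly 1.9%.
DEFAULT_GARDEN_COVER_PCT = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.5, 1.8, 2.2, 2.9, 4.3, 5.9)

_BASE_FRACTIONS = {
    "pasture": 0.50,
    "woodland": 0.12,
    "hedgerow": 0.03,
    "field_margin": 0.02,
    "arable": 0.24,
}

_PATCHES_PER_HABITAT = {
    "pasture": 6,
    "woodland": 3,
    "hedgerow": 10,
    "field_margin": 10,
    "arable": 5,
    "urban_other": 2,
}

_GARDEN_PATCH_M2 = 4000.0  # one patch ~ a small cluster of adjacent gardens


@dataclass
class Landscape:
    """One circular model landscape: composition plus a discrete patch map."""

    landscape_id: str
    areas: dict[str, float]  # habitat -> m^2
    cell_area: float
    patches: pd.DataFrame  # patch_id, x_m, y_m, area_m2, habitat

    def garden_fraction(self) -> float:
        return self.areas.get(GARDEN, 0.0) / self.cell_area


def _disc_point(rng, rmax=950.0):
    r = rmax * np.sqrt(rng.uniform())
    th = rng.uniform(0, 2 * np.pi)
    # centres snapped to a 10 m grid
    return round(r * np.cos(th), -1), round(r * np.sin(th), -1)


def gen_landscapes(
    n: int = 12,
    garden_cover_range: tuple[float, float] | None = None,
    seed: int = 0,
    garden_covers: Sequence[float] | None = None,
) -> list[Landscape]:
    """Generate ``n`` circular 1 km-radius landscapes with patch maps.

    Garden cover comes from (in order of precedence) ``garden_covers``
    (fractions), uniform draws in ``garden_cover_range``, or — when
    ``n == 12`` — the package's 12 reference cover values
    (:data:`DEFAULT_GARDEN_COVER_PCT`, mean 1.9%).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if garden_covers is not None:
        covers = np.asarray(garden_covers, dtype=float)
        if len(covers) != n:
            raise ValueError("need one garden cover per landscape")
    elif garden_cover_range is not None:
        lo, hi = garden_cover_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("garden cover range must satisfy 0 <= low <= high <= 1")
        covers = rng.uniform(lo, hi, n)
    elif n == 12:
        covers = np.asarray(DEFAULT_GARDEN_COVER_PCT) / 100.0
    else:
        covers = rng.uniform(0.002, 0.059, n)

    landscapes = []
    for i, g in enumerate(covers):
        jitter = rng.lognormal(0.0, 0.08, len(_BASE_FRACTIONS))
        base = np.array(list(_BASE_FRACTIONS.values())) * jitter
        base *= 0.91 / base.sum()  # non-garden vegetated share fixed at 91%
        areas = {
            h: float(f * CELL_AREA_M2) for h, f in zip(_BASE_FRACTIONS, base)
        }
        areas[GARDEN] = float(g * CELL_AREA_M2)
        areas["urban_other"] = float(CELL_AREA_M2 - sum(areas.values()))

        rows = []
        pid = 0
        # settlements: gardens cluster around 1-3 centres near the disc edge
        n_settlements = int(rng.integers(1, 4))
        centres = [_disc_point(rng, 800.0) for _ in range(n_settlements)]
        n_gpatch = (
            max(1, int(round(areas[GARDEN] / _GARDEN_PATCH_M2)))
            if areas[GARDEN] > 0
            else 0
        )
        gshare = rng.dirichlet(np.full(n_gpatch, 8.0)) if n_gpatch else []
        for j in range(n_gpatch):
            cx, cy = centres[j % n_settlements]
            x = round(float(np.clip(cx + rng.normal(0, 120), -950, 950)), -1)
            y = round(float(np.clip(cy + rng.normal(0, 120), -950, 950)), -1)
            rows.append((f"p{pid:04d}", x, y, areas[GARDEN] * gshare[j], GARDEN))
            pid += 1
        for habitat, k in _PATCHES_PER_HABITAT.items():
            area = areas.get(habitat, 0.0)
            if area <= 0:
                continue
            share = rng.dirichlet(np.full(k, 5.0))
            for s in share:
                x, y = _disc_point(rng)
                rows.append((f"p{pid:04d}", x, y, area * s, habitat))
                pid += 1
        patches = pd.DataFrame(
            rows, columns=["patch_id", "x_m", "y_m", "area_m2", "habitat"]
        )
        landscapes.append(
            Landscape(f"L{i + 1:02d}", areas, float(CELL_AREA_M2), patches)
        )
    return landscapes


# ---------------------------------------------------------------------------
# landcover rasters


@dataclass
class LandcoverRaster:
    """Class-coded raster with a resolution and class map."""

    grid: np.ndarray  # int codes, rows x cols
    resolution: float  # metres per pixel
    class_map: dict[int, str]
    nodata: int = -9999

    def mask(self, name: str) -> np.ndarray:
        codes = [c for c, n in self.class_map.items() if n == name]
        return np.isin(self.grid, codes)


CLASS_CODES = {0: "other", 1: "urban", 2: "arable", 3: "pasture"}


def gen_landcover_raster(
    size: int | tuple[int, int] = 200,
    resolution: float = 25.0,
    urban_fraction: float = 0.08,
    clustering: float = 3.0,
    seed: int = 0,
) -> LandcoverRaster:
    """Binary-urban + class raster with urban cells clustered into settlements.

    A white-noise field is smoothed with a Gaussian kernel (``clustering``
    = sigma in pixels) and the top ``urban_fraction`` quantile of cells is
    labelled urban, so the realized urban fraction is exact to one cell.
    Remaining cells are split into arable/pasture/other by a second,
    coarser smoothed field.
    """
    if not 0 <= urban_fraction <= 1:
        raise ValueError("urban_fraction must be in [0, 1]")
    shape = (size, size) if np.isscalar(size) else tuple(size)
    rng = np.random.default_rng(seed)
    n = shape[0] * shape[1]

    f = ndimage.gaussian_filter(rng.normal(size=shape), clustering)
    k = int(round(urban_fraction * n))
    urban = np.zeros(shape, dtype=bool)
    if k > 0:
        thresh_idx = np.argpartition(f.ravel(), n - k)[n - k:]
        urban.ravel()[thresh_idx] = True

    g = ndimage.gaussian_filter(rng.normal(size=shape), clustering * 3)
    grid = np.zeros(shape, dtype=np.int32)
    rest = ~urban
    if rest.any():
        q = np.quantile(g[rest], [0.45, 0.80])
        grid[rest & (g <= q[0])] = 2  # arable
        grid[rest & (g > q[0]) & (g <= q[1])] = 3  # pasture
        # remaining rest cells stay 0 = other
    grid[urban] = 1
    return LandcoverRaster(grid, float(resolution), dict(CLASS_CODES))
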