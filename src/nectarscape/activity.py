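"""Monthly garden:farmland bumblebee activity ratios from transect records.

Transect counts (BeeWalk-shaped: date, section habitat, section length,
species, caste, count) are filtered to unambiguous farmland or garden
sections, males are dropped, counts are scaled per km of transect walked
in each habitat-month, and the garden:farmland ratio of encounter rates
is computed per species and pooled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FARMLAND_LABELS = frozenset(
    {"farmland", "agricultural", "arable", "pasture", "improved_grassland"}
)
GARDEN_LABEL = "garden"
VALID_CASTES = frozenset({"worker", "queen", "male"})

__all__ = [
    "filter_transects",
    "activity_rate",
    "garden_farmland_ratio",
    "ratio_bootstrap",
]


def filter_transects(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep unambiguous farmland/garden sections; drop males.

    Sections primarily agricultural but secondarily garden are removed (to
    avoid ambiguity about which habitat the bees were using), as are male
    records (their foraging phenology differs from females').  Returns the
    filtered table (with a normalized ``habitat`` column) and the number
    of records removed per rule.  Idempotent.
    """
    bad_caste = set(records["caste"]) - VALID_CASTES
    if bad_caste:
        raise ValueError(f"unknown caste labels: {sorted(bad_caste)}")

    primary = records["primary_habitat"].astype(str)
    secondary = records.get("secondary_habitat")
    if secondary is None:
        secondary = pd.Series(pd.NA, index=records.index)
    is_farm = primary.isin(FARMLAND_LABELS)
    is_garden = primary == GARDEN_LABEL
    ambiguous = is_farm & (secondary == GARDEN_LABEL)
    male = records["caste"] == "male"
    other = ~(is_farm | is_garden)

    keep = (is_farm | is_garden) & ~ambiguous & ~male
    removed = {
        "ambiguous_habitat": int((ambiguous & ~male).sum()),
        "male": int(male.sum()),
        "other_habitat": int((other & ~male).sum()),
    }
    out = records.loc[keep].copy()
    out["habitat"] = np.where(
        out["primary_habitat"].eq(GARDEN_LABEL), "garden", "farmland"
    )
    return out, removed


def _month(dates: pd.Series) -> pd.Series:
    return pd.to_datetime(dates).dt.month


def _km_per_habitat_month(filtered: pd.DataFrame) -> pd.DataFrame:
    """Total km of transect walked per habitat-month.

    Each section is walked once per visit regardless of how many species
    rows it produced, so lengths are counted once per (section, date).
    """
    df = filtered.copy()
    df["month"] = _month(df["date"])
    key = ["habitat", "month"]
    if "section_id" in df.columns:
        sec = df.drop_duplicates(subset=["section_id", "date"])
    else:
        sec = df
    return sec.groupby(key)["length_km"].sum().rename("km")


def activity_rate(
    filtered: pd.DataFrame, habitat: str, month: int, species: str | None = None
) -> float:
    """Bees per km for one habitat-month (optionally one species).

    NaN (flagged missing) when no transect length was surveyed.
    """
    df = filtered.copy()
    df["month"] = _month(df["date"])
    sel = (df["habitat"] == habitat) & (df["month"] == month)
    km = _km_per_habitat_month(filtered)
    try:
        total_km = float(km.loc[(habitat, month)])
    except KeyError:
        total_km = 0.0
    if total_km <= 0:
        return float("nan")
    sub = df.loc[sel]
    if species is not None:
        sub = sub[sub["species"] == species]
    return float(sub["count"].sum()) / total_km


def garden_farmland_ratio(filtered: pd.DataFrame) -> pd.DataFrame:
    """Per species x month garden and farmland rates and their ratio.

    Includes a pooled ``all`` species row per month.  Ratio is NaN
    (missing) wherever the farmland rate is zero or a habitat-month was
    not surveyed — never infinity.
    """
    df = filtered.copy()
    df["month"] = _month(df["date"])
    km = _km_per_habitat_month(filtered)

    counts = (
        df.groupby(["habitat", "month", "species"])["count"].sum().rename("n")
    )
    pooled = df.groupby(["habitat", "month"])["count"].sum().rename("n")
    pooled = pd.concat({("all"): pooled}, names=["species"]).reorder_levels(
        ["habitat", "month", "species"]
    )
    counts = pd.concat([counts, pooled]).sort_index()

    rows = []
    months = sorted(df["month"].unique())
    species = sorted(df["species"].unique()) + ["all"]
    for m in months:
        for sp in species:
            rates = {}
            for hab in ("garden", "farmland"):
                total_km = float(km.get((hab, m), 0.0))
                n = float(counts.get((hab, m, sp), 0.0))
                rates[hab] = n / total_km if total_km > 0 else np.nan
            ratio = (
                rates["garden"] / rates["farmland"]
                if rates["farmland"] and not np.isnan(rates["farmland"])
                else np.nan
            )
            rows.append((m, sp, rates["garden"], rates["farmland"], ratio))
    return pd.DataFrame(
        rows, columns=["month", "species", "garden_rate", "farmland_rate", "ratio"]
    )


def ratio_bootstrap(
    filtered: pd.DataFrame,
    month: int,
    species: str | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, float, float]:
    """Nonparametric bootstrap CI for one month's garden:farmland ratio.

    Transect sections are the sampling unit: sections are resampled with
    replacement within each habitat.  Returns (ratio, lo, hi).
    """
    rng = np.random.default_rng(seed)
    df = filtered.copy()
    df["month"] = _month(df["date"])
    df = df[df["month"] == month]
    if species is not None:
        df = df[df["species"] == species]
    key = "section_id" if "section_id" in df.columns else None

    def _sections(hab):
        sub = df[df["habitat"] == hab]
        if key is None:
            return [(float(r.length_km), float(r["count"])) for _, r in sub.iterrows()]
        grp = sub.groupby(key).agg(km=("length_km", "first"), n=("count", "sum"))
        return list(zip(grp["km"], grp["n"]))

    g, f = _sections("garden"), _sections("farmland")
    if not g or not f:
        return float("nan"), float("nan"), float("nan")
    g_km, g_n = map(np.asarray, zip(*g))
    f_km, f_n = map(np.asarray, zip(*f))
    point = (g_n.sum() / g_km.sum()) / (f_n.sum() / f_km.sum())
    draws = np.empty(n_boot)
    for b in range(n_boot):
        gi = rng.integers(0, len(g_km), len(g_km))
        fi = rng.integers(0, len(f_km), len(f_km))
        fr = f_n[fi].sum() / f_km[fi].sum()
        draws[b] = (g_n[gi].sum() / g_km[gi].sum()) / fr if fr > 0 else np.nan
    alpha = (1 - ci) / 2
    lo, hi = np.nanquantile(draws, [alpha, 1 - alpha])
    return float(point), float(lo), float(hi)
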