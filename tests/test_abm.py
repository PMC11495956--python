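"""Colony simulator: treatments, foraging, colony dynamics, contrasts."""

import numpy as np
import pandas as pd
import pytest

from nectarscape import synthetic as synth
from nectarscape.abm import (
    AbmConfig,
    Patch,
    TreatmentSpec,
    World,
    apply_treatment,
    build_patches,
    daily_colony_update,
    daily_forage,
    run_experiment,
    run_simulation,
    treatment_contrasts,
)

FAST = AbmConfig(initial_queens=60, years=2)


def gaussian_curve(peak_day, sd, height):
    d = np.arange(1, 366, dtype=float)
    return height * np.exp(-0.5 * ((d - peak_day) / sd) ** 2)


def make_patch(pid="p0", habitat="garden", x=0.0, y=0.0, area=1000.0, curve=None):
    curve = curve if curve is not None else gaussian_curve(180, 60, 0.02)
    return Patch(pid, x, y, area, habitat, curve)


class TestApplyTreatment:
    pasture = gaussian_curve(190, 15, 0.05)

    def test_garden_treatment_is_identity(self):
        patches = [make_patch(), make_patch("p1", habitat="pasture")]
        out = apply_treatment(patches, TreatmentSpec("garden"), self.pasture)
        assert out[0] is patches[0] and out[1] is patches[1]

    def test_no_garden_zeroes_garden_sugar_only(self):
        patches = [make_patch(), make_patch("p1", habitat="pasture")]
        out = apply_treatment(patches, TreatmentSpec("no_garden"), self.pasture)
        assert out[0].annual_integral() == 0
        assert out[1] is patches[1]

    def test_pasture_replacement_uses_pasture_curve(self):
        out = apply_treatment(
            [make_patch()], TreatmentSpec("pasture_replacement"), self.pasture
        )
        np.testing.assert_array_equal(out[0].nectar_curve, self.pasture)

    def test_equal_quantity_preserves_annual_integral(self):
        p = make_patch()
        out = apply_treatment(
            [p], TreatmentSpec("garden_with_pasture_phenology"), self.pasture
        )
        assert out[0].annual_integral() == pytest.approx(
            p.annual_integral(), rel=1e-3
        )
        # but the timing is pasture's
        assert np.argmax(out[0].nectar_curve) == np.argmax(self.pasture)

    def test_zero_integral_pasture_rejected_for_rescaling(self):
        with pytest.raises(ValueError):
            apply_treatment(
                [make_patch()],
                TreatmentSpec("garden_with_pasture_phenology"),
                np.zeros(365),
            )

    def test_unknown_treatment_rejected(self):
        with pytest.raises(ValueError):
            TreatmentSpec("no_hedges")


class TestDailyForage:
    def test_empty_stocks_no_gain_energy_falls_by_upkeep(self):
        p = make_patch(curve=np.zeros(365))
        w = World([p], AbmConfig())
        w.day = 100
        w.add_colony(0.0, 0.0, energy=2.0, workers=10)
        w.replenish()
        rng = np.random.default_rng(0)
        daily_forage(w, rng)
        assert w.c_energy[0] == 2.0  # nothing collected, nothing spent flying
        daily_colony_update(w, rng)
        cfg = w.config
        eggs = int(w.c_worker_brood[0, -1])  # brood investment also draws energy
        expected = 2.0 - (
            10 * cfg.worker_daily_cost
            + cfg.colony_queen_daily_cost
            + eggs * cfg.egg_cost
        )
        assert w.c_energy[0] == pytest.approx(expected)
        assert w.c_energy[0] < 2.0

    def test_ample_stock_trip_yield_is_crop_capacity(self):
        cfg = AbmConfig()
        p = make_patch(curve=np.full(365, 1.0))  # 1000 g/day standing
        w = World([p], cfg)
        w.day = 100
        w.add_colony(0.0, 0.0, energy=1.0, workers=10)
        w.replenish()
        before = w.stock[0]
        daily_forage(w, np.random.default_rng(1))
        gross = before - w.stock[0]
        assert gross == pytest.approx(10 * cfg.trips_per_forager * cfg.crop_capacity)

    def test_near_patch_preferred_by_detection_kernel(self):
        """Two identical patches at 100 m and 900 m: the visit ratio over
        1000 trips approaches the kernel ratio e^{(900-100)/400} ~ 7.4."""
        cfg = AbmConfig()
        curve = np.full(365, 1.0)
        near = make_patch("near", x=100.0, area=1000.0, curve=curve)
        far = make_patch("far", x=900.0, area=1000.0, curve=curve)
        w = World([near, far], cfg)
        w.day = 150
        w.add_colony(0.0, 0.0, energy=1.0, workers=100)  # 1000 trips
        w.replenish()
        before = w.stock.copy()
        daily_forage(w, np.random.default_rng(2))
        visits = (before - w.stock) / cfg.crop_capacity
        ratio = visits[0] / visits[1]
        assert 5.0 < ratio < 11.0

    def test_sugar_conserved_each_day(self, landscapes, truth_curves):
        patches = build_patches(landscapes[7].patches, truth_curves)
        w = World(patches, AbmConfig())
        rng = np.random.default_rng(3)
        w.day = 60
        for i in range(5):
            w.add_colony(float(i * 100), 0.0, energy=1.0, workers=20)
        for day in range(120, 130):
            w.day = day
            w.replenish()
            before = w.stock.sum()
            daily_forage(w, rng)
            removed = before - w.stock.sum()
            assert removed == pytest.approx(w.last_gross_total, abs=1e-9)


class TestColonyUpdate:
    def test_starvation_kills_and_stays_dead(self):
        p = make_patch(curve=np.zeros(365))
        w = World([p], AbmConfig())
        w.day = 100
        w.add_colony(0.0, 0.0, energy=0.2, workers=10)
        rng = np.random.default_rng(0)
        for day in range(100, 140):
            w.day = day
            w.replenish()
            daily_forage(w, rng)
            daily_colony_update(w, rng)
        assert not w.c_alive[0]
        assert w.c_workers[0] == 0
        # inert: stays dead with zero agents
        for day in range(140, 150):
            w.day = day
            daily_colony_update(w, rng)
        assert not w.c_alive[0] and w.c_workers[0] == 0

    def test_unlimited_food_hits_worker_cap(self):
        cfg = AbmConfig()
        p = make_patch(curve=np.full(365, 10.0))
        w = World([p], cfg)
        w.day = 60
        w.add_colony(0.0, 0.0, energy=5.0, workers=1)
        rng = np.random.default_rng(1)
        for day in range(60, 213):
            w.day = day
            w.replenish()
            daily_forage(w, rng)
            daily_colony_update(w, rng)
        assert w.c_workers[0] == pytest.approx(cfg.max_workers, rel=0.2)

    def test_no_negative_stores_or_counts(self, landscapes, truth_curves):
        patches = build_patches(landscapes[2].patches, truth_curves)
        cfg = AbmConfig(initial_queens=40, years=1)
        w = World(patches, cfg)
        rng = np.random.default_rng(5)
        w.start_year(40, rng)
        for day in range(cfg.season_start, cfg.season_end + 1):
            w.day = day
            w.replenish()
            daily_forage(w, rng)
            daily_colony_update(w, rng)
            n = w.c_n
            assert np.all(w.stock >= -1e-12)
            assert np.all(w.c_workers[:n] >= 0)
            dead = ~w.c_alive[:n]
            assert np.all(w.c_workers[:n][dead] == 0)
            assert np.all(w.c_worker_brood[:n] >= 0)


class TestRunSimulation:
    def test_deterministic_given_seed(self, landscapes, truth_curves):
        patches = build_patches(landscapes[1].patches, truth_curves)
        a = run_simulation(patches, "garden", FAST, seed=42)
        b = run_simulation(patches, "garden", FAST, seed=42)
        assert a.max_colonies_per_year == b.max_colonies_per_year
        assert a.total_bees_per_year == b.total_bees_per_year
        np.testing.assert_array_equal(
            a.monthly_colony_density, b.monthly_colony_density
        )

    def test_zero_nectar_landscape_collapses(self, landscapes):
        zero = {h: np.zeros(365) for h in synth.FARMLAND_HABITATS} | {
            "garden": np.zeros(365)
        }
        patches = build_patches(landscapes[0].patches, zero)
        res = run_simulation(patches, "garden", FAST, seed=1)
        assert res.spring_queen_survival == 0.0
        assert res.max_colonies_per_year == 0.0

    def test_doubling_nectar_does_not_reduce_bees(self, landscapes, truth_curves):
        """Paired monotonicity over several seeds, in a food-limited regime
        where the supply actually constrains colony growth."""
        scarce = {h: 0.2 * c for h, c in truth_curves.items()}
        doubled = {h: 2 * c for h, c in scarce.items()}
        cfg = AbmConfig(initial_queens=50, years=2)
        ls = landscapes[4]
        p1 = build_patches(ls.patches, scarce)
        p2 = build_patches(ls.patches, doubled)
        base = np.mean(
            [run_simulation(p1, "garden", cfg, seed=s).total_bees_per_year for s in range(10)]
        )
        more = np.mean(
            [run_simulation(p2, "garden", cfg, seed=s).total_bees_per_year for s in range(10)]
        )
        assert more >= base

    def test_rejects_nonpositive_years(self):
        with pytest.raises(ValueError):
            AbmConfig(years=0)


class TestExperiment:
    def test_cardinality_and_determinism(self, landscapes, truth_curves):
        cfg = AbmConfig(initial_queens=30, years=1)
        t1 = run_experiment(
            landscapes[:2],
            truth_curves,
            treatments=("garden", "no_garden"),
            reps=1,
            config=cfg,
            seed=5,
        )
        assert len(t1) == 4
        t2 = run_experiment(
            landscapes[:2],
            truth_curves,
            treatments=("garden", "no_garden"),
            reps=1,
            config=cfg,
            seed=5,
        )
        pd.testing.assert_frame_equal(t1, t2)

    def test_reps_must_be_positive(self, landscapes, truth_curves):
        with pytest.raises(ValueError):
            run_experiment(landscapes[:1], truth_curves, reps=0)


def synthetic_table(effect_pct, noise_sd, seed, n_ls=12, reps=5):
    """Experiment table with a known injected treatment effect."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(50, 150, n_ls)
    rows = []
    for i in range(n_ls):
        for treatment, eff in (("garden", 0.0), ("treated", effect_pct)):
            for rep in range(reps):
                v = base[i] * (1 + eff / 100) + rng.normal(0, noise_sd)
                rows.append(
                    {
                        "landscape": f"L{i}",
                        "treatment": treatment,
                        "rep": rep,
                        "max_colonies_per_year": v,
                    }
                )
    return pd.DataFrame(rows)


class TestContrasts:
    def test_null_effect_ci_contains_zero(self):
        t = synthetic_table(0.0, 2.0, seed=1)
        out = treatment_contrasts(t, n_boot=2000, seed=2)
        row = out.iloc[0]
        assert row["ci_low"] <= 0 <= row["ci_high"]

    def test_exact_scaling_gives_degenerate_ci(self):
        t = synthetic_table(-20.0, 0.0, seed=3)
        out = treatment_contrasts(t, n_boot=500, seed=1)
        row = out.iloc[0]
        assert row["mean_pct_change"] == pytest.approx(-20.0)
        assert row["ci_low"] == pytest.approx(-20.0)
        assert row["ci_high"] == pytest.approx(-20.0)

    def test_recovers_injected_effect(self):
        t = synthetic_table(-15.0, 3.0, seed=7)
        out = treatment_contrasts(t, n_boot=5000, seed=11)
        row = out.iloc[0]
        assert row["ci_low"] <= -15.0 <= row["ci_high"]
        assert row["excludes_zero"]

    def test_missing_endpoint_is_error(self):
        t = synthetic_table(0.0, 1.0, seed=1)
        with pytest.raises(KeyError):
            treatment_contrasts(t, endpoint="nope")

    def test_missing_baseline_is_error(self):
        t = synthetic_table(0.0, 1.0, seed=1)
        with pytest.raises(ValueError):
            treatment_contrasts(t, baseline="absent")
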