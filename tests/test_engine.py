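"""Initialization, step loop, dosing, replicates and conservation laws."""

import math
from dataclasses import replace

import numpy as np
import pytest

from nkact.agents import (NC, NE, NV, MotilityParams, NKKillParams,
                          NKProliferationParams, ExhaustionParams,
                          PhenotypeRates, ProductParams, TumorParams)
from nkact.engine import (DoseEvent, GridConfig, Simulation, SimulationConfig,
                          TumorBolus, load_config, parse_etr, run_replicates,
                          tumor_only_config)


def _frozen_tumor(**kw):
    base = dict(p_b=0.0, d_b=0.0, m_b=0.0)
    base.update(kw)
    return TumorParams(**base)


class TestParseEtr:
    @pytest.mark.parametrize("raw,expected", [
        ("1:1", 1.0), ("1:5", 0.2), ("3:1", 3.0), (0.5, 0.5),
    ])
    def test_values(self, raw, expected):
        assert parse_etr(raw) == pytest.approx(expected)


class TestInitialization:
    def test_etr_one_to_one(self, static_product):
        cfg = SimulationConfig(n_tumor_init=1000, etr="1:1",
                               products={"NT": static_product()},
                               tumor=_frozen_tumor(), duration_days=1.0)
        sim = Simulation(cfg, seed=0)
        assert sim.total_tumor == 1000
        assert sim.counts[NC] == 1000
        assert sim.counts[NE] == sim.counts[NV] == 0

    def test_etr_one_to_five(self, static_product):
        cfg = SimulationConfig(n_tumor_init=1000, etr="1:5",
                               products={"NT": static_product()},
                               tumor=_frozen_tumor(), duration_days=1.0)
        assert Simulation(cfg, seed=0).counts[NC] == 200

    def test_central_disk_occupies_minimum_cells(self):
        cfg = SimulationConfig(n_tumor_init=1000, products={},
                               tumor=_frozen_tumor(), nk_at_start=False,
                               duration_days=1.0)
        sim = Simulation(cfg, seed=0)
        occupied = int((sim.grid.tumor_count > 0).sum())
        assert occupied >= math.ceil(1000 / 25)
        assert sim.grid.max_occupancy() <= 25
        # packed centrally: all occupied cells within a tight disk
        idx = np.argwhere(sim.grid.tumor_count > 0)
        center = np.array([49.5, 49.5])
        assert np.linalg.norm(idx - center, axis=1).max() < 10

    def test_nk_placed_outside_tumor_mass(self, static_product):
        cfg = SimulationConfig(n_tumor_init=500, etr=1.0,
                               products={"NT": static_product()},
                               tumor=_frozen_tumor(), duration_days=1.0)
        sim = Simulation(cfg, seed=1)
        for a in sim.agents:
            if not a.is_tumor:
                assert sim.grid.tumor_count[a.pos] == 0

    def test_grid_too_small_rejected(self):
        cfg = SimulationConfig(grid=GridConfig(width=3, height=3),
                               n_tumor_init=1000, products={},
                               nk_at_start=False, duration_days=1.0)
        with pytest.raises(ValueError, match="too small"):
            Simulation(cfg, seed=0)

    def test_unknown_dose_product_rejected(self, static_product):
        with pytest.raises(ValueError, match="unknown product"):
            SimulationConfig(products={"NT": static_product()},
                             dosing=[DoseEvent(day=1.0, product="CAR")],
                             duration_days=2.0)


class TestStep:
    def test_zero_agents_no_error(self):
        cfg = SimulationConfig(n_tumor_init=0, products={}, nk_at_start=False,
                               duration_days=1.0,
                               grid=GridConfig(width=5, height=5))
        sim = Simulation(cfg, seed=0)
        sim.step()
        rec = sim.record
        assert (rec[["B", "NC", "NE", "NV"]] == 0).all().all()

    def test_all_rates_zero_is_fixed_point(self, static_product):
        cfg = SimulationConfig(grid=GridConfig(width=10, height=10),
                               n_tumor_init=20, etr=0.5,
                               products={"NT": static_product(
                                   rates=PhenotypeRates(
                                       d_c=0, d_v=0, d_e=0, p_v=0,
                                       k_b_minus=0, k_b_plus=0),
                                   kill=NKKillParams(mu_c=-50, sigma_c=0))},
                               tumor=_frozen_tumor(), duration_days=1.0)
        sim = Simulation(cfg, seed=3)
        before = {id(a): a.pos for a in sim.agents}
        b0, nc0 = sim.total_tumor, sim.counts[NC]
        sim.step()
        assert sim.total_tumor == b0 and sim.counts[NC] == nc0
        assert {id(a): a.pos for a in sim.agents} == before

    def test_same_seed_bit_identical(self, static_product, effect_table,
                                     expression_pool):
        prod = ProductParams(
            kill=NKKillParams(mu_c=1.0, sigma_c=0.01),
            proliferation=NKProliferationParams(pc=0.2),
            exhaustion=ExhaustionParams(s0=4, variant="EM3"),
            rates=PhenotypeRates(d_c=0.1, d_e=0.2),
            motility=MotilityParams(),
            cytokine_species=("IL15",))
        from nkact.lattice import CytokineParams
        cfg = SimulationConfig(grid=GridConfig(width=30, height=30),
                               n_tumor_init=100, etr=1.0,
                               products={"CAR": prod},
                               cytokines={"IL15": CytokineParams()},
                               effect_table=effect_table,
                               expression_pool=expression_pool,
                               duration_days=3.0)
        r1 = Simulation(cfg, seed=11).run()
        r2 = Simulation(cfg, seed=11).run()
        assert r1.equals(r2)

    def test_death_cause_conservation(self, static_product):
        """Tumor deaths partition into cytotoxic + programmed exactly."""
        prod = static_product(kill=NKKillParams(mu_c=2.0, sigma_c=0.0),
                              motility=MotilityParams(m_n=0.9, v_n=39.0))
        cfg = SimulationConfig(grid=GridConfig(width=30, height=30),
                               n_tumor_init=200, etr=1.0,
                               products={"NT": prod},
                               tumor=TumorParams(p_b=0.2, d_b=0.05, m_b=0.1),
                               duration_days=4.0)
        sim = Simulation(cfg, seed=9)
        rec = sim.run()
        last = rec.iloc[-1]
        born = last["divisions_cum"]
        dead = last["deaths_cytotoxic_cum"] + last["deaths_programmed_cum"]
        assert 200 + born - dead == last["B"]
        # cumulative counters never decrease
        for col in ("deaths_cytotoxic_cum", "deaths_programmed_cum",
                    "divisions_cum"):
            assert rec[col].is_monotonic_increasing

    def test_nk_population_conservation(self, static_product):
        prod = static_product(rates=PhenotypeRates(d_c=0.3, d_e=0.5,
                                                   d_v=0.0, p_v=0.0))
        cfg = SimulationConfig(grid=GridConfig(width=20, height=20),
                               n_tumor_init=50, etr=2.0,
                               products={"NT": prod},
                               tumor=_frozen_tumor(), duration_days=4.0)
        sim = Simulation(cfg, seed=4)
        sim.run()
        live = sum(1 for a in sim.agents if not a.is_tumor and a.alive)
        assert live == sum(sim.counts.values())

    def test_genetics_free_when_b_zero(self, static_product, effect_table,
                                       expression_pool):
        from nkact.genetics import GeneticEffectParams
        prod = static_product(genetic=GeneticEffectParams(b=0.0))
        cfg = SimulationConfig(grid=GridConfig(width=20, height=20),
                               n_tumor_init=50, etr=1.0,
                               products={"NT": prod},
                               effect_table=effect_table,
                               expression_pool=expression_pool,
                               tumor=_frozen_tumor(), duration_days=1.0)
        sim = Simulation(cfg, seed=2)
        for a in sim.agents:
            if not a.is_tumor:
                assert a.profile is not None
                assert a.g_nk(prod.genetic) == 0.0


class TestTumorGrowthOracle:
    def test_log_linear_slope_recovers_rate(self, tumor_only_growth_config):
        """Sparse tumor-only growth: slope of ln(mean B) ~ p_b - d_b."""
        cfg = tumor_only_growth_config(p_b=0.455, duration_days=5.0,
                                       n_init=800, replicates=6)
        reps = run_replicates(cfg, base_seed=21)
        m = reps.mean
        slope = np.polyfit(m["day"], np.log(m["B"]), 1)[0]
        assert slope == pytest.approx(0.455 - 1e-4, rel=0.05)

    def test_no_programmed_death_when_rate_zero(self):
        cfg = SimulationConfig(grid=GridConfig(width=40, height=40),
                               n_tumor_init=200, products={},
                               tumor=TumorParams(p_b=0.3, d_b=0.0),
                               placement="uniform", nk_at_start=False,
                               duration_days=4.0)
        rec = Simulation(cfg, seed=1).run()
        assert (rec["deaths_programmed_cum"] == 0).all()


class TestReplicates:
    def test_single_replicate_aggregate(self, tumor_only_growth_config):
        cfg = tumor_only_growth_config(duration_days=1.0, n_init=100,
                                       replicates=1, width=40, height=40)
        reps = run_replicates(cfg, base_seed=3)
        assert len(reps) == 1
        assert np.allclose(reps.mean.to_numpy(float),
                           reps.replicates[0].to_numpy(float),
                           equal_nan=True)
        assert (reps.std[["B"]] == 0).all().all()

    def test_replicate_count_and_seed_offsets(self, tumor_only_growth_config):
        cfg = tumor_only_growth_config(duration_days=1.0, n_init=100,
                                       replicates=3, width=40, height=40)
        reps = run_replicates(cfg, base_seed=5)
        assert len(reps.replicates) == 3
        # replicate r is reproducible in isolation with seed base + r
        again = Simulation(cfg, seed=6).run()
        assert reps.replicates[1].equals(again)

    def test_tumor_only_config_strips_nk(self, static_product):
        cfg = SimulationConfig(products={"NT": static_product()}, etr=2.0,
                               dosing=[DoseEvent(day=1.0, product="NT")],
                               duration_days=2.0)
        ctl = tumor_only_config(cfg)
        assert ctl.n_nk_init == 0 and ctl.dosing == []


class TestDosing:
    def _cfg(self, dosing, static_product, **kw):
        return SimulationConfig(
            grid=GridConfig(width=40, height=40), n_tumor_init=100, etr=1.0,
            products={"NT": static_product()}, tumor=_frozen_tumor(),
            dosing=dosing, duration_days=10.0, **kw)

    def test_single_dose_adds_etr_scaled_cells(self, static_product):
        cfg = self._cfg([DoseEvent(day=2.0, product="NT", multiplier=1.0)],
                        static_product)
        sim = Simulation(cfg, seed=0)
        n0 = sim.counts[NC]
        for _ in range(12):  # through day 2
            sim.step()
        assert sim.counts[NC] == n0 + 100

    def test_4x_multiplier(self, static_product):
        cfg = self._cfg([DoseEvent(day=2.0, product="NT", multiplier=4.0)],
                        static_product)
        sim = Simulation(cfg, seed=0)
        n0 = sim.counts[NC]
        for _ in range(12):
            sim.step()
        assert sim.counts[NC] == n0 + 400

    def test_two_2x_events(self, static_product):
        cfg = self._cfg([DoseEvent(day=5.0, product="NT", multiplier=2.0),
                         DoseEvent(day=7.0, product="NT", multiplier=2.0)],
                        static_product)
        sim = Simulation(cfg, seed=0)
        n0 = sim.counts[NC]
        for _ in range(30):  # day 5
            sim.step()
        assert sim.counts[NC] == n0 + 200
        for _ in range(12):  # day 7
            sim.step()
        assert sim.counts[NC] == n0 + 400

    def test_tumor_bolus_rechallenge(self, static_product):
        cfg = SimulationConfig(
            grid=GridConfig(width=40, height=40), n_tumor_init=100,
            products={}, nk_at_start=False, tumor=_frozen_tumor(),
            tumor_boluses=[TumorBolus(day=1.0, n=50)],
            assay_mode="rechallenge", duration_days=2.0)
        sim = Simulation(cfg, seed=0)
        for _ in range(6):
            sim.step()
        assert sim.total_tumor == 150


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        y = tmp_path / "cfg.yaml"
        y.write_text("""
grid: {width: 20, height: 20, b_max: 25, dt_hours: 4.0}
duration_days: 2.0
etr: "1:5"
n_tumor_init: 50
placement: uniform
nk_at_start: true
tumor: {p_b: 0.455, d_b: 1.0e-4, m_b: 0.1}
cytokines:
  IL15: {half_life: 2.5}
products:
  NT:
    kill: {mu_c: 0.6, sigma_c: 0.01, gamma: 1.0}
    proliferation: {pc: 0.2, bpc: 0.01}
    exhaustion: {s0: 4, variant: EM1}
    rates: {d_c: 0.1, d_e: 0.2}
    cytokine_species: [IL15]
dosing:
  - {day: 1.0, product: NT, multiplier: 2.0}
""")
        cfg = load_config(y)
        assert cfg.etr == pytest.approx(0.2)
        assert cfg.products["NT"].kill.mu_c == 0.6
        assert cfg.products["NT"].cytokine_species == ("IL15",)
        assert cfg.dosing[0].multiplier == 2.0
        assert cfg.tumor.p_b == 0.455
        Simulation(cfg, seed=0).step()  # runnable

    def test_unknown_product_key_rejected(self, tmp_path):
        y = tmp_path / "bad.yaml"
        y.write_text("products:\n  NT:\n    typo: {}\n")
        with pytest.raises(ValueError, match="typo"):
            load_config(y)
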