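"""Simulation engine: initialization, the per-step loop, dosing, replicates.

One simulated tick is ΔT (default 4 h). Within a tick the agent activation
order is freshly shuffled with the run's seeded generator; each agent moves
and then acts (kill attempt / division / death), phenotype transitions are
resolved against the end-of-step tumor field, cytokine fields decay and
receive deposits, dosing events due that tick are applied and metrics are
recorded.

The simulated tumor burden stands in for bioluminescent radiance (assumed
proportional to population size), so normalized progression ratios computed
from these records are directly comparable to in-vivo radiance ratios.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agents import (NC, NE, NV, MotilityParams, NKAgent, NKKillParams,
                     NKProliferationParams, ExhaustionParams, PhenotypeRates,
                     ProductParams, TumorAgent, TumorParams,
                     attempt_kill, death_probability, division_probability,
                     nk_steps_per_move, phenotype_transitions,
                     proliferation_rate, sample_baseline_cytotoxicity,
                     sample_truncated_normal, stimulus_terms)
from .genetics import (GeneEffectTable, GeneticEffectParams,
                       assign_expression_profiles, load_effect_table)
from .lattice import CytokineParams, GridConfig, TMEGrid

__all__ = [
    "DoseEvent", "TumorBolus", "SimulationConfig", "Simulation",
    "ReplicateSet", "run_replicates", "tumor_only_config", "load_config",
    "parse_etr", "RECORD_COLUMNS",
]

RECORD_COLUMNS = [
    "step", "day", "B", "NC", "NE", "NV",
    "deaths_cytotoxic_cum", "deaths_programmed_cum",
    "divisions_cum", "mutated_divisions_cum",
    "cytokine_mean", "interaction_rate", "mean_pc",
    "fold_B", "fold_NK", "max_occupancy",
]


def parse_etr(etr) -> float:
    """Accept an effector-to-target ratio as a float or an 'E:T' string."""
    if isinstance(etr, str):
        e, t = etr.split(":")
        return float(e) / float(t)
    return float(etr)


@dataclass(frozen=True)
class DoseEvent:
    """One follow-up NK dose: ``multiplier`` x (n_tumor_init * etr) cells."""

    day: float
    product: str
    multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("dose multiplier must be positive")


@dataclass(frozen=True)
class TumorBolus:
    """Tumor re-challenge addition: ``n`` tumor cells at ``day``."""

    day: float
    n: int


@dataclass
class SimulationConfig:
    """Everything one run needs; replicate seeds derive from ``seed``."""

    grid: GridConfig = field(default_factory=GridConfig)
    duration_days: float = 14.0
    etr: float = 1.0
    n_tumor_init: int = 1000
    products: dict[str, ProductParams] = field(default_factory=dict)
    initial_product: str | None = None  # defaults to the first product
    tumor: TumorParams = field(default_factory=TumorParams)
    cytokines: dict[str, CytokineParams] = field(default_factory=dict)
    dosing: list[DoseEvent] = field(default_factory=list)
    tumor_boluses: list[TumorBolus] = field(default_factory=list)
    seed: int = 0
    replicates: int = 1
    record_every: int = 1
    assay_mode: str = "in_vivo"  # in_vivo | autonomous_growth | rechallenge
    placement: str = "center"    # center | uniform
    dose_placement: str = "periphery"  # periphery | peritumoral
    nk_at_start: bool = True
    day_offset: float = 0.0      # label offset vs in-vivo day counting
    effect_table: GeneEffectTable | None = None
    expression_pool: np.ndarray | pd.DataFrame | None = None
    tumor_antigen_pool: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.etr = parse_etr(self.etr)
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.etr < 0:
            raise ValueError("etr must be >= 0")
        if self.assay_mode not in {"in_vivo", "autonomous_growth", "rechallenge"}:
            raise ValueError(f"unknown assay_mode {self.assay_mode!r}")
        if self.placement not in {"center", "uniform"}:
            raise ValueError(f"unknown placement {self.placement!r}")
        for ev in self.dosing:
            if ev.day > self.duration_days:
                raise ValueError("dose events must fall within the duration")
            if ev.product not in self.products:
                raise ValueError(f"dose references unknown product {ev.product!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_days * 24.0 / self.grid.dt_hours))

    @property
    def n_nk_init(self) -> int:
        return int(round(self.n_tumor_init * self.etr)) if self.nk_at_start else 0


def tumor_only_config(config: SimulationConfig) -> SimulationConfig:
    """Matched control: same tumor dynamics and seeds, zero NK cells."""
    return replace(config, etr=0.0, dosing=[], nk_at_start=False)


class Simulation:
    """One seeded realization of the lattice model."""

    def __init__(self, config: SimulationConfig, seed: int | None = None) -> None:
        self.config = config
        self.rng = np.random.default_rng(config.seed if seed is None else seed)
        self.grid = TMEGrid(config.grid, config.cytokines)
        self.agents: list = []
        self.step_index = 0
        self.total_tumor = 0
        self.counts = {NC: 0, NE: 0, NV: 0}
        self.deaths_cytotoxic = 0
        self.deaths_programmed = 0
        self.divisions = 0
        self.mutated_divisions = 0
        self._pending_doses = sorted(config.dosing, key=lambda e: e.day)
        self._pending_boluses = sorted(config.tumor_boluses, key=lambda e: e.day)
        self._profiles_cache: dict[str, tuple] = {}
        self._mean_pc = 0.0
        self._records: list[list] = []
        self._b_init = 0
        self._nk_norm = 0
        self._max_occupancy_seen = 0
        self._initialize()

    # ------------------------------------------------------------------
    # initialization
    # ------------------------------------------------------------------

    def _center_positions(self) -> list[tuple[int, int]]:
        h, w = self.grid.shape
        ci, cj = (h - 1) / 2.0, (w - 1) / 2.0
        pos = [(i, j) for i in range(h) for j in range(w)]
        pos.sort(key=lambda p: ((p[0] - ci) ** 2 + (p[1] - cj) ** 2,
                                p[0], p[1]))
        return pos

    def _sample_antigen(self) -> float:
        pool = self.config.tumor_antigen_pool
        if pool is None or len(pool) == 0:
            return 1.0
        return float(pool[self.rng.integers(0, len(pool))])

    def _place_tumor(self, n: int, mode: str) -> None:
        cfg = self.config
        if mode == "center":
            order = self._center_positions()
            needed = math.ceil(n / cfg.grid.b_max)
            if needed > len(order):
                raise ValueError("grid too small for the tumor population")
            placed = 0
            for p in order:
                while self.grid.check_capacity(p) and placed < n:
                    self._add_tumor(TumorAgent(p, self._sample_antigen()))
                    placed += 1
                if placed >= n:
                    break
        else:  # uniform sparse placement (growth-rate assays)
            h, w = self.grid.shape
            placed = 0
            attempts = 0
            while placed < n:
                p = (int(self.rng.integers(0, h)), int(self.rng.integers(0, w)))
                if self.grid.check_capacity(p):
                    self._add_tumor(TumorAgent(p, self._sample_antigen()))
                    placed += 1
                attempts += 1
                if attempts > 100 * n + 1000:
                    raise ValueError("grid too small for the tumor population")

    def _periphery_positions(self) -> list[tuple[int, int]]:
        """Positions outside the tumor mass (annulus), nearest-first."""
        h, w = self.grid.shape
        ci, cj = (h - 1) / 2.0, (w - 1) / 2.0
        if self.total_tumor:
            occupied = np.argwhere(self.grid.tumor_count > 0)
            r_t = math.sqrt(max(((occupied[:, 0] - ci) ** 2 +
                                 (occupied[:, 1] - cj) ** 2).max(), 0.0))
        else:
            r_t = 0.0
        out = [(i, j) for i in range(h) for j in range(w)
               if (i - ci) ** 2 + (j - cj) ** 2 > (r_t + 1.0) ** 2]
        if not out:
            # scattered tumor (uniform placement): any tumor-free cell
            free = np.argwhere(self.grid.tumor_count == 0)
            out = [tuple(map(int, p)) for p in free]
        if not out:
            raise ValueError("grid too small: no periphery left for NK placement")
        return out

    def _peritumoral_positions(self) -> list[tuple[int, int]]:
        nb = self.grid.neighborhood_tumor_sum()
        cand = np.argwhere(nb > 0)
        if len(cand) == 0:
            return self._periphery_positions()
        return [tuple(map(int, p)) for p in cand]

    def _product_profiles(self, name: str):
        """Expression-profile source for a product (shared pool)."""
        cfg = self.config
        if cfg.effect_table is None or cfg.expression_pool is None:
            return None
        return cfg.effect_table, cfg.expression_pool

    def _make_nk(self, name: str, pos) -> NKAgent:
        cfg = self.config
        prod = cfg.products[name]
        c_nk = sample_baseline_cytotoxicity(prod.kill, self.rng)
        profile = None
        src = self._product_profiles(name)
        if src is not None:
            table, pool = src
            profile = assign_expression_profiles(pool, table, 1, self.rng)[0]
        return NKAgent(name, pos, c_nk, profile, prod.exhaustion.s0)

    def _add_nk_dose(self, name: str, n: int, positions) -> None:
        if n <= 0:
            return
        idx = self.rng.integers(0, len(positions), size=n)
        for k in idx:
            nk = self._make_nk(name, positions[int(k)])
            self.grid.register(nk, nk.pos)
            self.agents.append(nk)
            self.counts[NC] += 1

    def _add_tumor(self, tumor: TumorAgent) -> None:
        self.grid.register(tumor, tumor.pos)
        self.agents.append(tumor)
        self.total_tumor += 1

    def _initialize(self) -> None:
        cfg = self.config
        self._place_tumor(cfg.n_tumor_init, cfg.placement)
        if cfg.products and cfg.n_nk_init > 0:
            name = cfg.initial_product or next(iter(cfg.products))
            self._add_nk_dose(name, cfg.n_nk_init, self._periphery_positions())
        self._b_init = max(self.total_tumor, 1)
        self._nk_norm = sum(self.counts.values())
        self._record()

    # ------------------------------------------------------------------
    # per-agent handlers
    # ------------------------------------------------------------------

    def _move_tumor(self, t: TumorAgent) -> None:
        p = self.config.tumor
        if p.m_b == 0 or self.rng.random() >= p.m_b:
            return
        for _ in range(p.v_b):
            nbrs = [q for q in self.grid.neighborhood(t.pos)
                    if self.grid.check_capacity(q)]
            if not nbrs:
                return
            q = nbrs[self.rng.integers(0, len(nbrs))]
            self.grid.move(t, t.pos, q)
            t.pos = q

    def _tumor_step(self, t: TumorAgent) -> None:
        cfg = self.config
        dt = cfg.grid.dt_days
        self._move_tumor(t)
        p = cfg.tumor
        if self.rng.random() < death_probability(p.d_b, dt):
            self._kill_agent(t, cause="programmed")
            return
        if self.rng.random() < division_probability(p.p_b, dt):
            self._tumor_divide(t)

    def _tumor_divide(self, t: TumorAgent) -> None:
        if self.grid.check_capacity(t.pos):
            pos = t.pos
        else:
            nbrs = [q for q in self.grid.neighborhood(t.pos)
                    if self.grid.check_capacity(q)]
            if not nbrs:
                return  # division refused: BMax is a hard invariant
            pos = nbrs[self.rng.integers(0, len(nbrs))]
        daughter = TumorAgent(pos, t.antigen_expr, t.mutations)
        if self.rng.random() < self.config.tumor.p_mutate:
            daughter.mutations += 1
        self.divisions += 1
        if daughter.mutations > t.mutations:
            self.mutated_divisions += 1
        # register at once so capacity checks later in this step see it;
        # it acts from the next step (activation order was snapshotted)
        self._add_tumor(daughter)

    def _move_nk(self, nk: NKAgent, prod: ProductParams) -> None:
        m = prod.motility
        if m.m_n == 0 or self.rng.random() >= m.m_n:
            return
        g = self.config.grid
        n_sub = nk_steps_per_move(m, g.dt_hours, g.l, self.rng)
        chemotax = self.total_tumor > 0
        for _ in range(n_sub):
            nbrs = self.grid.neighborhood(nk.pos)
            if chemotax:
                scores = [self._nbhd_tumor[q] for q in nbrs]
                best = max(scores)
                cand = [q for q, s in zip(nbrs, scores) if s == best]
            else:
                cand = nbrs
            q = cand[self.rng.integers(0, len(cand))]
            self.grid.move(nk, nk.pos, q)
            nk.pos = q

    def _nk_kill_phase(self, nk: NKAgent, prod: ProductParams) -> None:
        if nk.s <= 0:
            return
        targets = [a for a in self.grid.agents_at(nk.pos) if a.is_tumor and a.alive]
        for q in self.grid.neighborhood(nk.pos):
            if self.grid.tumor_count[q]:
                targets.extend(a for a in self.grid.agents_at(q)
                               if a.is_tumor and a.alive)
        if not targets:
            return
        tgt = targets[self.rng.integers(0, len(targets))]
        killed = attempt_kill(nk, tgt, prod.kill, prod.exhaustion,
                              prod.genetic, self.config.tumor, self.rng)
        if killed:
            self._kill_agent(tgt, cause="cytotoxic")

    def _nk_step(self, nk: NKAgent) -> None:
        cfg = self.config
        prod = cfg.products[nk.product]
        dt = cfg.grid.dt_days
        ph = nk.phenotype
        if ph == NE:
            if self.rng.random() < death_probability(prod.rates.d_e, dt):
                self._kill_agent(nk)
            return
        self._move_nk(nk, prod)
        if ph == NC:
            self._nk_kill_phase(nk, prod)
            if self.rng.random() < death_probability(prod.rates.d_c, dt):
                self._kill_agent(nk)
                return
            b_local = int(self._nbhd_tumor[nk.pos])
            c_local = self.grid.total_cytokine(nk.pos)
            autonomous = cfg.assay_mode == "autonomous_growth"
            _, w = stimulus_terms(b_local, c_local, prod.proliferation,
                                  autonomous=autonomous)
            p_div = proliferation_rate(prod.proliferation, nk.age_t, w,
                                       dt, self.rng)
            self._pc_sum += p_div
            self._pc_n += 1
            if self.rng.random() < p_div:
                self._nk_divide(nk)
        else:  # NV
            if self.rng.random() < death_probability(prod.rates.d_v, dt):
                self._kill_agent(nk)
                return
            if prod.rates.p_v > 0 and self.rng.random() < division_probability(
                    prod.rates.p_v, dt):
                self._nk_divide(nk)
        nk.age_t += 1

    def _nk_divide(self, nk: NKAgent) -> None:
        daughter = NKAgent(nk.product, nk.pos, nk.c_nk,
                           None if nk.profile is None else nk.profile.copy(),
                           self.config.products[nk.product].exhaustion.s0)
        daughter.phenotype = nk.phenotype
        daughter.s = nk.s  # current capacity is inherited
        daughter.n_kills = nk.n_kills
        self.grid.register(daughter, daughter.pos)
        self.agents.append(daughter)
        self.counts[daughter.phenotype] += 1
        self._born_this_step.add(id(daughter))

    def _kill_agent(self, agent, cause: str | None = None) -> None:
        agent.alive = False
        self.grid.unregister(agent, agent.pos)
        if agent.is_tumor:
            self.total_tumor -= 1
            if cause == "cytotoxic":
                self.deaths_cytotoxic += 1
            else:
                self.deaths_programmed += 1
        else:
            self.counts[agent.phenotype] -= 1

    # ------------------------------------------------------------------
    # the step
    # ------------------------------------------------------------------

    def step(self) -> None:
        """Advance the model by one ΔT tick."""
        cfg = self.config
        self._born_this_step: set[int] = set()
        self._pc_sum, self._pc_n = 0.0, 0
        self._nbhd_tumor = self.grid.neighborhood_tumor_sum()
        order = list(self.agents)
        self.rng.shuffle(order)
        for agent in order:
            if not agent.alive:
                continue
            if agent.is_tumor:
                self._tumor_step(agent)
            else:
                self._nk_step(agent)
        # end-of-step phenotype transitions against the updated tumor field
        nbhd = self.grid.neighborhood_tumor_sum()
        for agent in self.agents:
            if agent.is_tumor or not agent.alive \
                    or id(agent) in self._born_this_step:
                continue
            old = agent.phenotype
            prod = cfg.products[agent.product]
            b = int(nbhd[agent.pos])
            new = phenotype_transitions(agent, b == 0, b > 0,
                                        prod.rates, prod.exhaustion, self.rng)
            if new != old:
                self.counts[old] -= 1
                self.counts[new] += 1
        # cytokine decay + armored deposition
        if self.grid.cytokine:
            armored: dict[str, list] = {}
            for a in self.agents:
                if not a.is_tumor and a.alive:
                    for sp in cfg.products[a.product].cytokine_species:
                        armored.setdefault(sp, []).append(a.pos)
            self.grid.update_cytokine_field(armored)
        self.step_index += 1
        self._apply_scheduled_events()
        if len(self.agents) > 4 * (self.total_tumor + sum(self.counts.values())) \
                and len(self.agents) > 10000:
            self.agents = [a for a in self.agents if a.alive]
        self._mean_pc = self._pc_sum / self._pc_n if self._pc_n else 0.0
        if self.step_index % cfg.record_every == 0 \
                or self.step_index == cfg.n_steps:
            self._record()

    def _apply_scheduled_events(self) -> None:
        day = self.step_index * self.config.grid.dt_days
        eps = 1e-9
        while self._pending_doses and self._pending_doses[0].day <= day + eps:
            ev = self._pending_doses.pop(0)
            n = int(round(ev.multiplier * self.config.n_tumor_init
                          * self.config.etr))
            pos = (self._peritumoral_positions()
                   if self.config.dose_placement == "peritumoral"
                   else self._periphery_positions())
            self._add_nk_dose(ev.product, n, pos)
            if self._nk_norm == 0:
                self._nk_norm = sum(self.counts.values())
        while self._pending_boluses and self._pending_boluses[0].day <= day + eps:
            ev = self._pending_boluses.pop(0)
            h, w = self.grid.shape
            placed, attempts = 0, 0
            while placed < ev.n and attempts < 100 * ev.n + 1000:
                p = (int(self.rng.integers(0, h)), int(self.rng.integers(0, w)))
                if self.grid.check_capacity(p):
                    self._add_tumor(TumorAgent(p, self._sample_antigen()))
                    placed += 1
                attempts += 1

    # ------------------------------------------------------------------
    # recording
    # ------------------------------------------------------------------

    def _record(self) -> None:
        cfg = self.config
        day = self.step_index * cfg.grid.dt_days + cfg.day_offset
        n_nk = sum(self.counts.values())
        if self.total_tumor > 0:
            nc_here = np.zeros(self.grid.shape, dtype=bool)
            for a in self.agents:
                if not a.is_tumor and a.alive and a.phenotype == NC:
                    nc_here[a.pos] = True
            with_nc = int(self.grid.tumor_count[nc_here].sum())
            interaction = with_nc / self.total_tumor
        else:
            interaction = 0.0
        cyt_mean = (float(np.mean(sum(self.grid.cytokine.values())))
                    if self.grid.cytokine else 0.0)
        occ = self.grid.max_occupancy()
        self._max_occupancy_seen = max(self._max_occupancy_seen, occ)
        self._records.append([
            self.step_index, day, self.total_tumor,
            self.counts[NC], self.counts[NE], self.counts[NV],
            self.deaths_cytotoxic, self.deaths_programmed,
            self.divisions, self.mutated_divisions,
            cyt_mean, interaction, self._mean_pc,
            self.total_tumor / self._b_init,
            (n_nk / self._nk_norm) if self._nk_norm else np.nan,
            occ,
        ])

    def run(self) -> pd.DataFrame:
        """Run to the configured duration; returns the time-series record."""
        for _ in range(self.config.n_steps):
            self.step()
        return self.record

    @property
    def record(self) -> pd.DataFrame:
        return pd.DataFrame(self._records, columns=RECORD_COLUMNS)


@dataclass
class ReplicateSet:
    """Per-replicate records plus pointwise mean/SD aggregates."""

    replicates: list[pd.DataFrame]
    mean: pd.DataFrame
    std: pd.DataFrame
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.replicates)


def run_replicates(config: SimulationConfig,
                   base_seed: int | None = None) -> ReplicateSet:
    """Run ``config.replicates`` seeded realizations and aggregate.

    Replicate ``r`` uses seed ``base_seed + r`` so runs are individually
    reproducible; aggregates are computed pointwise per recorded step.
    """
    base = config.seed if base_seed is None else base_seed
    records = [Simulation(config, seed=base + r).run()
               for r in range(config.replicates)]
    stack = pd.concat(records, keys=range(len(records)))
    grouped = stack.groupby(level=1)
    mean = grouped.mean()
    std = grouped.std(ddof=0) if len(records) > 1 else mean * 0.0
    return ReplicateSet(records, mean, std, config)


# ---------------------------------------------------------------------------
# YAML config
# ---------------------------------------------------------------------------

def _build(cls, data: dict):
    return cls(**data) if data else cls()


def load_config(path: str | Path) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML file.

    The YAML mirrors the dataclass field names; product blocks are nested
    dicts keyed by product name; ``effect_table`` / ``expression_pool`` may
    be file paths (CSV/TSV as documented in :mod:`nkact.genetics`).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "grid" in raw:
        kwargs["grid"] = _build(GridConfig, raw.pop("grid"))
    if "tumor" in raw:
        kwargs["tumor"] = _build(TumorParams, raw.pop("tumor"))
    if "cytokines" in raw:
        kwargs["cytokines"] = {k: _build(CytokineParams, v)
                               for k, v in raw.pop("cytokines").items()}
    if "products" in raw:
        prods = {}
        for name, block in raw.pop("products").items():
            block = dict(block or {})
            prods[name] = ProductParams(
                kill=_build(NKKillParams, block.pop("kill", {})),
                proliferation=_build(NKProliferationParams,
                                     block.pop("proliferation", {})),
                exhaustion=_build(ExhaustionParams, block.pop("exhaustion", {})),
                rates=_build(PhenotypeRates, block.pop("rates", {})),
                motility=_build(MotilityParams, block.pop("motility", {})),
                genetic=_build(GeneticEffectParams, block.pop("genetic", {})),
                cytokine_species=tuple(block.pop("cytokine_species", ())),
            )
            if block:
                raise ValueError(f"unknown product keys {sorted(block)}")
        kwargs["products"] = prods
    if "dosing" in raw:
        kwargs["dosing"] = [DoseEvent(**d) for d in raw.pop("dosing")]
    if "tumor_boluses" in raw:
        kwargs["tumor_boluses"] = [TumorBolus(**d)
                                   for d in raw.pop("tumor_boluses")]
    table_path = raw.pop("effect_table", None)
    pool_path = raw.pop("expression_pool", None)
    kwargs.update(raw)
    cfg = SimulationConfig(**kwargs)
    if table_path:
        cfg.effect_table = load_effect_table(table_path)
    if pool_path:
        p = Path(pool_path)
        sep = "\t" if p.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
        cfg.expression_pool = pd.read_csv(p, sep=sep, index_col=0)
    return cfg
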