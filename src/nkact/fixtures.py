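"""Synthetic data generators.

Everything the package needs to run end-to-end without downloads: a
synthetic gene/pathway effect table (standing in for an upstream
regression-coefficient table, with LAG3 and PDCD1 flagged as exhaustion
markers), a synthetic normalized-expression pool (log-normal stand-in for
pre-infusion single-cell profiles; real scRNA-seq count structure, batch
effects etc. are deliberately not emulated), analytic observed-progression
curves for fast calibration unit tests, and deterministic micro-scenarios
(tiny boards with known single-step outcome distributions) used as oracles
for the agent rules.

All generators are pure functions of (spec, seed): same spec, same bytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agents import (NC, NV, ExhaustionParams, MotilityParams, NKAgent,
                     NKKillParams, NKProliferationParams, PhenotypeRates,
                     ProductParams, TumorAgent, TumorParams)
from .calibration import ObservedProgression
from .engine import Simulation, SimulationConfig
from .genetics import GeneEffectTable
from .lattice import GridConfig

__all__ = [
    "FixtureSpec", "MARKER_GENES",
    "synth_effect_table", "synth_expression_pool", "synth_trajectory",
    "micro_scenario", "MICRO_SCENARIOS",
]

MARKER_GENES = ("LAG3", "PDCD1")


@dataclass(frozen=True)
class FixtureSpec:
    """Sizes, noise levels and seed for every synthetic generator."""

    n_genes: int = 20
    n_cells: int = 100
    include_markers: bool = True
    growth_rate_treated: float = 0.2   # per day, analytic trajectories
    growth_rate_control: float = 0.455
    noise_sd: float = 0.0
    sampling_days: tuple[float, ...] = (0.0, 7.0, 14.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells < 1:
            raise ValueError("n_genes and n_cells must be >= 1")
        if self.include_markers and self.n_genes < 2:
            raise ValueError("need >= 2 genes to include both markers")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(b <= a for a, b in zip(self.sampling_days,
                                      self.sampling_days[1:])):
            raise ValueError("sampling_days must be strictly increasing")


def synth_effect_table(spec: FixtureSpec) -> GeneEffectTable:
    """Coefficients ~ N(0, 0.5^2); marker genes flagged with negative betas.

    Negative marker coefficients encode that exhaustion-marker expression
    down-regulates anti-tumor activity, so marker accumulation during
    serial killing degrades the kill probability.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    betas = rng.normal(0.0, 0.5, size=n)
    ids = [f"GENE{i:03d}" for i in range(n)]
    flags = np.zeros(n, dtype=bool)
    if spec.include_markers:
        for k, marker in enumerate(MARKER_GENES):
            ids[k] = marker
            flags[k] = True
            betas[k] = -abs(betas[k]) - 0.05  # strictly negative
    return GeneEffectTable(ids, betas, flags)


def synth_expression_pool(spec: FixtureSpec) -> pd.DataFrame:
    """Non-negative (features x cells) matrix of log-normal pseudo-profiles.

    Per-feature scales vary over an order of magnitude so profiles are
    non-degenerate; rows are indexed by the matching effect-table ids.
    """
    rng = np.random.default_rng(spec.seed + 1)
    table = synth_effect_table(spec)
    scales = rng.uniform(0.1, 1.0, size=spec.n_genes)
    values = rng.lognormal(mean=0.0, sigma=0.5,
                           size=(spec.n_genes, spec.n_cells))
    values *= scales[:, None]
    return pd.DataFrame(values, index=table.feature_ids,
                        columns=[f"cell{j}" for j in range(spec.n_cells)])


def synth_trajectory(spec: FixtureSpec,
                     group: str = "treated") -> ObservedProgression:
    """Analytic normalized-progression curve with multiplicative noise.

    ratio(day) = exp((r_treated - r_control) * day) * (1 + eps),
    eps ~ N(0, noise_sd^2), clipped at 0. For calibration recovery tests
    prefer simulator-generated observations (see the calibration tests).
    """
    rng = np.random.default_rng(spec.seed + 2)
    dr = spec.growth_rate_treated - spec.growth_rate_control
    pts = []
    for d in spec.sampling_days:
        eps = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        pts.append((float(d), max(0.0, math.exp(dr * d) * (1.0 + eps))))
    return ObservedProgression({group: pts})


# ---------------------------------------------------------------------------
# micro-scenarios: tiny boards with known single-step outcome laws
# ---------------------------------------------------------------------------

def _static_product(**overrides) -> ProductParams:
    """A product with all autonomous dynamics off (micro-scenario default)."""
    base = dict(
        kill=NKKillParams(mu_c=0.5, sigma_c=0.0, gamma=1.0),
        proliferation=NKProliferationParams(pc=0.0, sigma_pc=0.0),
        exhaustion=ExhaustionParams(s0=5),
        rates=PhenotypeRates(d_c=0.0, d_v=0.0, d_e=0.0, p_v=0.0),
        motility=MotilityParams(m_n=0.0),
    )
    base.update(overrides)
    return ProductParams(**base)


def _static_tumor(**overrides) -> TumorParams:
    base = dict(p_b=0.0, d_b=0.0, m_b=0.0, p_evade_base=0.0)
    base.update(overrides)
    return TumorParams(**base)


def _scenario_one_nc_one_tumor(seed: int) -> Simulation:
    """3x3 board: one cytotoxic NK adjacent to one tumor cell.

    Per step the kill event is Bernoulli(p_kill) with
    p_kill = logistic(c_nk)^gamma (no genetics, no evasion); the empirical
    kill frequency over seeded replicates is the binomial oracle for the
    cytotoxicity rule.
    """
    cfg = SimulationConfig(
        grid=GridConfig(width=3, height=3), duration_days=1.0,
        n_tumor_init=0, products={"NT": _static_product()},
        tumor=_static_tumor(), nk_at_start=False, seed=seed)
    sim = Simulation(cfg, seed=seed)
    tumor = TumorAgent((1, 1))
    sim._add_tumor(tumor)
    nk = NKAgent("NT", (1, 0), c_nk=0.5, profile=None, s0=5)
    sim.grid.register(nk, nk.pos)
    sim.agents.append(nk)
    sim.counts[NC] += 1
    return sim


def _scenario_clearance_event(seed: int, n_nk: int = 100) -> Simulation:
    """Tumor-exposed NC agents on a tumor-free board.

    With the default NC->NV probability of 1.0, every exposed cytotoxic
    agent becomes vigilant after one step.
    """
    cfg = SimulationConfig(
        grid=GridConfig(width=12, height=12), duration_days=1.0,
        n_tumor_init=0, products={"NT": _static_product()},
        tumor=_static_tumor(), nk_at_start=False, seed=seed)
    sim = Simulation(cfg, seed=seed)
    rng = np.random.default_rng(seed)
    for _ in range(n_nk):
        pos = (int(rng.integers(0, 12)), int(rng.integers(0, 12)))
        nk = NKAgent("NT", pos, c_nk=0.5, profile=None, s0=5)
        nk.tumor_exposed = True
        sim.grid.register(nk, nk.pos)
        sim.agents.append(nk)
        sim.counts[NC] += 1
    return sim


def _scenario_recall_event(seed: int, n_nk: int = 1000) -> Simulation:
    """Vigilant NK agents each co-located with tumor cells.

    Each NV recalls to NC with probability kB+ (default 0.9) in one step.
    Tumor kill/death dynamics are off so exposure is guaranteed.
    """
    side = max(6, int(math.ceil(math.sqrt(n_nk))) + 2)
    cfg = SimulationConfig(
        grid=GridConfig(width=side, height=side, b_max=25),
        duration_days=1.0, n_tumor_init=0,
        products={"NT": _static_product(
            kill=NKKillParams(mu_c=-30.0, sigma_c=0.0, gamma=1.0))},
        tumor=_static_tumor(), nk_at_start=False, seed=seed)
    sim = Simulation(cfg, seed=seed)
    rng = np.random.default_rng(seed)
    for _ in range(n_nk):
        pos = (int(rng.integers(0, side)), int(rng.integers(0, side)))
        if sim.grid.check_capacity(pos):
            sim._add_tumor(TumorAgent(pos))
        nk = NKAgent("NT", pos, c_nk=0.0, profile=None, s0=5)
        nk.phenotype = NV
        sim.grid.register(nk, nk.pos)
        sim.agents.append(nk)
        sim.counts[NV] += 1
    return sim


def _scenario_full_capacity_cell(seed: int) -> Simulation:
    """One grid cell packed to capacity, high division rate, no movement.

    Divisions into the full home cell must be redirected to neighbors or
    skipped; occupancy never exceeds the capacity.
    """
    cfg = SimulationConfig(
        grid=GridConfig(width=3, height=3, b_max=25), duration_days=2.0,
        n_tumor_init=0, products={},
        tumor=_static_tumor(p_b=5.0), nk_at_start=False, seed=seed)
    sim = Simulation(cfg, seed=seed)
    for _ in range(25):
        sim._add_tumor(TumorAgent((1, 1)))
    return sim


MICRO_SCENARIOS = {
    "one_nc_one_tumor": _scenario_one_nc_one_tumor,
    "clearance_event": _scenario_clearance_event,
    "recall_event": _scenario_recall_event,
    "full_capacity_cell": _scenario_full_capacity_cell,
}


def micro_scenario(name: str, seed: int = 0, **kwargs) -> Simulation:
    """Build a registered micro-scenario board (see :data:`MICRO_SCENARIOS`)."""
    try:
        builder = MICRO_SCENARIOS[name]
    except KeyError:
        raise KeyError(f"unknown micro-scenario {name!r}; "
                       f"available: {sorted(MICRO_SCENARIOS)}") from None
    return builder(seed, **kwargs)
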