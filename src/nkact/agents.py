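"""Per-agent behavioral rules for NK and tumor cell agents.

Four agent kinds live on the lattice: cytotoxic NK cells (NC, which kill),
exhausted NK cells (NE, inert), vigilant NK cells (NV, dormant with recall
potential) and tumor cells (B). All action rules are stochastic: an agent
commits to an action when a uniform draw passes the relevant probability.

Rates and probabilities
-----------------------
Parameters stated per day (proliferation and death rates) are converted to
per-step probabilities over the step length ΔT:

* death:    p_step = 1 − exp(−rate · ΔT_days)
* division: p_step = exp(rate · ΔT_days) − 1, capped at 1

Death applied before division makes the expected per-day multiplication
factor exactly e^(rate_div − rate_death), so configured rates are
recoverable from simulated growth curves by a log-linear fit.

Kill probability
----------------
On contact, a cytotoxic NK agent kills a tumor cell with

    p_kill = logistic(c_NK + G_NK)^γ · (1 − p_evade)

where c_NK ~ truncN(μ_c, σ_c²) on [0, ∞) is the agent's baseline
cytotoxicity, G_NK the genetic modifier (see :mod:`nkact.genetics`), γ the
CAR engineering exponent (0.5 engineered / 1.0 non-transduced: γ < 1
inflates the logistic base toward 1) and p_evade the target's evasion
probability.

Serial killing and exhaustion
-----------------------------
Each NC starts with serial killing capacity S0 and spends it on kills;
three exhaustion variants are supported:

* EM1: s = S0 − ΣI_kill (pure budget depletion)
* EM2: EM1 plus marker accumulation — each kill adds 1 to the flagged
  exhaustion-marker expression entries, degrading p_kill through G_NK
* EM3: EM2 plus marker-driven acceleration, s = S0 − ΣI_kill · e^γ_exh
  with γ_exh = Σ_g x_g / (x50_g + x_g)

An NC whose capacity reaches 0 becomes exhausted (NE) at the end of that
step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, ndtr, ndtri

from .genetics import ExpressionProfile, GeneticEffectParams, genetic_effect

__all__ = [
    "NKKillParams", "NKProliferationParams", "ExhaustionParams",
    "PhenotypeRates", "TumorParams", "MotilityParams", "ProductParams",
    "NKAgent", "TumorAgent",
    "NC", "NE", "NV",
    "sample_truncated_normal", "sample_baseline_cytotoxicity",
    "compute_pkill", "effective_evasion", "stimulus_terms",
    "proliferation_rate", "attempt_kill", "phenotype_transitions",
    "death_probability", "division_probability",
]

# phenotype tags
NC = "NC"
NE = "NE"
NV = "NV"


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NKKillParams:
    """Cytotoxicity sampling and CAR exponent.

    mu_c/sigma_c parameterize the truncated-normal baseline cytotoxicity;
    gamma is the CAR effect exponent (0.5 for CAR products, 1.0 for
    non-transduced NK cells).
    """

    mu_c: float = 0.5
    sigma_c: float = 0.01
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_c < 0:
            raise ValueError("sigma_c must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class NKProliferationParams:
    """Cytokine/tumor-stimulated NK proliferation.

    The instantaneous baseline rate decays with cell age t (in steps):
    pc*(t) = pc · exp(w − bpc·t), where w couples local tumor load and
    cytokine level through saturating Hill terms

        kB = (B^γ1 + δ) / (B^γ1 + B50^γ1 + δ)
        w  = kB · (c^γ2 + δ) / (c^γ2 + c50^γ2 + δ)

    Under the vanilla model (``model="VM"``) w is forced to 0. In
    tumor-free autonomous-growth assays kB is pinned to ``kb_autonomous``
    (default 1.0) so the cytokine term still acts. The realized per-step
    rate is drawn from truncN(pc*(t), σ_pc²) on [0, ∞).

    pc is per day; bpc is per step (ΔT⁻¹); sigma_pc defaults to 0.01·pc.
    """

    pc: float = 0.3
    bpc: float = 0.0
    sigma_pc: float | None = None
    b50: float = 25.0
    c50: float = 70.0
    gamma1: float = 0.2
    gamma2: float = 0.2
    delta: float = 1e-6
    model: str = "CM"
    kb_autonomous: float = 1.0

    def __post_init__(self) -> None:
        if self.pc < 0 or self.bpc < 0:
            raise ValueError("pc and bpc must be >= 0")
        if self.b50 <= 0 or self.c50 <= 0:
            raise ValueError("b50 and c50 must be positive")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.model not in {"CM", "VM"}:
            raise ValueError("model must be 'CM' or 'VM'")

    @property
    def effective_sigma_pc(self) -> float:
        return 0.01 * self.pc if self.sigma_pc is None else self.sigma_pc


@dataclass(frozen=True)
class ExhaustionParams:
    """Serial-killing budget and exhaustion variant (EM1/EM2/EM3)."""

    s0: int = 5
    variant: str = "EM1"
    x50: float = 1.0  # marker half-maximum, shared across flagged markers

    def __post_init__(self) -> None:
        if self.s0 < 1:
            raise ValueError("s0 must be >= 1")
        if self.variant not in {"EM1", "EM2", "EM3"}:
            raise ValueError("variant must be EM1, EM2 or EM3")
        if self.variant == "EM3" and not self.x50 > 0:
            raise ValueError("x50 must be positive under EM3")


@dataclass(frozen=True)
class PhenotypeRates:
    """Death/proliferation rates (per day) and phenotype-switch probabilities."""

    d_c: float = 0.1      # cytotoxic NK death rate, /day
    p_v: float = 1e-3     # vigilant proliferation, /day
    d_v: float = 1e-3     # vigilant death, /day
    p_e: float = 0.0      # exhausted proliferation, /day
    d_e: float = 0.1      # exhausted death, /day
    k_b_minus: float = 1.0  # NC -> NV on local clearance
    k_b_plus: float = 0.9   # NV -> NC on tumor re-exposure

    def __post_init__(self) -> None:
        for name in ("d_c", "p_v", "d_v", "p_e", "d_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("k_b_minus", "k_b_plus"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class TumorParams:
    """Tumor proliferation, death, evasion/mutation and motility."""

    p_b: float = 0.455     # proliferation rate, /day (lymphoma default)
    d_b: float = 1e-4      # death rate, /day
    p_mutate: float = 1e-3  # per-division resistance-mutation probability
    p_evade_base: float = 0.0
    kappa_antigen: float = 0.5  # proportional evasion reduction per unit antigen
    p_mutate_increment: float = 1e-3  # evasion gain per acquired mutation
    m_b: float = 0.1       # movement probability per step
    v_b: int = 1           # movement speed, grid cells per step

    def __post_init__(self) -> None:
        for name in ("p_mutate", "p_evade_base", "m_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_b < 0 or self.d_b < 0:
            raise ValueError("p_b and d_b must be >= 0")


@dataclass(frozen=True)
class MotilityParams:
    """NK movement: probability per step and speed in μm/hr."""

    m_n: float = 0.9
    v_n: float = 39.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.m_n <= 1.0:
            raise ValueError("m_n must be in [0, 1]")
        if self.v_n < 0:
            raise ValueError("v_n must be >= 0")


@dataclass(frozen=True)
class ProductParams:
    """Complete parameter block for one NK cell product (e.g. NT, CAR19)."""

    kill: NKKillParams = field(default_factory=NKKillParams)
    proliferation: NKProliferationParams = field(default_factory=NKProliferationParams)
    exhaustion: ExhaustionParams = field(default_factory=ExhaustionParams)
    rates: PhenotypeRates = field(default_factory=PhenotypeRates)
    motility: MotilityParams = field(default_factory=MotilityParams)
    genetic: GeneticEffectParams = field(default_factory=GeneticEffectParams)
    cytokine_species: tuple[str, ...] = ()  # armoring, e.g. ("IL15",)


# ---------------------------------------------------------------------------
# agents
# ---------------------------------------------------------------------------

class NKAgent:
    """One NK cell agent (any phenotype)."""

    __slots__ = ("product", "phenotype", "pos", "c_nk", "profile", "s",
                 "age_t", "tumor_exposed", "n_kills", "alive", "pending_ne")
    is_tumor = False

    def __init__(self, product: str, pos, c_nk: float,
                 profile: ExpressionProfile | None, s0: int) -> None:
        self.product = product
        self.phenotype = NC
        self.pos = pos
        self.c_nk = c_nk
        self.profile = profile
        self.s = float(s0)
        self.age_t = 0
        self.tumor_exposed = False
        self.n_kills = 0
        self.alive = True
        self.pending_ne = False

    def g_nk(self, genetic: GeneticEffectParams) -> float:
        if self.profile is None:
            return 0.0
        return genetic_effect(genetic, self.profile)


class TumorAgent:
    """One tumor cell agent."""

    __slots__ = ("pos", "antigen_expr", "mutations", "alive")
    is_tumor = True

    def __init__(self, pos, antigen_expr: float = 1.0, mutations: int = 0) -> None:
        self.pos = pos
        self.antigen_expr = antigen_expr
        self.mutations = mutations
        self.alive = True


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def sample_truncated_normal(mu: float, sigma: float,
                            rng: np.random.Generator) -> float:
    """One draw from normal(mu, sigma²) truncated to [0, ∞).

    Uses the inverse-CDF method (exact, one uniform per draw); with
    sigma = 0 degenerates to max(mu, 0).
    """
    if sigma == 0:
        return max(mu, 0.0)
    lo = ndtr(-mu / sigma)  # CDF mass below 0
    u = lo + (1.0 - lo) * rng.random()
    # guard the open upper end of the uniform
    u = min(u, 1.0 - 1e-16)
    return float(mu + sigma * ndtri(u))


def sample_baseline_cytotoxicity(params: NKKillParams,
                                 rng: np.random.Generator) -> float:
    """Draw c_NK ~ truncN(μ_c, σ_c²) on [0, ∞)."""
    return sample_truncated_normal(params.mu_c, params.sigma_c, rng)


# ---------------------------------------------------------------------------
# rule functions
# ---------------------------------------------------------------------------

def compute_pkill(c_nk: float, g_nk: float, gamma: float,
                  p_evade: float) -> float:
    """p_kill = logistic(c_NK + G_NK)^γ · (1 − p_evade), in [0, 1]."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if not 0.0 <= p_evade <= 1.0:
        raise ValueError("p_evade must be in [0, 1]")
    base = float(expit(c_nk + g_nk))
    return base ** gamma * (1.0 - p_evade)


def effective_evasion(tumor: TumorAgent, params: TumorParams) -> float:
    """Current evasion probability of one tumor cell.

    High CAR-target antigen expression reduces the baseline evasion
    proportionally; each acquired resistance mutation adds a fixed
    increment. Clipped to [0, 1].
    """
    p = params.p_evade_base * (1.0 - params.kappa_antigen * tumor.antigen_expr)
    p += tumor.mutations * params.p_mutate_increment
    return min(1.0, max(0.0, p))


def stimulus_terms(b_local: float, c_local: float,
                   params: NKProliferationParams,
                   autonomous: bool = False) -> tuple[float, float]:
    """Hill stimulation terms (kB, w) from local tumor load and cytokine.

    In autonomous-growth (tumor-free assay) mode kB is pinned to the
    configured constant instead of being computed from the (absent) tumor
    field.
    """
    if b_local < 0 or c_local < 0:
        raise ValueError("b_local and c_local must be >= 0")
    d = params.delta
    if autonomous:
        kb = params.kb_autonomous
    else:
        bg = b_local ** params.gamma1 if b_local > 0 else 0.0
        kb = (bg + d) / (bg + params.b50 ** params.gamma1 + d)
    cg = c_local ** params.gamma2 if c_local > 0 else 0.0
    w = kb * (cg + d) / (cg + params.c50 ** params.gamma2 + d)
    return kb, w


def division_probability(rate_per_day: float, dt_days: float) -> float:
    """Per-step division probability for a per-day rate (capped at 1)."""
    return min(1.0, math.exp(rate_per_day * dt_days) - 1.0)


def death_probability(rate_per_day: float, dt_days: float) -> float:
    """Per-step death probability for a per-day rate."""
    return 1.0 - math.exp(-rate_per_day * dt_days)


def proliferation_rate(params: NKProliferationParams, age_t: int, w: float,
                       dt_days: float, rng: np.random.Generator) -> float:
    """Per-step NC division probability.

    pc*(t) = pc · exp(w − bpc·t) with t in steps (w ≡ 0 under VM), a
    realized rate pC' ~ truncN(pc*(t), σ_pc²) on [0, ∞), then the per-day
    rate is converted to a per-step probability.
    """
    if age_t < 0:
        raise ValueError("age_t must be >= 0")
    if params.model == "VM":
        w = 0.0
    pc_star = params.pc * math.exp(w - params.bpc * age_t)
    pc_prime = sample_truncated_normal(pc_star, params.effective_sigma_pc, rng)
    return division_probability(pc_prime, dt_days)


def _recompute_skc(nk: NKAgent, exh: ExhaustionParams) -> None:
    """Update nk.s after a kill, per exhaustion variant."""
    if exh.variant in ("EM1", "EM2"):
        nk.s = exh.s0 - nk.n_kills
    else:  # EM3
        if nk.profile is not None and len(nk.profile.marker_values):
            x = nk.profile.marker_values
            gamma_exh = float(np.sum(x / (exh.x50 + x)))
        else:
            gamma_exh = 0.0
        nk.s = exh.s0 - nk.n_kills * math.exp(gamma_exh)


def attempt_kill(nk: NKAgent, tumor: TumorAgent, kill: NKKillParams,
                 exh: ExhaustionParams, genetic: GeneticEffectParams,
                 tumor_params: TumorParams, rng: np.random.Generator) -> bool:
    """One kill attempt of ``nk`` against ``tumor``.

    Returns True iff the tumor cell was killed. On a kill the NK agent's
    cumulative kill count rises, exhaustion markers are incremented (+1
    each, EM2/EM3) and its serial killing capacity is recomputed; the
    caller handles removing the dead tumor and the end-of-step NE
    transition once s reaches 0. Any contact marks the NK tumor-exposed.
    """
    if nk.phenotype != NC:
        raise ValueError("only cytotoxic NK agents can attempt kills")
    if nk.s <= 0:
        raise ValueError("NK agent has no remaining serial killing capacity")
    nk.tumor_exposed = True
    p_evade = effective_evasion(tumor, tumor_params)
    p = compute_pkill(nk.c_nk, nk.g_nk(genetic), kill.gamma, p_evade)
    if rng.random() >= p:
        return False
    nk.n_kills += 1
    if exh.variant in ("EM2", "EM3") and nk.profile is not None:
        nk.profile.increment_markers(1.0)
    _recompute_skc(nk, exh)
    tumor.alive = False
    return True


def phenotype_transitions(nk: NKAgent, local_tumor_cleared: bool,
                          tumor_present: bool, rates: PhenotypeRates,
                          exh: ExhaustionParams,
                          rng: np.random.Generator) -> str:
    """End-of-step phenotype update; returns the (possibly new) phenotype.

    NC with exhausted capacity becomes NE deterministically. NC that has
    seen tumor and whose Moore-1 neighborhood is now tumor-free becomes NV
    with probability kB−. NV re-exposed to tumor recalls to NC with
    probability kB+, with its serial killing capacity restored to S0.
    """
    if nk.phenotype == NC:
        if nk.s <= 0:
            nk.phenotype = NE
        elif nk.tumor_exposed and local_tumor_cleared:
            if rates.k_b_minus > 0 and rng.random() < rates.k_b_minus:
                nk.phenotype = NV
    elif nk.phenotype == NV and tumor_present:
        if rates.k_b_plus > 0 and rng.random() < rates.k_b_plus:
            nk.phenotype = NC
            nk.s = float(exh.s0)
            nk.n_kills = 0
    return nk.phenotype


def nk_steps_per_move(motility: MotilityParams, dt_hours: float, l: float,
                      rng: np.random.Generator) -> int:
    """Stochastically rounded number of grid-cell sub-steps per move event.

    Expected value is v_N · ΔT / l (e.g. 39 μm/h · 4 h / 50 μm = 3.12).
    """
    x = motility.v_n * dt_hours / l
    base = int(x)
    return base + (1 if rng.random() < x - base else 0)
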