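"""Simulation-based calibration by coarse-to-fine MSE grid search.

The observable is normalized tumor progression: the treated group's mean
tumor burden divided by the mean burden of a matched tumor-only control at
the same timepoints (burden standing in for radiance). Calibration proceeds
in stages mirroring how such models are fitted in practice:

1. tumor proliferation (and optionally death) rates are fitted to the
   control curve and then frozen;
2. for each candidate effector-to-target ratio, the remaining parameters
   are grid-searched per treatment group and the ETR minimizing the total
   MSE across groups is selected;
3. grids are refined around the incumbents and re-searched.

Each candidate is scored with a reduced replicate count and the incumbents
re-evaluated at the full count; fit stability is summarized by the
coefficient of variation of the progression ratio across replicates at each
observed day.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import (ReplicateSet, SimulationConfig, run_replicates,
                     tumor_only_config)

__all__ = [
    "ObservedProgression", "SearchSpace", "CalibrationResult",
    "normalized_progression", "mse_loss", "global_search",
    "set_config_param",
]


@dataclass(frozen=True)
class ObservedProgression:
    """Observed normalized tumor-progression ratios per treatment group.

    ``groups`` maps a group name to a list of (day, ratio) pairs with days
    strictly increasing and ratios >= 0. An optional ``control`` group name
    identifies a curve of raw fold-change data for the tumor-only arm used
    in stage 1 (fitting tumor rates).
    """

    groups: dict[str, list[tuple[float, float]]]
    control_group: str | None = None

    def __post_init__(self) -> None:
        for g, pts in self.groups.items():
            days = [d for d, _ in pts]
            if any(b <= a for a, b in zip(days, days[1:])):
                raise ValueError(f"group {g!r}: days must be strictly increasing")
            if any(r < 0 for _, r in pts):
                raise ValueError(f"group {g!r}: ratios must be >= 0")

    def days(self, group: str) -> list[float]:
        return [d for d, _ in self.groups[group]]

    def ratios(self, group: str) -> np.ndarray:
        return np.array([r for _, r in self.groups[group]], dtype=float)

    @property
    def treatment_groups(self) -> list[str]:
        return [g for g in self.groups if g != self.control_group]

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   control_group: str | None = None) -> "ObservedProgression":
        """Build from a long table with columns group, day, ratio."""
        groups = {
            g: [(float(r.day), float(r.ratio))
                for r in sub.sort_values("day").itertuples()]
            for g, sub in df.groupby("group", sort=True)
        }
        return cls(groups, control_group)


@dataclass(frozen=True)
class SearchSpace:
    """Candidate grids per parameter (dotted config paths) plus ETR options.

    ``tumor_grids`` are fitted first against the control curve and frozen;
    ``nk_grids`` are searched per treatment group under each candidate ETR.
    ``refine_factor`` controls how many points each refinement stage places
    between the incumbent's neighbors.
    """

    tumor_grids: dict[str, list[float]] = field(default_factory=dict)
    nk_grids: dict[str, list[float]] = field(default_factory=dict)
    etr_candidates: list[float] = field(default_factory=lambda: [1.0])
    refine_stages: int = 1
    refine_factor: int = 4
    max_evaluations: int = 2000

    def __post_init__(self) -> None:
        for name, grid in {**self.tumor_grids, **self.nk_grids}.items():
            if not grid:
                raise ValueError(f"empty candidate grid for {name!r}")
        if not self.etr_candidates:
            raise ValueError("at least one ETR candidate is required")


@dataclass
class CalibrationResult:
    """Best-fit parameters, MSEs, selected ETR and stability diagnostics."""

    tumor_params: dict[str, float]
    control_mse: float
    etr: float
    best_params: dict[str, dict[str, float]]      # group -> param -> value
    group_mse: dict[str, float]
    top_k: dict[str, list[tuple[dict[str, float], float]]]
    cv_over_time: dict[str, pd.DataFrame]
    n_evaluations: int = 0

    @property
    def total_mse(self) -> float:
        return float(sum(self.group_mse.values()))


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def _series_at_days(mean_record: pd.DataFrame, days, column: str = "B") -> np.ndarray:
    """Read a recorded column at the steps closest to the requested days."""
    rec_days = mean_record["day"].to_numpy()
    out = np.empty(len(days))
    for k, d in enumerate(days):
        if d > rec_days[-1] + 1e-9:
            raise ValueError(f"day {d} beyond simulated horizon {rec_days[-1]}")
        out[k] = mean_record[column].to_numpy()[np.argmin(np.abs(rec_days - d))]
    return out


def normalized_progression(treated: pd.DataFrame, control: pd.DataFrame,
                           obs_days) -> np.ndarray:
    """Treated / control mean tumor burden at each observation day."""
    t = _series_at_days(treated, obs_days)
    c = _series_at_days(control, obs_days)
    zero = np.nonzero(c <= 0)[0]
    if len(zero):
        raise ZeroDivisionError(
            f"control tumor burden is zero at day {obs_days[int(zero[0])]}")
    return t / c


def mse_loss(sim_ratios, obs_ratios) -> float:
    """Mean squared error between simulated and observed curves."""
    sim = np.asarray(sim_ratios, dtype=float)
    obs = np.asarray(obs_ratios, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError(f"shape mismatch {sim.shape} vs {obs.shape}")
    return float(np.mean((sim - obs) ** 2))


# ---------------------------------------------------------------------------
# config plumbing
# ---------------------------------------------------------------------------

def set_config_param(config: SimulationConfig, path: str,
                     value: float) -> SimulationConfig:
    """Return a copy of ``config`` with one dotted parameter replaced.

    Paths address nested frozen dataclasses, e.g. ``tumor.p_b``, ``etr`` or
    ``products.NT.kill.mu_c``.
    """
    parts = path.split(".")

    def rebuild(obj, parts, value):
        if not parts:
            return value
        head = parts[0]
        if isinstance(obj, dict):
            new = dict(obj)
            new[head] = rebuild(obj[head], parts[1:], value)
            return new
        if not hasattr(obj, head):
            raise KeyError(f"unknown config field {head!r} in {path!r}")
        child = rebuild(getattr(obj, head), parts[1:], value)
        return replace(obj, **{head: child})

    if len(parts) == 1:
        return replace(config, **{parts[0]: value})
    return replace(config, **{parts[0]: rebuild(getattr(config, parts[0]),
                                                parts[1:], value)})


def _apply_params(config: SimulationConfig,
                  params: dict[str, float]) -> SimulationConfig:
    for path, value in params.items():
        config = set_config_param(config, path, value)
    return config


def _refined_grid(grid: list[float], best: float, factor: int) -> list[float]:
    """Linear refinement of a sorted grid around the incumbent value."""
    grid = sorted(grid)
    i = int(np.argmin([abs(g - best) for g in grid]))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if math.isclose(lo, hi):
        return [best]
    return sorted(set(np.linspace(lo, hi, factor + 1).tolist()) | {best})


# ---------------------------------------------------------------------------
# the search
# ---------------------------------------------------------------------------

def _combinations(grids: dict[str, list[float]], cap: int):
    names = list(grids)
    combos = list(itertools.product(*(grids[n] for n in names)))
    if len(combos) > cap:
        combos = combos[:cap]
    return [dict(zip(names, c)) for c in combos]


def global_search(space: SearchSpace, obs: ObservedProgression,
                  base_config: SimulationConfig,
                  screen_replicates: int = 5,
                  top_k: int = 10) -> CalibrationResult:
    """Staged exhaustive grid search minimizing progression MSE.

    See the module docstring for the staging. Within every stage the best
    (lowest-MSE) candidate is retained, so refinement can only improve the
    incumbent; ties keep the earlier candidate.
    """
    n_evals = 0

    def control_curve(cfg: SimulationConfig, replicates: int) -> pd.DataFrame:
        c = replace(tumor_only_config(cfg), replicates=replicates)
        return run_replicates(c).mean

    # ---- stage 1: tumor rates against the control fold-change curve
    tumor_best: dict[str, float] = {}
    control_mse = float("nan")
    cfg = base_config
    if space.tumor_grids and obs.control_group:
        days = obs.days(obs.control_group)
        target = obs.ratios(obs.control_group)
        candidates = _combinations(space.tumor_grids, space.max_evaluations)
        scores = []
        for cand in candidates:
            mean = control_curve(_apply_params(cfg, cand), screen_replicates)
            score = mse_loss(_series_at_days(mean, days, "fold_B"), target)
            scores.append((score, cand))
            n_evals += 1
        control_mse, tumor_best = min(scores, key=lambda t: t[0])
        cfg = _apply_params(cfg, tumor_best)

    groups = obs.treatment_groups

    def search_groups(cfg_at_etr: SimulationConfig,
                      grids: dict[str, list[float]],
                      control_mean: pd.DataFrame):
        """Per-group exhaustive search; returns (results, total_mse)."""
        nonlocal n_evals
        results: dict[str, list[tuple[dict, float]]] = {g: [] for g in groups}
        candidates = _combinations(grids, space.max_evaluations)
        for cand in candidates:
            c = replace(_apply_params(cfg_at_etr, cand),
                        replicates=screen_replicates)
            mean = run_replicates(c).mean
            n_evals += 1
            for g in groups:
                days = obs.days(g)
                sim = normalized_progression(mean, control_mean, days)
                results[g].append((cand, mse_loss(sim, obs.ratios(g))))
        for g in groups:
            results[g].sort(key=lambda t: t[1])
        total = sum(results[g][0][1] for g in groups)
        return results, total

    # ---- stage 2: ETR selection with the coarse NK grids
    best_etr, best_results, best_total, best_control = None, None, np.inf, None
    for etr in space.etr_candidates:
        cfg_e = replace(cfg, etr=etr)
        control_mean = control_curve(cfg_e, screen_replicates)
        if space.nk_grids:
            results, total = search_groups(cfg_e, space.nk_grids, control_mean)
        else:
            results, total = search_groups(cfg_e, {}, control_mean)
        if total < best_total:
            best_etr, best_results, best_total = etr, results, total
            best_control = control_mean
    assert best_etr is not None and best_results is not None

    # ---- stage 3: refinement around per-group incumbents
    cfg_e = replace(cfg, etr=best_etr)
    for _ in range(space.refine_stages):
        if not space.nk_grids:
            break
        refined_any = False
        for g in groups:
            incumbent, inc_mse = best_results[g][0]
            grids = {name: _refined_grid(space.nk_grids[name],
                                         incumbent[name],
                                         space.refine_factor)
                     for name in space.nk_grids}
            if all(len(v) == 1 for v in grids.values()):
                continue
            refined_any = True
            res, _ = search_groups(cfg_e, grids, best_control)
            merged = best_results[g] + res[g]
            merged.sort(key=lambda t: t[1])
            best_results[g] = merged
        if not refined_any:
            break

    # ---- full-replicate re-evaluation of incumbents + CV diagnostics
    best_params: dict[str, dict[str, float]] = {}
    group_mse: dict[str, float] = {}
    cv: dict[str, pd.DataFrame] = {}
    full_control = control_curve(cfg_e, base_config.replicates)
    for g in groups:
        incumbent, _ = best_results[g][0]
        c = _apply_params(cfg_e, incumbent)
        reps = run_replicates(c)
        days = obs.days(g)
        sim = normalized_progression(reps.mean, full_control, days)
        best_params[g] = incumbent
        group_mse[g] = mse_loss(sim, obs.ratios(g))
        per_rep = np.stack([
            _series_at_days(r, days) for r in reps.replicates
        ])  # replicate x day, raw burden
        mean_r = per_rep.mean(axis=0)
        std_r = per_rep.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv_vals = np.where(mean_r > 0, std_r / mean_r, np.nan)
        cv[g] = pd.DataFrame({"day": days, "cv": cv_vals})

    top = {g: [(p, m) for p, m in best_results[g][:top_k]] for g in groups}
    return CalibrationResult(
        tumor_params=tumor_best, control_mse=control_mse, etr=best_etr,
        best_params=best_params, group_mse=group_mse, top_k=top,
        cv_over_time=cv, n_evaluations=n_evals,
    )
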