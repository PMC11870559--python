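"""Post-simulation analytics.

Tumor-burden AUC and time-to-clearance summaries of recorded trajectories,
parameter sweeps ("in-silico perturbation experiments") with random-forest
feature importance (mean decrease in impurity and permutation importance),
and nonparametric group comparison (two-tailed Mann-Whitney U with
Benjamini-Hochberg correction).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split
from statsmodels.stats.multitest import multipletests

from .calibration import set_config_param
from .engine import SimulationConfig, run_replicates

__all__ = [
    "SweepDesign", "ImportanceReport",
    "auc_tumor_growth", "time_to_clearance",
    "run_sweep", "feature_importance", "compare_groups",
    "benjamini_hochberg",
]


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (monotone, >= raw, capped at 1)."""
    _, p_adj, _, _ = multipletests(np.asarray(p_values, float),
                                   method="fdr_bh")
    return p_adj


@dataclass(frozen=True)
class SweepDesign:
    """Full-factorial perturbation design over dotted config parameters."""

    parameters: dict[str, list[float]]
    runs_per_combination: int = 1
    horizon_days: float = 35.0

    def __post_init__(self) -> None:
        if not self.parameters:
            raise ValueError("at least one parameter must be varied")
        if self.runs_per_combination < 1:
            raise ValueError("runs_per_combination must be >= 1")

    def combinations(self) -> list[dict[str, float]]:
        names = list(self.parameters)
        return [dict(zip(names, combo))
                for combo in itertools.product(*(self.parameters[n]
                                                 for n in names))]


@dataclass(frozen=True)
class ImportanceReport:
    """Per-parameter MDI and permutation-importance scores."""

    response: str
    mdi: pd.Series
    permutation: pd.Series
    permutation_std: pd.Series
    degenerate: bool = False


def auc_tumor_growth(record: pd.DataFrame, horizon: float,
                     column: str = "fold_B") -> float:
    """Trapezoidal integral of tumor burden (fold change) over [0, horizon] days."""
    days = record["day"].to_numpy(float)
    if horizon > days[-1] + 1e-9:
        raise ValueError(f"horizon {horizon} beyond recorded {days[-1]} days")
    y = record[column].to_numpy(float)
    mask = days <= horizon + 1e-9
    return float(np.trapezoid(y[mask], days[mask]))


def time_to_clearance(record: pd.DataFrame,
                      column: str = "B") -> float | None:
    """First recorded day at which the tumor count is 0 and stays 0.

    Transient clearance (tumor returning later, e.g. on re-challenge)
    does not count; returns None if the tumor is never durably cleared.
    """
    b = record[column].to_numpy(float)
    days = record["day"].to_numpy(float)
    nonzero = np.nonzero(b > 0)[0]
    if len(nonzero) == 0:
        return float(days[0])
    last = nonzero[-1]
    if last == len(b) - 1:
        return None
    return float(days[last + 1])


def run_sweep(design: SweepDesign, base_config: SimulationConfig,
              base_seed: int = 0) -> pd.DataFrame:
    """Execute the design; one row per run with parameters, AUC and TTC."""
    rows = []
    seed = base_seed
    for combo in design.combinations():
        cfg = base_config
        for path, value in combo.items():
            cfg = set_config_param(cfg, path, value)
        for _ in range(design.runs_per_combination):
            from .engine import Simulation
            rec = Simulation(cfg, seed=seed).run()
            seed += 1
            ttc = time_to_clearance(rec)
            rows.append({**combo,
                         "auc": auc_tumor_growth(rec, design.horizon_days),
                         "time_to_clearance": np.nan if ttc is None else ttc,
                         "seed": seed - 1})
    return pd.DataFrame(rows)


def feature_importance(results: pd.DataFrame, feature_columns: list[str],
                       response: str, rng: np.random.Generator | int = 0,
                       n_trees: int = 500,
                       n_permutation_repeats: int = 10) -> ImportanceReport:
    """Random-forest importance of swept parameters for a response.

    Fits a seeded RandomForestRegressor on parameters vs response, reports
    MDI (normalized to sum to 1) and permutation importance estimated on a
    held-out split with ``n_permutation_repeats`` shuffles per feature.
    """
    if len(results) < 20:
        raise ValueError("need at least 20 sweep rows for importance analysis")
    y = results[response].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"response {response!r} contains non-finite values")
    seed = int(rng.integers(2 ** 31)) if isinstance(rng, np.random.Generator) \
        else int(rng)
    X = results[feature_columns].to_numpy(float)
    if np.ptp(y) == 0:
        warnings.warn("constant response: importances are degenerate",
                      RuntimeWarning, stacklevel=2)
        zeros = pd.Series(0.0, index=feature_columns)
        return ImportanceReport(response, zeros, zeros.copy(), zeros.copy(),
                                degenerate=True)
    X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=0.25,
                                              random_state=seed)
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                               n_jobs=1)
    rf.fit(X_tr, y_tr)
    mdi = pd.Series(rf.feature_importances_, index=feature_columns)
    pi = permutation_importance(rf, X_te, y_te,
                                n_repeats=max(10, n_permutation_repeats),
                                random_state=seed)
    return ImportanceReport(
        response=response,
        mdi=mdi,
        permutation=pd.Series(pi.importances_mean, index=feature_columns),
        permutation_std=pd.Series(pi.importances_std, index=feature_columns),
    )


def compare_groups(samples: dict[str, np.ndarray],
                   alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise two-tailed Mann-Whitney U with BH adjustment.

    ``samples`` maps group name to a 1-D array of per-run outcomes (e.g.
    tumor-growth AUCs). Returns one row per unordered pair with the U
    statistic, raw and BH-adjusted p-values and a significance flag.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for g, v in samples.items():
        if len(v) == 0:
            raise ValueError(f"group {g!r} is empty")
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
    names = list(samples)
    rows = []
    for a, b in itertools.combinations(names, 2):
        u, p = mannwhitneyu(samples[a], samples[b], alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "U": float(u),
                     "p_value": float(p)})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = benjamini_hochberg(df["p_value"])
    df["significant"] = df["p_adjusted"] < alpha
    return df
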