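"""Model/Results front end over the simulation and calibration machinery.

`TumorNKModel` bundles a simulation configuration with (optionally) observed
tumor-progression data, in the style of statistical modelling packages:
``simulate()`` returns a :class:`SimulationResults` holding per-replicate
and aggregated trajectories, and ``fit()`` runs the staged MSE grid search
returning a :class:`CalibrationResults` with parameter estimates,
goodness-of-fit and stability diagnostics, each with a ``summary()``.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import auc_tumor_growth, time_to_clearance
from .calibration import (CalibrationResult, ObservedProgression, SearchSpace,
                          global_search, normalized_progression)
from .engine import (ReplicateSet, SimulationConfig, load_config,
                     run_replicates, tumor_only_config)

__all__ = ["TumorNKModel", "SimulationResults", "CalibrationResults"]


class TumorNKModel:
    """On-lattice tumor / NK-cell adoptive-therapy model.

    Parameters
    ----------
    config : SimulationConfig
        Full simulation configuration (grid, product parameter blocks,
        tumor parameters, dosing).
    observed : ObservedProgression, optional
        Normalized tumor-progression data to calibrate against.
    """

    def __init__(self, config: SimulationConfig,
                 observed: ObservedProgression | None = None) -> None:
        self.config = config
        self.observed = observed

    @classmethod
    def from_config(cls, path: str | Path,
                    observed: ObservedProgression | None = None) -> "TumorNKModel":
        """Build from a YAML configuration file."""
        return cls(load_config(path), observed)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, config: SimulationConfig,
                       control_group: str | None = None) -> "TumorNKModel":
        """Build from a long observation table (columns group, day, ratio)."""
        return cls(config, ObservedProgression.from_frame(data, control_group))

    # ------------------------------------------------------------------

    def simulate(self, seed: int | None = None,
                 replicates: int | None = None,
                 tumor_only: bool = False) -> "SimulationResults":
        """Run seeded replicates (optionally of the matched tumor-only control)."""
        cfg = self.config
        if tumor_only:
            cfg = tumor_only_config(cfg)
        if replicates is not None:
            cfg = replace(cfg, replicates=replicates)
        reps = run_replicates(cfg, base_seed=seed)
        return SimulationResults(self, reps)

    def fit(self, space: SearchSpace,
            screen_replicates: int = 5) -> "CalibrationResults":
        """Calibrate against the attached observations by MSE grid search."""
        if self.observed is None:
            raise ValueError("no observed progression data attached; "
                             "construct with observed= or from_dataframe()")
        res = global_search(space, self.observed, self.config,
                            screen_replicates=screen_replicates)
        return CalibrationResults(self, res)


class SimulationResults:
    """Aggregated replicate trajectories with convenience summaries."""

    def __init__(self, model: TumorNKModel, replicates: ReplicateSet) -> None:
        self.model = model
        self._reps = replicates
        self.mean = replicates.mean
        self.std = replicates.std
        self.replicates = replicates.replicates

    def normalized_vs(self, control: "SimulationResults",
                      days) -> np.ndarray:
        """Normalized progression of this run against a control run."""
        return normalized_progression(self.mean, control.mean, days)

    def auc(self, horizon: float | None = None) -> float:
        horizon = horizon or float(self.mean["day"].iloc[-1])
        return auc_tumor_growth(self.mean, horizon)

    def time_to_clearance(self) -> float | None:
        return time_to_clearance(self.mean)

    def summary(self) -> pd.DataFrame:
        """Endpoint summary: final populations, deaths by cause, AUC."""
        last = self.mean.iloc[-1]
        ttc = self.time_to_clearance()
        rows = {
            "duration_days": last["day"],
            "final_tumor": last["B"],
            "final_tumor_fold": last["fold_B"],
            "final_NC": last["NC"], "final_NE": last["NE"],
            "final_NV": last["NV"],
            "tumor_deaths_cytotoxic": last["deaths_cytotoxic_cum"],
            "tumor_deaths_programmed": last["deaths_programmed_cum"],
            "auc_fold_B": self.auc(),
            "time_to_clearance": np.nan if ttc is None else ttc,
            "replicates": float(len(self.replicates)),
        }
        return pd.DataFrame({"value": rows})

    def plot(self, ax=None, column: str = "fold_B", label: str | None = None):
        """Mean trajectory with a +/-1 SD band (matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        d = self.mean["day"]
        m = self.mean[column]
        s = self.std[column]
        ax.plot(d, m, label=label or column)
        ax.fill_between(d, m - s, m + s, alpha=0.25)
        ax.set_xlabel("day")
        ax.set_ylabel(column)
        if label:
            ax.legend()
        return ax


class CalibrationResults:
    """Fitted parameter sets with MSEs and replicate-stability diagnostics."""

    def __init__(self, model: TumorNKModel, result: CalibrationResult) -> None:
        self.model = model
        self.result = result

    @property
    def etr(self) -> float:
        return self.result.etr

    @property
    def params(self) -> dict[str, dict[str, float]]:
        return self.result.best_params

    @property
    def mse(self) -> dict[str, float]:
        return self.result.group_mse

    @property
    def total_mse(self) -> float:
        return self.result.total_mse

    def summary(self) -> pd.DataFrame:
        """One row per group: best-fit parameters, MSE, mean CV over time."""
        rows = []
        for g, params in self.result.best_params.items():
            cv = self.result.cv_over_time[g]["cv"]
            rows.append({
                "group": g, **params,
                "mse": self.result.group_mse[g],
                "mean_cv": float(np.nanmean(cv)) if len(cv) else np.nan,
            })
        df = pd.DataFrame(rows).set_index("group")
        df.attrs["etr"] = self.result.etr
        df.attrs["tumor_params"] = self.result.tumor_params
        df.attrs["total_mse"] = self.result.total_mse
        return df

    def top_k_frame(self, group: str) -> pd.DataFrame:
        """Top candidate parameter sets for one group, ascending MSE."""
        rows = [{**p, "mse": m} for p, m in self.result.top_k[group]]
        return pd.DataFrame(rows)
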