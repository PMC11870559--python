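"""Gene/pathway effect coefficients and per-agent expression profiles.

Individual NK agents carry a normalized expression profile ``g`` (genes and
pathway density scores) drawn from a pre-infusion single-cell pool. A fixed
coefficient vector ``beta`` — upstream regression effects of each feature on
tumor control, with the sign convention already applied by the data
producer — maps the profile to a bounded per-agent cytotoxicity modifier

    G_NK = tanh(b * sum_i beta_i * g_i),

with ``b`` a small overall scaling coefficient (default 0.1) keeping the
argument in the responsive range of tanh. A flagged subset of features
(exhaustion markers, canonically LAG3 and PDCD1) is mutable at run time:
kill events increment those entries, feeding back into G_NK and hence the
kill probability.

Expression values are used exactly as provided; no re-normalization is done
here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneEffectTable",
    "ExpressionProfile",
    "GeneticEffectParams",
    "load_effect_table",
    "assign_expression_profiles",
    "genetic_effect",
]


@dataclass(frozen=True)
class GeneticEffectParams:
    """Overall genetic-effect scaling. ``b >= 0``, dimensionless."""

    b: float = 0.1

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError("b must be non-negative")


class GeneEffectTable:
    """Feature ids, coefficients and the exhaustion-marker flag.

    Feature order defines the alignment contract for every
    :class:`ExpressionProfile` built against this table.
    """

    def __init__(self, feature_ids, betas, is_exhaustion_marker=None) -> None:
        self.feature_ids = list(feature_ids)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dupes = sorted({f for f in self.feature_ids
                            if self.feature_ids.count(f) > 1})
            raise ValueError(f"duplicate feature ids: {dupes}")
        self.beta = np.asarray(betas, dtype=float)
        if self.beta.shape != (len(self.feature_ids),):
            raise ValueError("betas must align with feature_ids")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("betas must be finite")
        if is_exhaustion_marker is None:
            is_exhaustion_marker = np.zeros(len(self.feature_ids), dtype=bool)
        self.is_exhaustion_marker = np.asarray(is_exhaustion_marker, dtype=bool)
        if self.is_exhaustion_marker.shape != self.beta.shape:
            raise ValueError("marker flags must align with feature_ids")
        self.marker_indices = np.flatnonzero(self.is_exhaustion_marker)

    def __len__(self) -> int:
        return len(self.feature_ids)

    @property
    def marker_ids(self) -> list[str]:
        return [self.feature_ids[i] for i in self.marker_indices]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature_id": self.feature_ids,
            "beta": self.beta,
            "is_exhaustion_marker": self.is_exhaustion_marker,
        })


def load_effect_table(path: str | Path) -> GeneEffectTable:
    """Read a coefficient table from CSV/TSV.

    Requires columns ``feature_id`` and ``beta``; an optional boolean
    ``is_exhaustion_marker`` column flags the mutable marker subset.
    Coefficients are used as-is (any sign flip is the producer's job).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"feature_id", "beta"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    bad = df[~df["beta"].apply(lambda v: isinstance(v, (int, float))
                               and math.isfinite(float(v)))]
    if len(bad):
        raise ValueError(
            f"{path}: non-numeric beta in rows {bad.index.tolist()} "
            f"(feature_id {bad['feature_id'].tolist()})")
    dup = df["feature_id"][df["feature_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate feature_id {dup.tolist()}")
    flags = df["is_exhaustion_marker"].astype(bool).to_numpy() \
        if "is_exhaustion_marker" in df.columns else None
    return GeneEffectTable(df["feature_id"].tolist(),
                           df["beta"].to_numpy(float), flags)


class ExpressionProfile:
    """One agent's feature vector, aligned to a :class:`GeneEffectTable`.

    Caches the weighted sum ``sum(beta * g)`` so that marker increments
    during kill events are O(#markers), not O(#features).
    """

    __slots__ = ("values", "_table", "_weighted_sum")

    def __init__(self, values: np.ndarray, table: GeneEffectTable) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(table),):
            raise ValueError(
                f"profile length {values.shape} does not match table "
                f"({len(table)} features)")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        self.values = values.copy()
        self._table = table
        self._weighted_sum = float(table.beta @ self.values)

    @property
    def weighted_sum(self) -> float:
        return self._weighted_sum

    @property
    def marker_values(self) -> np.ndarray:
        return self.values[self._table.marker_indices]

    def increment_markers(self, amount: float = 1.0) -> None:
        """Add ``amount`` to every flagged exhaustion-marker entry."""
        idx = self._table.marker_indices
        self.values[idx] += amount
        self._weighted_sum += amount * float(self._table.beta[idx].sum())

    def copy(self) -> "ExpressionProfile":
        return ExpressionProfile(self.values, self._table)


def genetic_effect(params: GeneticEffectParams, profile: ExpressionProfile) -> float:
    """G_NK = tanh(b * sum(beta * g)); bounded in (−1, 1)."""
    return math.tanh(params.b * profile.weighted_sum)


def assign_expression_profiles(
    pool: np.ndarray | pd.DataFrame,
    table: GeneEffectTable,
    n: int,
    rng: np.random.Generator,
) -> list[ExpressionProfile]:
    """Draw ``n`` profiles uniformly with replacement from pool columns.

    ``pool`` is features x cells, rows aligned to ``table`` order (a
    DataFrame is re-indexed by ``feature_id``). Each draw is copied so
    marker updates stay per-agent.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if isinstance(pool, pd.DataFrame):
        missing = set(table.feature_ids) - set(pool.index)
        if missing:
            raise ValueError(f"pool missing features: {sorted(missing)}")
        pool = pool.loc[table.feature_ids].to_numpy(float)
    pool = np.asarray(pool, dtype=float)
    if pool.ndim != 2 or pool.shape[0] != len(table):
        raise ValueError("pool must be a (features x cells) matrix aligned "
                         "to the effect table")
    if pool.shape[1] == 0:
        if n > 0:
            raise ValueError("cannot assign profiles from an empty pool")
        return []
    cols = rng.integers(0, pool.shape[1], size=n)
    return [ExpressionProfile(pool[:, c], table) for c in cols]
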