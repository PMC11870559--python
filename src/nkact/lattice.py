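"""Discrete 2D tumor-microenvironment lattice.

The spatial substrate of the simulator: a bounded square lattice with Moore
(Chebyshev) neighborhoods, per-site tumor occupancy bookkeeping with a hard
carrying capacity ``b_max``, and one dimensionless cytokine scalar field per
cytokine species with first-order (half-life) decay and local deposition by
cytokine-armored NK agents.

Conventions
-----------
Positions are 0-based integer ``(row, col)`` tuples with the origin at the
top-left. Borders are absorbing walls: neighborhoods are clipped at the grid
edge and there is no wraparound. The cytokine field carries no diffusion;
levels are dimensionless and only enter the model through Hill ratios
against the half-maximum constant ``c50``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridConfig",
    "CytokineParams",
    "TMEGrid",
    "moore_neighborhood",
]

Position = tuple[int, int]


@dataclass(frozen=True)
class GridConfig:
    """Geometry and timing of the lattice.

    Parameters
    ----------
    width, height : int
        Grid extent in cells (each cell is ``l`` μm across). Default 100x100
        covers a 5x5 mm patch at ``l`` = 50 μm, enough to hold 1000 tumor
        cells in a central disk of ceil(1000/25) = 40 sites with ample
        periphery for NK placement.
    l : float
        Edge length of one grid cell, μm.
    b_max : int
        Maximum number of tumor cells per grid cell (carrying capacity).
    dt_hours : float
        Model step length ΔT in hours. One step approximates a single
        NK-tumor conjugation (migration + attachment) cycle.
    """

    width: int = 100
    height: int = 100
    l: float = 50.0
    b_max: int = 25
    dt_hours: float = 4.0

    def __post_init__(self) -> None:
        if self.width < 3 or self.height < 3:
            raise ValueError("grid must be at least 3x3")
        if self.l <= 0:
            raise ValueError("grid cell size l must be positive")
        if self.b_max < 1:
            raise ValueError("b_max must be >= 1")
        if self.dt_hours <= 0:
            raise ValueError("dt_hours must be positive")

    @property
    def dt_days(self) -> float:
        return self.dt_hours / 24.0


@dataclass(frozen=True)
class CytokineParams:
    """Decay/production parameters for one cytokine species.

    half_life is in hours (e.g. 2.5 h for IL-15, 0.2 h for IL-21);
    ``deposit_per_step`` is the dimensionless amount each armored NK agent
    adds to its own site per step; ``initial_level`` seeds the whole field.
    """

    half_life: float = 2.5
    deposit_per_step: float = 1.0
    initial_level: float = 0.0

    def __post_init__(self) -> None:
        if not self.half_life > 0:
            raise ValueError("half_life must be positive")
        if self.deposit_per_step < 0:
            raise ValueError("deposit_per_step must be non-negative")
        if self.initial_level < 0:
            raise ValueError("initial_level must be non-negative")

    def decay_factor(self, dt_hours: float) -> float:
        """Per-step retention factor 2^(−ΔT / half-life)."""
        return float(2.0 ** (-dt_hours / self.half_life))


def moore_neighborhood(
    pos: Position,
    radius: int,
    width: int,
    height: int,
    include_self: bool = False,
) -> list[Position]:
    """All positions within Chebyshev distance ``radius`` of ``pos``.

    Clipped at the grid borders (absorbing walls). ``pos`` itself is
    excluded unless ``include_self`` is set.
    """
    i, j = pos
    if not (0 <= i < height and 0 <= j < width):
        raise ValueError(f"position {pos} outside {height}x{width} grid")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    out: list[Position] = []
    for ii in range(max(0, i - radius), min(height, i + radius + 1)):
        for jj in range(max(0, j - radius), min(width, j + radius + 1)):
            if not include_self and ii == i and jj == j:
                continue
            out.append((ii, jj))
    return out


class TMEGrid:
    """Lattice state: agent occupancy, tumor counts and cytokine fields.

    ``tumor_count`` is a dense int array kept in lockstep with the per-site
    occupancy lists; ``b_max`` is enforced by refusing registration into a
    full site (callers redirect or skip). Cytokine fields are one dense
    float array per species.
    """

    def __init__(self, config: GridConfig,
                 cytokines: dict[str, CytokineParams] | None = None) -> None:
        self.config = config
        h, w = config.height, config.width
        self.tumor_count = np.zeros((h, w), dtype=np.int32)
        # occupancy[i][j] is the list of agents registered at (i, j)
        self.occupancy: list[list[list]] = [
            [[] for _ in range(w)] for _ in range(h)
        ]
        self.cytokine_params: dict[str, CytokineParams] = dict(cytokines or {})
        self.cytokine: dict[str, np.ndarray] = {
            name: np.full((h, w), p.initial_level, dtype=float)
            for name, p in self.cytokine_params.items()
        }

    # -- geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.config.height, self.config.width

    def in_bounds(self, pos: Position) -> bool:
        i, j = pos
        return 0 <= i < self.config.height and 0 <= j < self.config.width

    def neighborhood(self, pos: Position, radius: int = 1,
                     include_self: bool = False) -> list[Position]:
        return moore_neighborhood(pos, radius, self.config.width,
                                  self.config.height, include_self)

    # -- occupancy ----------------------------------------------------

    def register(self, agent, pos: Position) -> None:
        if not self.in_bounds(pos):
            raise ValueError(f"position {pos} outside grid")
        self.occupancy[pos[0]][pos[1]].append(agent)
        if agent.is_tumor:
            self.tumor_count[pos] += 1

    def unregister(self, agent, pos: Position) -> None:
        self.occupancy[pos[0]][pos[1]].remove(agent)
        if agent.is_tumor:
            self.tumor_count[pos] -= 1

    def move(self, agent, old: Position, new: Position) -> None:
        self.unregister(agent, old)
        self.register(agent, new)

    def check_capacity(self, pos: Position) -> bool:
        """True iff another tumor cell fits at ``pos`` (count < b_max)."""
        if not self.in_bounds(pos):
            raise ValueError(f"position {pos} outside grid")
        return int(self.tumor_count[pos]) < self.config.b_max

    def agents_at(self, pos: Position) -> list:
        return self.occupancy[pos[0]][pos[1]]

    def n_registered(self) -> int:
        return sum(len(self.occupancy[i][j])
                   for i in range(self.config.height)
                   for j in range(self.config.width))

    # -- local readouts -----------------------------------------------

    def total_cytokine(self, pos: Position) -> float:
        """Summed level over species at one site (dimensionless)."""
        return float(sum(f[pos] for f in self.cytokine.values()))

    def local_state(self, pos: Position, radius: int = 1,
                    cytokine_radius: int = 0) -> tuple[int, float]:
        """Tumor load and cytokine level around ``pos``.

        Returns ``(B_local, c_local)`` where ``B_local`` sums tumor counts
        over the Moore ``radius`` neighborhood *including* ``pos`` and
        ``c_local`` is the cytokine level at ``pos`` (``cytokine_radius=0``,
        the default) or its mean over the neighborhood.
        """
        if not self.in_bounds(pos):
            raise ValueError(f"position {pos} outside grid")
        i, j = pos
        h, w = self.shape
        sl = (slice(max(0, i - radius), min(h, i + radius + 1)),
              slice(max(0, j - radius), min(w, j + radius + 1)))
        b_local = int(self.tumor_count[sl].sum())
        if cytokine_radius == 0:
            c_local = self.total_cytokine(pos)
        else:
            r = cytokine_radius
            slc = (slice(max(0, i - r), min(h, i + r + 1)),
                   slice(max(0, j - r), min(w, j + r + 1)))
            c_local = float(sum(f[slc].mean() for f in self.cytokine.values())) \
                if self.cytokine else 0.0
        return b_local, c_local

    def neighborhood_tumor_sum(self) -> np.ndarray:
        """Dense array of radius-1 neighborhood tumor sums (incl. self).

        Used for chemotaxis scoring and NK proliferation stimulus; computed
        by summing the 9 shifted copies of ``tumor_count`` (border-clipped).
        """
        padded = np.pad(self.tumor_count, 1, mode="constant")
        h, w = self.shape
        out = np.zeros((h, w), dtype=np.int64)
        for di in range(3):
            for dj in range(3):
                out += padded[di:di + h, dj:dj + w]
        return out

    # -- cytokine dynamics --------------------------------------------

    def update_cytokine_field(
        self, armored_positions: dict[str, list[Position]] | None = None
    ) -> None:
        """One ΔT tick of every cytokine field.

        Each level is multiplied by ``2^(−ΔT/half-life)``, then
        ``deposit_per_step`` is added at every armored-NK position supplied
        for that species. No spatial transport.
        """
        armored_positions = armored_positions or {}
        for name, fld in self.cytokine.items():
            p = self.cytokine_params[name]
            fld *= p.decay_factor(self.config.dt_hours)
            dep = p.deposit_per_step
            if dep:
                for pos in armored_positions.get(name, ()):
                    fld[pos] += dep

    def max_occupancy(self) -> int:
        return int(self.tumor_count.max())

    # -- export --------------------------------------------------------

    def export_snapshot(self, directory, step: int) -> list:
        """Write dense row-major CSV snapshots of the current fields.

        One ``tumor_count_<step>.csv`` plus one
        ``cytokine_<species>_<step>.csv`` per species; returns the paths.
        """
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        p = directory / f"tumor_count_{step:05d}.csv"
        np.savetxt(p, self.tumor_count, fmt="%d", delimiter=",")
        paths.append(p)
        for name, fld in self.cytokine.items():
            p = directory / f"cytokine_{name}_{step:05d}.csv"
            np.savetxt(p, fld, delimiter=",")
            paths.append(p)
        return paths
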