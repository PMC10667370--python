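"""Simulation protocols, seeding rules, RNG control and trajectory recording.

Two experiment protocols probe pattern formation:

* **Protocol A** (sequential seeding): the domain starts empty and a single
  resting cell with a uniformly random major-axis direction is introduced at
  the origin every ``introduction_interval`` steps, so the population grows
  as ``N_t = ceil(t / interval)``.
* **Protocol B** (bulk seeding): ``n_cells`` resting cells are placed at
  once, centres i.i.d. uniform in an axis-aligned cube centred at the
  origin, axes uniformly random; no further cells are added.

All stochastic draws flow through one seeded ``numpy.random.Generator`` so a
(config, seed) pair reproduces a trajectory bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import CellState, ModelParams, NonFiniteStateError, Population, StepInfo, advance
from .geometry import SpheroidShape, shape_from_oblateness

__all__ = [
    "SimulationConfig",
    "Frame",
    "Trajectory",
    "random_unit_vector",
    "complete_frame",
    "introduce_cell",
    "run_simulation",
    "run_simulation_A",
    "run_simulation_B",
    "cube_side_for_density",
    "expected_cell_count",
]

#: reference cube side for the bulk protocol at the reference population size
_REFERENCE_CUBE_SIDE = 20.0
_REFERENCE_N_CELLS = 2500


def cube_side_for_density(n_cells: int) -> float:
    """Cube side giving the same mean number density as 2,500 cells in side 20."""
    return _REFERENCE_CUBE_SIDE * (n_cells / _REFERENCE_N_CELLS) ** (1.0 / 3.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one run; together with ``seed`` it determines the trajectory."""

    protocol: str = "A"  # "A" (sequential) or "B" (bulk)
    total_steps: int = 25_000
    oblateness: float = 0.7
    params: ModelParams = field(default_factory=ModelParams)
    seed: int = 0
    introduction_interval: int = 10  # protocol A
    n_cells: int = 2500  # protocol B
    cube_side: float | None = None  # protocol B; None -> reference-density rule
    record_every: int = 100

    def __post_init__(self) -> None:
        if self.protocol not in ("A", "B"):
            raise ValueError(f"protocol must be 'A' or 'B', got {self.protocol!r}")
        if self.total_steps < 1:
            raise ValueError("total_steps must be >= 1")
        if self.introduction_interval < 1:
            raise ValueError("introduction_interval must be >= 1")
        if self.cube_side is not None and self.cube_side <= 0:
            raise ValueError("cube_side must be positive")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")

    @property
    def shape(self) -> SpheroidShape:
        return shape_from_oblateness(self.oblateness)

    def resolved_cube_side(self) -> float:
        if self.cube_side is not None:
            return self.cube_side
        return cube_side_for_density(self.n_cells)


@dataclass
class Frame:
    """Recorded snapshot: step index plus per-cell ids/positions/velocities/frames."""

    t: int
    ids: np.ndarray
    r: np.ndarray
    v: np.ndarray
    frames: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.ids)

    @property
    def e_x(self) -> np.ndarray:
        """Major-axis directions, shape (N, 3)."""
        return self.frames[:, :, 0]


@dataclass
class Trajectory:
    """Time-indexed record of a run; the unit of exchange with the analysis layer."""

    config: SimulationConfig
    frames: list[Frame] = field(default_factory=list)
    step_info: list[StepInfo] = field(default_factory=list)

    @property
    def times(self) -> list[int]:
        return [f.t for f in self.frames]

    @property
    def final(self) -> Frame:
        return self.frames[-1]

    def frame_at(self, t: int) -> Frame:
        for f in self.frames:
            if f.t == t:
                return f
        raise KeyError(f"no recorded frame at step {t}; recorded: {self.times}")


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    """Uniform direction on the unit sphere (normalised 3-variate Gaussian)."""
    while True:
        g = rng.standard_normal(3)
        norm = np.linalg.norm(g)
        if norm > 1e-12:
            return g / norm


def complete_frame(e_x: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame with the given major axis.

    ``e_y = normalize(h x e_x)`` with ``h`` the canonical basis vector least
    aligned with ``e_x``; ``e_z = e_x x e_y``.  Deterministic and
    singularity-free; for a body of revolution the spin about ``e_x`` is
    dynamically irrelevant.
    """
    e_x = np.asarray(e_x, dtype=float)
    h = np.zeros(3)
    h[np.argmin(np.abs(e_x))] = 1.0
    e_y = np.cross(h, e_x)
    e_y /= np.linalg.norm(e_y)
    e_z = np.cross(e_x, e_y)
    return np.column_stack([e_x, e_y, e_z])


def introduce_cell(rng: np.random.Generator, at: np.ndarray | None = None) -> CellState:
    """A resting cell at ``at`` (default origin) with a uniformly random major axis."""
    at = np.zeros(3) if at is None else np.asarray(at, dtype=float)
    return CellState(r=at.copy(), v=np.zeros(3), frame=complete_frame(random_unit_vector(rng)))


def _record(traj: Trajectory, t: int, pop: Population) -> None:
    traj.frames.append(
        Frame(t=t, ids=pop.ids.copy(), r=pop.r.copy(), v=pop.v.copy(), frames=pop.frames.copy())
    )


def _run(config: SimulationConfig, progress=None) -> Trajectory:
    rng = np.random.default_rng(config.seed)
    shape = config.shape
    grid = config.params.grid()
    traj = Trajectory(config=config)

    if config.protocol == "A":
        pop = Population.empty()
        next_id = 0
    else:
        side = config.resolved_cube_side()
        states = []
        for _ in range(config.n_cells):
            cell = introduce_cell(rng)
            cell.r = rng.uniform(-side / 2.0, side / 2.0, size=3)
            states.append(cell)
        pop = Population.from_states(states, ids=np.arange(config.n_cells, dtype=np.int64))
        next_id = config.n_cells

    _record(traj, 0, pop)
    for t_old in range(config.total_steps):
        if config.protocol == "A" and t_old % config.introduction_interval == 0:
            pop = pop.append(introduce_cell(rng), cell_id=next_id)
            next_id += 1
        try:
            pop, info = advance(pop, shape, grid, config.params)
        except NonFiniteStateError as err:
            raise RuntimeError(
                f"non-finite {err.what} for cell index {err.cell_index} "
                f"while advancing step {t_old} -> {t_old + 1}"
            ) from err
        traj.step_info.append(info)
        t = t_old + 1
        if t % config.record_every == 0 or t == config.total_steps:
            _record(traj, t, pop)
        if progress is not None:
            progress(t, pop, info)
    return traj


def run_simulation_A(config: SimulationConfig, progress=None) -> Trajectory:
    """Sequential-seeding run; a new resting cell appears at the origin before the
    step leaving every time divisible by the introduction interval, so the
    recorded population follows ``N_t = ceil(t / interval)``."""
    if config.protocol != "A":
        raise ValueError("config.protocol must be 'A'")
    return _run(config, progress)


def run_simulation_B(config: SimulationConfig, progress=None) -> Trajectory:
    """Bulk-seeding run: all cells placed uniformly in the cube at t=0."""
    if config.protocol != "B":
        raise ValueError("config.protocol must be 'B'")
    return _run(config, progress)


def run_simulation(config: SimulationConfig, progress=None) -> Trajectory:
    """Dispatch on ``config.protocol``."""
    return run_simulation_A(config, progress) if config.protocol == "A" else run_simulation_B(config, progress)


def expected_cell_count(t: int, interval: int = 10) -> int:
    """Sequential-seeding population law ``N_t = ceil(t / interval)``."""
    return math.ceil(t / interval)
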