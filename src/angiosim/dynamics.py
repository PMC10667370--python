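"""One synchronous update step of the discrete cell-dynamics system.

Each cell carries a position ``r``, a velocity ``v`` and an orthonormal
orientation frame whose columns are the spheroid's major/middle/minor axes.
Per step (one step ~ 2 min, one length unit ~ 40 um):

* pairs in sampling-point contact repel with constant magnitude ``f_r``;
* pairs with centre distance <= ``R_a`` attract with constant magnitude
  ``f_a`` (contact does not suppress attraction; the net radial push while
  interpenetrating is ``f_r - f_a > 0``);
* a moving cell with at least one neighbour within ``R_a`` receives a
  constant drive ``d`` along its velocity;
* ``v' = (1 - gamma1) v + sum F + D`` and ``r' = r + v`` (old velocity);
* the frame is rotated by ``R = Q P``: ``Q`` turns the major axis toward the
  new velocity with angle ``gamma2 * sin(2 xi)`` (head-tail symmetric), and
  ``P`` responds to contact, each penetrating sampling point ``(k, l)``
  contributing a rotation ``-f_p sin(2 phi_k)`` about the axis obtained by
  rotating the minor axis ``e_z`` about ``e_x`` by ``2 pi l / L``.

The module exposes small per-pair operations (used directly in tests and as
an independent reference) and a vectorised engine, :func:`advance`, that
applies the identical mathematics to the whole population at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    SamplingGrid,
    SpheroidShape,
    _rodrigues_batch,
    nearest_rotation,
    rotation_exp,
)

__all__ = [
    "CellState",
    "ModelParams",
    "Population",
    "StepInfo",
    "NonFiniteStateError",
    "repulsive_force",
    "attractive_force",
    "driving_force",
    "velocity_update",
    "alignment_rotation",
    "contact_rotation",
    "contact_rotation_axes",
    "step",
    "advance",
]

_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Force/rotation constants; defaults are the baseline parameter set."""

    gamma1: float = 0.1  # friction, in (0, 1)
    f_r: float = 0.02  # repulsion strength (excluded volume), > f_a
    f_a: float = 0.001  # attraction strength
    d: float = 0.002  # driving strength
    f_p: float = 0.001  # contact-rotation strength
    gamma2: float = 0.01  # velocity-alignment rotation strength
    K: int = 10  # polar sampling divisions
    L: int = 8  # azimuthal sampling divisions
    r_a_factor: float = 1.25  # R_a = r_a_factor * a_r (scales with shape)
    v_zero_tol: float = 1e-12  # speed below which v counts as zero
    symmetric_contact: bool = True  # two-sided sampling-point test
    per_neighbor_rotation: bool = False  # multiply P per neighbour instead of one exp

    def __post_init__(self) -> None:
        # the model assumes f_r > f_a > 0 (excluded volume) and gamma1 in (0,1);
        # zero values are admitted so degenerate/oracle configurations (free
        # decay, momentum conservation, null dynamics) remain expressible
        if not 0.0 <= self.gamma1 < 1.0:
            raise ValueError(f"gamma1 must lie in [0, 1), got {self.gamma1}")
        if self.f_a > self.f_r:
            raise ValueError(
                f"excluded volume requires f_r >= f_a, got f_r={self.f_r}, f_a={self.f_a}"
            )
        for name in ("f_r", "f_a", "d", "f_p", "gamma2"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")

    def attraction_radius(self, shape: SpheroidShape) -> float:
        """Interaction radius ``R_a``; tied to the semi-major axis."""
        return self.r_a_factor * shape.a_r

    def grid(self) -> SamplingGrid:
        return SamplingGrid(K=self.K, L=self.L)


@dataclass
class CellState:
    """State of one cell: centre, velocity, orientation frame (columns e_x, e_y, e_z)."""

    r: np.ndarray
    v: np.ndarray
    frame: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.frame = np.asarray(self.frame, dtype=float)

    @property
    def e_x(self) -> np.ndarray:
        return self.frame[:, 0]

    @property
    def e_y(self) -> np.ndarray:
        return self.frame[:, 1]

    @property
    def e_z(self) -> np.ndarray:
        return self.frame[:, 2]


class NonFiniteStateError(RuntimeError):
    """Raised when a cell's state stops being finite during an update."""

    def __init__(self, cell_index: int, what: str):
        self.cell_index = cell_index
        self.what = what
        super().__init__(f"non-finite {what} for cell index {cell_index}")


@dataclass
class Population:
    """Array-of-cells container used by the vectorised engine.

    ``ids`` are stable per-cell identifiers (never reused); ``frames`` has
    shape (N, 3, 3) with axis columns.
    """

    ids: np.ndarray
    r: np.ndarray
    v: np.ndarray
    frames: np.ndarray

    @classmethod
    def empty(cls) -> "Population":
        return cls(
            ids=np.empty(0, dtype=np.int64),
            r=np.empty((0, 3)),
            v=np.empty((0, 3)),
            frames=np.empty((0, 3, 3)),
        )

    @classmethod
    def from_states(cls, states: list[CellState], ids=None) -> "Population":
        n = len(states)
        if ids is None:
            ids = np.arange(n, dtype=np.int64)
        if n == 0:
            return cls.empty()
        return cls(
            ids=np.asarray(ids, dtype=np.int64),
            r=np.array([s.r for s in states], dtype=float),
            v=np.array([s.v for s in states], dtype=float),
            frames=np.array([s.frame for s in states], dtype=float),
        )

    def to_states(self) -> list[CellState]:
        return [CellState(self.r[i].copy(), self.v[i].copy(), self.frames[i].copy()) for i in range(self.n)]

    @property
    def n(self) -> int:
        return len(self.ids)

    def append(self, state: CellState, cell_id: int) -> "Population":
        return Population(
            ids=np.append(self.ids, np.int64(cell_id)),
            r=np.vstack([self.r, state.r[None, :]]),
            v=np.vstack([self.v, state.v[None, :]]),
            frames=np.concatenate([self.frames, state.frame[None, :, :]], axis=0),
        )

    def copy(self) -> "Population":
        return Population(self.ids.copy(), self.r.copy(), self.v.copy(), self.frames.copy())


@dataclass
class StepInfo:
    """Diagnostics from one engine step."""

    n_candidate_pairs: int = 0
    n_contact_pairs: int = 0
    mean_speed: float = 0.0


# ---------------------------------------------------------------------------
# per-pair reference operations
# ---------------------------------------------------------------------------


def _unit_separation(cell_i: CellState, cell_j: CellState) -> np.ndarray:
    """Unit vector from i toward j.

    When the centres coincide the direction 0/0 is undefined; the major axis
    of cell-i (the lower-index cell of the pair) stands in.  Deterministic
    given the state, and isotropic across runs because axes are seeded at
    random — a fixed lab axis here would lock coincident-seeded populations
    onto a single line.
    """
    delta = cell_j.r - cell_i.r
    dist = np.linalg.norm(delta)
    if dist < _ZERO_TOL:
        return cell_i.e_x.copy()
    return delta / dist


def repulsive_force(
    cell_i: CellState, cell_j: CellState, params: ModelParams, in_contact: bool
) -> np.ndarray:
    """Constant-magnitude repulsion ``-f_r * (r_j - r_i)/|r_j - r_i|`` while in contact."""
    if not in_contact:
        return np.zeros(3)
    return -params.f_r * _unit_separation(cell_i, cell_j)


def attractive_force(cell_i: CellState, cell_j: CellState, params: ModelParams, R_a: float) -> np.ndarray:
    """Constant-magnitude attraction toward j when centre distance <= R_a (boundary included)."""
    dist = np.linalg.norm(cell_j.r - cell_i.r)
    if dist > R_a:
        return np.zeros(3)
    return params.f_a * _unit_separation(cell_i, cell_j)


def driving_force(cell_i: CellState, neighbors_within_Ra: bool, params: ModelParams) -> np.ndarray:
    """Constant push ``d`` along the current velocity, only when moving and near a neighbour."""
    speed = np.linalg.norm(cell_i.v)
    if speed <= params.v_zero_tol or not neighbors_within_Ra:
        return np.zeros(3)
    return params.d * cell_i.v / speed


def velocity_update(
    cell_i: CellState, total_force: np.ndarray, driving: np.ndarray, params: ModelParams
) -> np.ndarray:
    """``v' = (1 - gamma1) v + sum_j F_ij + D``."""
    return (1.0 - params.gamma1) * cell_i.v + np.asarray(total_force) + np.asarray(driving)


def alignment_rotation(cell_i: CellState, v_next: np.ndarray, params: ModelParams) -> np.ndarray:
    """Rotation ``Q`` turning the major axis toward the updated velocity.

    Rotation angle ``gamma2 * sin(2 xi)`` about ``e_x x v'``, where ``xi`` is
    the angle between ``e_x`` and ``v'``; identity when ``v'`` vanishes or is
    parallel/antiparallel to the axis.  The ``sin(2 xi)`` factor makes the
    alignment head-tail symmetric with an unstable perpendicular equilibrium.
    """
    v_next = np.asarray(v_next, dtype=float)
    speed = np.linalg.norm(v_next)
    if speed <= params.v_zero_tol:
        return np.eye(3)
    c = np.cross(cell_i.e_x, v_next)
    c_norm = np.linalg.norm(c)
    if c_norm < _ZERO_TOL:
        return np.eye(3)
    sin_xi = c_norm / speed
    cos_xi = float(cell_i.e_x @ v_next) / speed
    chi = params.gamma2 * 2.0 * sin_xi * cos_xi  # gamma2 * sin(2 xi)
    return rotation_exp(chi, c / c_norm)


def contact_rotation_axes(cell_i: CellState, L: int) -> np.ndarray:
    """The L contact-rotation axes ``n_l``: e_z rotated about e_x by ``2 pi l / L``.

    For an orthonormal frame this reduces to ``cos(a) e_z - sin(a) e_y``.
    """
    alpha = 2.0 * np.pi * np.arange(L) / L
    return np.cos(alpha)[:, None] * cell_i.e_z - np.sin(alpha)[:, None] * cell_i.e_y


def contact_rotation(
    cell_i: CellState, penetrating_indices: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Rotation ``P`` from the penetrating sampling points of cell-i's own grid.

    Each penetrating index ``(k, l)`` contributes angle ``-f_p sin(2 phi_k)``
    (``phi_k = pi k / K``) about axis ``n_l``; contributions (over all contacting neighbours) are summed
    into one generator and exponentiated once.  Pole rows k=0 and k=K contribute
    nothing since ``sin(0) = sin(2 pi) = 0``.
    """
    penetrating_indices = np.asarray(penetrating_indices, dtype=int).reshape(-1, 2)
    if len(penetrating_indices) == 0:
        return np.eye(3)
    k, l = penetrating_indices[:, 0], penetrating_indices[:, 1]
    phi_k = np.pi * k / params.K
    psi = -params.f_p * np.sin(2.0 * phi_k)
    axes = contact_rotation_axes(cell_i, params.L)  # (L, 3)
    w = (psi[:, None] * axes[l]).sum(axis=0)
    angle = np.linalg.norm(w)
    if angle < _ZERO_TOL:
        return np.eye(3)
    return rotation_exp(angle, w / angle)


# ---------------------------------------------------------------------------
# vectorised engine
# ---------------------------------------------------------------------------

_PAIR_CHUNK = 4096  # bounds the temporary (chunk, grid, 3) arrays to a few MB


def _candidate_pairs(r: np.ndarray, cutoff: float) -> np.ndarray:
    """All index pairs (i < j) with centre distance <= cutoff."""
    if len(r) < 2:
        return np.empty((0, 2), dtype=np.int64)
    tree = cKDTree(r)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64)
    return pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]


def advance(
    pop: Population,
    shape: SpheroidShape,
    grid: SamplingGrid,
    params: ModelParams,
) -> tuple[Population, StepInfo]:
    """One synchronous step of the whole population.

    All contacts and forces are evaluated from the time-t configuration before
    any state is written; positions advance with the old velocity while the
    alignment rotation uses the updated one.
    """
    n = pop.n
    info = StepInfo()
    if n == 0:
        return pop.copy(), info

    r, v, frames = pop.r, pop.v, pop.frames
    R_a = params.attraction_radius(shape)
    cutoff = max(2.0 * shape.a_r, R_a) + 1e-12

    pairs = _candidate_pairs(r, cutoff)
    i_idx, j_idx = pairs[:, 0], pairs[:, 1]
    delta = r[j_idx] - r[i_idx]
    dist = np.linalg.norm(delta, axis=1)
    # unit separation; coincident centres fall back on the lower-index cell's
    # major axis (deterministic, isotropic — see _unit_separation)
    u = delta / np.maximum(dist, _ZERO_TOL)[:, None]
    coincident = dist < _ZERO_TOL
    if coincident.any():
        u[coincident] = frames[i_idx[coincident]][:, :, 0]

    # exact support-slab prefilter: bodies are disjoint (hence no sampling
    # point of one inside the other) whenever the centre distance exceeds the
    # sum of the two half-extents along the centre line
    semi = shape.semi_axes
    if len(pairs):
        bu_i = np.einsum("pba,pb->pa", frames[i_idx], u)
        bu_j = np.einsum("pba,pb->pa", frames[j_idx], u)
        h_i = np.linalg.norm(bu_i * semi, axis=1)
        h_j = np.linalg.norm(bu_j * semi, axis=1)
        cand = dist <= h_i + h_j + 1e-9
    else:
        cand = np.zeros(0, dtype=bool)
    info.n_candidate_pairs = int(cand.sum())

    contact = np.zeros(len(pairs), dtype=bool)
    w_p = np.zeros((n, 3))  # contact-rotation generator vector per cell
    per_nb: list[list[tuple[int, np.ndarray]]] | None = None
    if params.per_neighbor_rotation:
        per_nb = [[] for _ in range(n)]

    if cand.any():
        psi_k = -params.f_p * np.sin(2.0 * np.pi * np.arange(grid.K + 1) / grid.K)
        alpha = 2.0 * np.pi * np.arange(grid.L) / grid.L
        cos_a, sin_a = np.cos(alpha), np.sin(alpha)
        body_pts = grid.unit_dirs * semi  # (M, 3)
        inv_sq = 1.0 / semi**2
        cand_idx = np.flatnonzero(cand)
        for start in range(0, len(cand_idx), _PAIR_CHUNK):
            sel = cand_idx[start : start + _PAIR_CHUNK]
            ci, cj = i_idx[sel], j_idx[sel]
            F_i, F_j = frames[ci], frames[cj]
            pts_i = r[ci][:, None, :] + np.einsum("pab,mb->pma", F_i, body_pts)
            pts_j = r[cj][:, None, :] + np.einsum("pab,mb->pma", F_j, body_pts)
            # body-frame coordinates of i's points in j and vice versa
            y_ij = np.einsum("pma,pab->pmb", pts_i - r[cj][:, None, :], F_j)
            y_ji = np.einsum("pma,pab->pmb", pts_j - r[ci][:, None, :], F_i)
            mask_ij = (y_ij**2 * inv_sq).sum(-1) <= 1.0  # (P, M)
            mask_ji = (y_ji**2 * inv_sq).sum(-1) <= 1.0
            if params.symmetric_contact:
                contact[sel] = mask_ij.any(1) | mask_ji.any(1)
            else:
                contact[sel] = mask_ij.any(1)
                mask_ji[:] = False
            # accumulate the contact-rotation generator of each involved cell
            for mask, own, F_own in ((mask_ij, ci, F_i), (mask_ji, cj, F_j)):
                if not mask.any():
                    continue
                wl = np.einsum(
                    "pkl,k->pl", mask.reshape(-1, grid.K + 1, grid.L).astype(float), psi_k
                )
                e_y, e_z = F_own[:, :, 1], F_own[:, :, 2]
                n_axes = cos_a[None, :, None] * e_z[:, None, :] - sin_a[None, :, None] * e_y[:, None, :]
                contrib = np.einsum("pl,plc->pc", wl, n_axes)
                if per_nb is None:
                    np.add.at(w_p, own, contrib)
                else:
                    other = cj if own is ci else ci
                    for row in range(len(own)):
                        per_nb[own[row]].append((int(other[row]), contrib[row]))
    info.n_contact_pairs = int(contact.sum())

    # forces ---------------------------------------------------------------
    F = np.zeros((n, 3))
    if len(pairs):
        rep = contact[:, None] * (-params.f_r) * u  # force on i from j
        att_mask = dist <= R_a
        att = att_mask[:, None] * params.f_a * u
        f_on_i = rep + att
        np.add.at(F, i_idx, f_on_i)
        np.add.at(F, j_idx, -f_on_i)
        has_nb = np.zeros(n, dtype=bool)
        has_nb[i_idx[att_mask]] = True
        has_nb[j_idx[att_mask]] = True
    else:
        has_nb = np.zeros(n, dtype=bool)

    speed = np.linalg.norm(v, axis=1)
    drive_on = has_nb & (speed > params.v_zero_tol)
    D = np.zeros((n, 3))
    if drive_on.any():
        D[drive_on] = params.d * v[drive_on] / speed[drive_on, None]

    v_new = (1.0 - params.gamma1) * v + F + D
    r_new = r + v

    # rotations ------------------------------------------------------------
    e_x = frames[:, :, 0]
    speed_new_sq = np.einsum("ij,ij->i", v_new, v_new)
    cross = np.cross(e_x, v_new)
    dot = np.einsum("ij,ij->i", e_x, v_new)
    moving = speed_new_sq > params.v_zero_tol**2
    w_q = np.zeros((n, 3))
    w_q[moving] = (
        2.0 * params.gamma2 * (dot[moving] / speed_new_sq[moving])[:, None] * cross[moving]
    )
    Q = _rodrigues_batch(w_q)

    if per_nb is None:
        P = _rodrigues_batch(w_p)
    else:
        P = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
        for ci_ in range(n):
            entries = sorted(per_nb[ci_], key=lambda e: e[0])
            for _, wvec in entries:
                P[ci_] = P[ci_] @ _rodrigues_batch(wvec[None, :])[0]

    # apply and re-orthonormalise only where a rotation is actually active;
    # inactive cells keep their frame bit-identically (and cheaply)
    active = (np.einsum("ij,ij->i", w_q, w_q) > 0) | (np.einsum("ij,ij->i", w_p, w_p) > 0)
    if per_nb is not None:
        active |= ~np.isclose(P, np.eye(3), atol=0.0).reshape(n, -1).all(axis=1)
    frames_new = frames.copy()
    if active.any():
        R = Q[active] @ P[active]
        frames_new[active] = nearest_rotation(R @ frames[active])

    for name, arr in (("position", r_new), ("velocity", v_new), ("frame", frames_new)):
        finite = np.isfinite(arr).reshape(n, -1).all(axis=1)
        if not finite.all():
            raise NonFiniteStateError(int(np.flatnonzero(~finite)[0]), name)

    info.mean_speed = float(speed.mean()) if n else 0.0
    return Population(ids=pop.ids.copy(), r=r_new, v=v_new, frames=frames_new), info


def step(
    cells: list[CellState],
    shape: SpheroidShape,
    grid: SamplingGrid,
    params: ModelParams,
) -> list[CellState]:
    """Synchronous update of a list of cell states (wrapper over :func:`advance`)."""
    pop, _ = advance(Population.from_states(cells), shape, grid, params)
    return pop.to_states()
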