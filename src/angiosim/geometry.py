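"""Spheroid geometry, surface sampling, contact tests and SO(3) helpers.

Each cell is a constant-volume spheroid (a rotational ellipsoid,
``b_r = c_r``) whose shape is controlled by a single oblateness parameter
``chi = 1 - b_r / a_r``.  Contact between two cells is decided by a discrete
surface-sampling test: a ``(K+1) x L`` grid of points is placed on each
surface and a pair is declared in contact when a sampling point of one cell
lies inside the other.  The penetrating grid indices feed the contact-induced
rotation of the dynamics layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "SpheroidShape",
    "SamplingGrid",
    "ContactResult",
    "shape_from_oblateness",
    "surface_points",
    "point_inside",
    "cells_in_contact",
    "skew",
    "rotation_exp",
    "nearest_rotation",
    "is_orthonormal_frame",
]

#: tolerance below which a vector norm is treated as zero
_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class SpheroidShape:
    """Semi-axes of one cell, ``c_r <= b_r <= a_r``, all positive.

    Model spheroids additionally satisfy ``b_r = c_r`` and the unit-volume
    scaling ``a_r * b_r**2 = 1``; build them with :func:`shape_from_oblateness`.
    """

    a_r: float
    b_r: float
    c_r: float

    def __post_init__(self) -> None:
        if not (0.0 < self.c_r <= self.b_r <= self.a_r):
            raise ValueError(
                f"semi-axes must satisfy 0 < c_r <= b_r <= a_r, got "
                f"({self.a_r}, {self.b_r}, {self.c_r})"
            )

    @property
    def oblateness(self) -> float:
        """``chi = 1 - b_r / a_r`` in [0, 1)."""
        return 1.0 - self.b_r / self.a_r

    @property
    def semi_axes(self) -> np.ndarray:
        return np.array([self.a_r, self.b_r, self.c_r])


def shape_from_oblateness(chi: float) -> SpheroidShape:
    """Spheroid with oblateness ``chi`` under the unit-volume constraint.

    Solving ``chi = 1 - b_r/a_r`` together with ``a_r * b_r**2 = 1`` gives

        a_r = (1 - chi)**(-2/3),   b_r = c_r = (1 - chi)**(1/3).

    ``chi = 0`` is the unit sphere; ``chi -> 1`` is an ever longer needle of
    the same volume.
    """
    if not 0.0 <= chi < 1.0:
        raise ValueError(f"oblateness must lie in [0, 1), got {chi}")
    a_r = (1.0 - chi) ** (-2.0 / 3.0)
    b_r = (1.0 - chi) ** (1.0 / 3.0)
    return SpheroidShape(a_r=a_r, b_r=b_r, c_r=b_r)


@dataclass(frozen=True)
class SamplingGrid:
    """Angular grid ``phi_k = pi*k/K`` (k=0..K), ``theta_l = 2*pi*l/L`` (l=0..L-1).

    The two poles (k=0 and k=K) produce L coincident points each; they are
    kept so grid indices match the ``(K+1) x L`` index set, and they are
    harmless downstream because the contact-rotation angle ``-f_p sin(2*phi_k)``
    vanishes at both poles.
    """

    K: int = 10
    L: int = 8

    def __post_init__(self) -> None:
        if self.K < 1 or self.L < 1:
            raise ValueError(f"K and L must be positive integers, got K={self.K}, L={self.L}")

    @property
    def n_points(self) -> int:
        return (self.K + 1) * self.L

    @cached_property
    def phi(self) -> np.ndarray:
        """phi per grid point, shape (n_points,); point index p = k*L + l."""
        k = np.arange(self.K + 1)
        return np.repeat(np.pi * k / self.K, self.L)

    @cached_property
    def theta(self) -> np.ndarray:
        l = np.arange(self.L)
        return np.tile(2.0 * np.pi * l / self.L, self.K + 1)

    @cached_property
    def k_index(self) -> np.ndarray:
        return np.repeat(np.arange(self.K + 1), self.L)

    @cached_property
    def l_index(self) -> np.ndarray:
        return np.tile(np.arange(self.L), self.K + 1)

    @cached_property
    def unit_dirs(self) -> np.ndarray:
        """Body-frame unit directions (cos phi, sin phi cos theta, sin phi sin theta)."""
        sp = np.sin(self.phi)
        return np.column_stack([np.cos(self.phi), sp * np.cos(self.theta), sp * np.sin(self.theta)])


def surface_points(
    shape: SpheroidShape,
    center: np.ndarray,
    frame: np.ndarray,
    grid: SamplingGrid,
) -> np.ndarray:
    """World-frame sampling points, shape ``(grid.n_points, 3)``.

    ``x(phi, theta) = center + R @ diag(a,b,c) @ (cos phi, sin phi cos theta,
    sin phi sin theta)``, where ``R`` is the frame matrix whose columns are
    the major/middle/minor axes.
    """
    center = np.asarray(center, dtype=float)
    body = grid.unit_dirs * shape.semi_axes  # (M,3)
    return center + body @ np.asarray(frame, dtype=float).T


def point_inside(
    point: np.ndarray,
    shape: SpheroidShape,
    center: np.ndarray,
    frame: np.ndarray,
) -> np.ndarray | bool:
    """Whether point(s) lie inside (or on) the spheroid.

    Evaluates the body-frame quadratic form
    ``sum((R^T (x - r) / (a, b, c))**2) <= 1``; boundary points count as
    inside (a 1e-12 tolerance keeps points constructed exactly on the
    surface from flipping outside through rounding).  Accepts a single
    3-vector or an (N, 3) array.
    """
    point = np.asarray(point, dtype=float)
    single = point.ndim == 1
    body = (np.atleast_2d(point) - np.asarray(center, dtype=float)) @ np.asarray(frame, dtype=float)
    q = ((body / shape.semi_axes) ** 2).sum(axis=1)
    inside = q <= 1.0 + 1e-12
    return bool(inside[0]) if single else inside


@dataclass
class ContactResult:
    """Outcome of the sampling-point contact test for one ordered pair."""

    in_contact: bool
    #: (k, l) grid indices of cell-i's sampling points found inside cell-j
    penetrating_i: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    #: (k, l) grid indices of cell-j's sampling points found inside cell-i
    penetrating_j: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))


def cells_in_contact(
    cell_i: tuple[SpheroidShape, np.ndarray, np.ndarray],
    cell_j: tuple[SpheroidShape, np.ndarray, np.ndarray],
    grid: SamplingGrid,
    *,
    symmetric: bool = True,
) -> ContactResult:
    """Sampling-point contact test between two cells.

    Each cell is a ``(shape, center, frame)`` triple.  With ``symmetric=True``
    (default) contact is declared when any sampling point of either cell lies
    inside the other; a one-sided test (points of i in j only) can miss a thin
    cell piercing a fat one between sampling points.  Penetrating indices are
    reported per cell for the contact-rotation operator.
    """
    shape_i, r_i, R_i = cell_i
    shape_j, r_j, R_j = cell_j
    kl = np.column_stack([grid.k_index, grid.l_index])

    pts_i = surface_points(shape_i, r_i, R_i, grid)
    mask_i = point_inside(pts_i, shape_j, r_j, R_j)
    pts_j = surface_points(shape_j, r_j, R_j, grid)
    mask_j = point_inside(pts_j, shape_i, r_i, R_i)

    if symmetric:
        in_contact = bool(mask_i.any() or mask_j.any())
    else:
        in_contact = bool(mask_i.any())
        mask_j = np.zeros_like(mask_j)
    return ContactResult(
        in_contact=in_contact,
        penetrating_i=kl[mask_i],
        penetrating_j=kl[mask_j],
    )


def skew(n: np.ndarray) -> np.ndarray:
    """Antisymmetric matrix ``S(n)`` with ``S @ w = n x w`` for all w."""
    nx, ny, nz = np.asarray(n, dtype=float)
    return np.array([[0.0, -nz, ny], [nz, 0.0, -nx], [-ny, nx, 0.0]])


def rotation_exp(angle: float, axis: np.ndarray) -> np.ndarray:
    """``exp(angle * S(axis))`` via the closed-form axis-angle (Rodrigues) formula.

    ``axis`` must be unit-norm unless ``angle`` is zero.
    """
    if angle == 0.0:
        return np.eye(3)
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise ValueError(f"rotation axis must be unit-norm, got |axis| = {np.linalg.norm(axis)}")
    S = skew(axis)
    return np.eye(3) + np.sin(angle) * S + (1.0 - np.cos(angle)) * (S @ S)


def _rodrigues_batch(w: np.ndarray, zero_tol: float = _ZERO_TOL) -> np.ndarray:
    """Batched ``exp(S(w))`` for rotation vectors ``w`` of shape (N, 3).

    Rows with ``|w| < zero_tol`` map to the identity.  sinc-style evaluation
    keeps the small-angle limit well conditioned.
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    angle = np.linalg.norm(w, axis=1)
    out = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    act = angle >= zero_tol
    if not act.any():
        return out
    a = angle[act]
    axis = w[act] / a[:, None]
    S = np.zeros((act.sum(), 3, 3))
    S[:, 0, 1], S[:, 0, 2] = -axis[:, 2], axis[:, 1]
    S[:, 1, 0], S[:, 1, 2] = axis[:, 2], -axis[:, 0]
    S[:, 2, 0], S[:, 2, 1] = -axis[:, 1], axis[:, 0]
    S2 = S @ S
    out[act] += np.sin(a)[:, None, None] * S + (1.0 - np.cos(a))[:, None, None] * S2
    return out


def nearest_rotation(M: np.ndarray) -> np.ndarray:
    """Nearest proper rotation(s) to ``M`` (Frobenius norm), via polar projection.

    Accepts one 3x3 matrix or a batch (N, 3, 3).  Used to re-orthonormalise
    orientation frames after many composed incremental rotations.
    """
    M = np.asarray(M, dtype=float)
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    det = np.linalg.det(R)
    if M.ndim == 2:
        if det < 0:
            U[..., :, -1] *= -1.0
            R = U @ Vt
        return R
    bad = det < 0
    if bad.any():
        U[bad, :, -1] *= -1.0
        R = U @ Vt
    return R


def is_orthonormal_frame(frame: np.ndarray, tol: float = 1e-9) -> bool:
    """Right-handed orthonormal check: ``R^T R = I`` and ``det R = +1`` within tol."""
    frame = np.asarray(frame, dtype=float)
    return bool(
        np.allclose(frame.T @ frame, np.eye(3), atol=tol)
        and abs(np.linalg.det(frame) - 1.0) <= tol
    )
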