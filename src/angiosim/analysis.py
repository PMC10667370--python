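"""Pattern metrics for cell-centre clouds and orientation fields.

Two quantities characterise the simulated patterns:

* the **local order parameter** ``O(eps)``: for each cell, the absolute
  cosine of the angle between its major axis and the vector sum of the major
  axes of all cells strictly within distance ``eps``; averaged over cells.
  1 means perfect (nematic-like, head-tail symmetric) alignment, 0.5 is the
  isotropic baseline for axes drawn uniformly on the sphere;
* the **box-counting dimension** of the cell-centre point cloud: the
  least-squares slope of log(occupied boxes) against log(1/edge) over a
  geometric ladder of grid resolutions.  Values near 1 indicate filament- or
  branch-like patterns, near 3 space-filling aggregates.

Replicate runs are summarised by the sample mean with a t-distribution 95%
confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "OrientationField",
    "OrderParameterResult",
    "BoxCountResult",
    "ReplicateSummary",
    "local_order_parameter",
    "box_counting_dimension",
    "replicate_summary",
    "branch_projection",
    "order_parameter_series",
]

_ZERO_TOL = 1e-12


@dataclass
class OrientationField:
    """Cell centres with unit major-axis directions."""

    positions: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.axes = np.atleast_2d(np.asarray(self.axes, dtype=float))
        if self.positions.shape != self.axes.shape or self.positions.shape[1] != 3:
            raise ValueError(
                f"positions and axes must both have shape (N, 3), got "
                f"{self.positions.shape} and {self.axes.shape}"
            )
        norms = np.linalg.norm(self.axes, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("axes must be unit-norm within 1e-9")

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass
class OrderParameterResult:
    """Mean |cos sigma_i| plus bookkeeping of cells excluded from the average."""

    value: float
    epsilon: float
    n_cells: int
    n_eligible: int
    #: cells with empty eps-neighbourhood or a cancelling neighbour sum
    n_excluded: int

    def __float__(self) -> float:
        return self.value


def local_order_parameter(field: OrientationField, epsilon: float = np.inf) -> OrderParameterResult:
    """Local orientation order ``O(eps)`` of an orientation field.

    For each cell i, the neighbour direction is the plain vector sum of
    ``e_x_j`` over all j != i with ``|r_j - r_i| < eps`` (strict); the cell
    contributes ``|cos sigma_i|`` where ``sigma_i`` is the angle between its
    own axis and that sum.  Cells whose neighbourhood is empty, or whose
    neighbour sum nearly cancels (norm < 1e-12), have no defined angle and
    are excluded from the average; their count is reported.
    ``epsilon = inf`` means every other cell is a neighbour.
    """
    n = field.n
    if n < 2:
        raise ValueError(f"order parameter requires at least 2 cells, got {n}")
    axes = field.axes
    if np.isinf(epsilon):
        sums = axes.sum(axis=0) - axes  # all j != i
    else:
        tree = cKDTree(field.positions)
        sums = np.zeros((n, 3))
        # query_pairs uses closed balls; enforce the strict inequality below
        pairs = tree.query_pairs(epsilon, output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(field.positions[pairs[:, 0]] - field.positions[pairs[:, 1]], axis=1)
            pairs = pairs[d < epsilon]
        if len(pairs):
            np.add.at(sums, pairs[:, 0], axes[pairs[:, 1]])
            np.add.at(sums, pairs[:, 1], axes[pairs[:, 0]])
    norms = np.linalg.norm(sums, axis=1)
    eligible = norms >= _ZERO_TOL
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        value = float("nan")
    else:
        cosines = np.abs(np.einsum("ij,ij->i", axes[eligible], sums[eligible])) / norms[eligible]
        value = float(np.clip(cosines, 0.0, 1.0).mean())
    return OrderParameterResult(
        value=value, epsilon=float(epsilon), n_cells=n, n_eligible=n_eligible,
        n_excluded=n - n_eligible,
    )


@dataclass
class BoxCountResult:
    """Box-count ladder, the fitted dimension and fit diagnostics."""

    scales: np.ndarray  # box edge lengths, descending
    counts: np.ndarray  # occupied boxes per scale
    dimension: float
    fit_range: tuple[int, int]  # [start, stop) indices of scales used in the fit
    r_squared: float
    degenerate: bool = False


def box_counting_dimension(
    points: np.ndarray,
    *,
    ratio: float = 2.0,
    coarsest_fraction: float = 0.5,
    saturation_occupancy: float = 3.0,
) -> BoxCountResult:
    """Grid box-counting dimension of a 3-D point cloud.

    The counting grid is anchored at the cloud's bounding-box corner.  Edge
    lengths descend geometrically (factor ``ratio``) from
    ``coarsest_fraction`` of the largest bounding-box extent; a scale is
    dropped (and the ladder stops) once the occupied-box count exceeds
    ``n / saturation_occupancy`` — beyond that, counts approach one box per
    point regardless of geometry and the slope is biased toward 0.  The
    dimension is the least-squares slope of ``log(count)`` against
    ``log(1/edge)`` over the whole retained ladder, clipped to the
    meaningful range [0, 3].

    Calibration on uniform samples of known dimension (segment, square
    patch, solid cube) recovers 1/2/3 within ~0.1 at 10^4 points and within
    ~0.15 at 500 points; finite clouds carry a small negative bias at the
    coarse, boundary-dominated scales, so values are comparable between
    patterns measured at similar n.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n_pts = len(points)
    if n_pts < 2:
        raise ValueError("box counting requires at least 2 points")
    lo = points.min(axis=0)
    extent = float((points.max(axis=0) - lo).max())
    if extent < _ZERO_TOL:
        return BoxCountResult(
            scales=np.array([1.0]), counts=np.array([1]), dimension=0.0,
            fit_range=(0, 1), r_squared=1.0, degenerate=True,
        )
    cap = n_pts / saturation_occupancy
    scales, counts = [], []
    edge = extent * coarsest_fraction
    while True:
        idx = np.floor((points - lo) / edge).astype(np.int64)
        cnt = len(np.unique(idx, axis=0))
        # keep at least two scales so a slope exists even for tiny inputs
        if cnt > cap and len(scales) >= 2:
            break
        scales.append(edge)
        counts.append(cnt)
        if (cnt > cap and len(scales) >= 2) or len(scales) >= 64:
            break
        edge /= ratio
    scales_arr = np.asarray(scales)
    counts_arr = np.asarray(counts, dtype=np.int64)
    x = np.log(1.0 / scales_arr)
    y = np.log(counts_arr.astype(float))
    if len(x) < 2 or np.ptp(y) < _ZERO_TOL:
        slope, r2 = 0.0, 1.0
    else:
        fit = stats.linregress(x, y)
        slope, r2 = float(fit.slope), float(fit.rvalue**2)
    return BoxCountResult(
        scales=scales_arr, counts=counts_arr,
        dimension=float(np.clip(slope, 0.0, 3.0)),
        fit_range=(0, len(scales_arr)), r_squared=r2,
    )


@dataclass
class ReplicateSummary:
    """Sample mean with a t-distribution 95% confidence interval."""

    mean: float
    ci_low: float
    ci_high: float
    n: int

    @property
    def half_width(self) -> float:
        return (self.ci_high - self.ci_low) / 2.0


def replicate_summary(values, confidence: float = 0.95) -> ReplicateSummary:
    """Mean and t-based confidence interval over replicate metric values."""
    values = np.asarray(list(values), dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError(f"replicate summary requires at least 2 values, got {n}")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(n))
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1))
    half = tcrit * sem
    return ReplicateSummary(mean=mean, ci_low=mean - half, ci_high=mean + half, n=n)


def branch_projection(trajectory, cell_ids, axis, origin=None):
    """Scalar positions of selected cells along a branch axis, per recorded step.

    Projects ``(r - origin) . axis`` for every requested cell at every
    recorded time; crossings of the resulting 1-D curves reveal cells
    overtaking each other (cell mixing) inside a branch.  Returns
    ``(times, {cell_id: 1-D array})``; positions are NaN before a cell exists.
    """
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise ValueError(f"branch axis must be unit-norm, got |axis| = {np.linalg.norm(axis)}")
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    cell_ids = [int(c) for c in cell_ids]
    known = set()
    for f in trajectory.frames:
        known.update(int(i) for i in f.ids)
    unknown = [c for c in cell_ids if c not in known]
    if unknown:
        raise KeyError(f"cell id(s) {unknown} never appear in the trajectory")
    times = np.asarray(trajectory.times)
    series = {c: np.full(len(times), np.nan) for c in cell_ids}
    for ti, f in enumerate(trajectory.frames):
        proj = (f.r - origin) @ axis
        id_pos = {int(cid): proj[row] for row, cid in enumerate(f.ids)}
        for c in cell_ids:
            if c in id_pos:
                series[c][ti] = id_pos[c]
    return times, series


def order_parameter_series(trajectory, epsilons=(5.0, 10.0, 20.0, np.inf)):
    """``O(eps)`` at every recorded step with >= 2 cells, for each ``eps``.

    Returns a list of dict rows ``{t, epsilon, value, n_cells, n_excluded}``
    (tidy layout, one row per time x eps).
    """
    rows = []
    for f in trajectory.frames:
        if f.n_cells < 2:
            continue
        fld = OrientationField(positions=f.r, axes=f.e_x)
        for eps in epsilons:
            res = local_order_parameter(fld, eps)
            rows.append(
                {
                    "t": f.t,
                    "epsilon": float(eps),
                    "value": res.value,
                    "n_cells": res.n_cells,
                    "n_excluded": res.n_excluded,
                }
            )
    return rows
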