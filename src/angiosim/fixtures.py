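"""Synthetic inputs with known ground-truth metric values.

These generators produce orientation fields, point clouds and toy
trajectories whose order parameter / box-counting dimension / crossing
structure is known analytically, for calibrating and testing the analysis
layer independently of the simulator.
"""

from __future__ import annotations

import numpy as np

from .analysis import OrientationField
from .dynamics import StepInfo
from .simulation import Frame, SimulationConfig, Trajectory, complete_frame, random_unit_vector

__all__ = [
    "aligned_field",
    "random_field",
    "line_cloud",
    "plane_cloud",
    "cube_cloud",
    "two_walkers",
    "FIXTURE_KINDS",
]


def aligned_field(n: int, seed: int = 0, axis=(0.0, 0.0, 1.0)) -> OrientationField:
    """n cells at random positions, all axes identical -> order parameter exactly 1."""
    rng = np.random.default_rng(seed)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return OrientationField(
        positions=rng.uniform(-5.0, 5.0, size=(n, 3)),
        axes=np.tile(axis, (n, 1)),
    )


def random_field(n: int, seed: int = 0) -> OrientationField:
    """Axes i.i.d. uniform on the sphere -> order parameter 0.5 asymptotically."""
    rng = np.random.default_rng(seed)
    axes = rng.standard_normal((n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    return OrientationField(positions=rng.uniform(-5.0, 5.0, size=(n, 3)), axes=axes)


def line_cloud(n: int, seed: int = 0, length: float = 10.0) -> np.ndarray:
    """Points uniform on a segment (dimension 1), randomly oriented in 3-D."""
    rng = np.random.default_rng(seed)
    direction = random_unit_vector(rng)
    return rng.uniform(0.0, length, size=(n, 1)) * direction


def plane_cloud(n: int, seed: int = 0, side: float = 10.0) -> np.ndarray:
    """Points uniform on a square patch (dimension 2)."""
    rng = np.random.default_rng(seed)
    frame = complete_frame(random_unit_vector(rng))
    uv = rng.uniform(0.0, side, size=(n, 2))
    return uv @ frame[:, 1:].T


def cube_cloud(n: int, seed: int = 0, side: float = 10.0) -> np.ndarray:
    """Points uniform in a cube (dimension 3)."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, side, size=(n, 3))


def two_walkers(n_steps: int = 50) -> Trajectory:
    """Toy trajectory of two straight-line cells that swap order along x.

    Walker 0 moves +x from 0, walker 1 moves -x from ``n_steps``/2; their
    x-projections cross exactly once.  Exercises the branch-projection
    crossing diagnostics without running the simulator.
    """
    config = SimulationConfig(protocol="B", total_steps=n_steps, n_cells=2, record_every=1)
    traj = Trajectory(config=config)
    eye = np.eye(3)
    for t in range(n_steps + 1):
        r = np.array(
            [[t * 1.0, 0.0, 0.0], [n_steps / 2.0 - t * 1.0, 0.5, 0.0]]
        )
        v = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
        traj.frames.append(
            Frame(
                t=t,
                ids=np.array([0, 1], dtype=np.int64),
                r=r,
                v=v,
                frames=np.broadcast_to(eye, (2, 3, 3)).copy(),
            )
        )
        if t < n_steps:
            traj.step_info.append(StepInfo())
    return traj


FIXTURE_KINDS = {
    "aligned_field": aligned_field,
    "random_field": random_field,
    "line_cloud": line_cloud,
    "plane_cloud": plane_cloud,
    "cube_cloud": cube_cloud,
    "two_walkers": two_walkers,
}
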