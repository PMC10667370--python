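"""Trajectory/config/metric readers and writers.

Formats:

* tidy trajectory CSV — one row per (step, cell) with position, velocity and
  the major/minor axis directions, written with 17 significant digits so a
  write/read round trip reproduces doubles within 1e-12;
* HDF5 container — one group per recorded frame, lossless;
* YAML/JSON config files mirroring :class:`~angiosim.simulation.SimulationConfig`
  (unknown keys are rejected, not ignored);
* JSON run manifests sufficient to reproduce a run;
* optional per-frame XYZ export for 3-D viewers.

Column units: 1 step ~ 2 min, 1 length unit ~ 40 um.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .dynamics import ModelParams
from .simulation import Frame, SimulationConfig, Trajectory

__all__ = [
    "trajectory_to_dataframe",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_trajectory_hdf5",
    "read_trajectory_hdf5",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "write_manifest",
    "write_xyz",
]

#: tidy CSV column order (ex/ez suffice: e_y = e_z x e_x for a right-handed frame)
CSV_COLUMNS = [
    "step", "cell_id", "x", "y", "z", "vx", "vy", "vz",
    "ex_x", "ex_y", "ex_z", "ez_x", "ez_y", "ez_z",
]

_CSV_HEADER_COMMENT = "# units: 1 step ~ 2 min, 1 length unit ~ 40 um\n"


def trajectory_to_dataframe(traj: Trajectory) -> pd.DataFrame:
    rows = []
    for f in traj.frames:
        if f.n_cells == 0:
            continue
        block = pd.DataFrame(
            {
                "step": f.t,
                "cell_id": f.ids,
                "x": f.r[:, 0], "y": f.r[:, 1], "z": f.r[:, 2],
                "vx": f.v[:, 0], "vy": f.v[:, 1], "vz": f.v[:, 2],
                "ex_x": f.frames[:, 0, 0], "ex_y": f.frames[:, 1, 0], "ex_z": f.frames[:, 2, 0],
                "ez_x": f.frames[:, 0, 2], "ez_y": f.frames[:, 1, 2], "ez_z": f.frames[:, 2, 2],
            }
        )
        rows.append(block)
    if not rows:
        return pd.DataFrame(columns=CSV_COLUMNS)
    return pd.concat(rows, ignore_index=True)[CSV_COLUMNS]


def write_trajectory_csv(traj: Trajectory, path) -> None:
    path = Path(path)
    df = trajectory_to_dataframe(traj)
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER_COMMENT)
        df.to_csv(fh, index=False, float_format="%.17g")


def read_trajectory_csv(path, config: SimulationConfig | None = None) -> Trajectory:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV is missing column(s) {missing}")
    traj = Trajectory(config=config)
    for t, block in df.groupby("step", sort=True):
        e_x = block[["ex_x", "ex_y", "ex_z"]].to_numpy()
        e_z = block[["ez_x", "ez_y", "ez_z"]].to_numpy()
        e_y = np.cross(e_z, e_x)
        frames = np.stack([e_x, e_y, e_z], axis=-1)
        traj.frames.append(
            Frame(
                t=int(t),
                ids=block["cell_id"].to_numpy(dtype=np.int64),
                r=block[["x", "y", "z"]].to_numpy(),
                v=block[["vx", "vy", "vz"]].to_numpy(),
                frames=frames,
            )
        )
    return traj


def write_trajectory_hdf5(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "angiosim-trajectory-v1"
        if traj.config is not None:
            h5.attrs["config_json"] = json.dumps(config_to_dict(traj.config))
        grp = h5.create_group("frames")
        for i, f in enumerate(traj.frames):
            g = grp.create_group(f"{i:06d}")
            g.attrs["t"] = f.t
            g.create_dataset("ids", data=f.ids)
            g.create_dataset("r", data=f.r)
            g.create_dataset("v", data=f.v)
            g.create_dataset("frames", data=f.frames)


def read_trajectory_hdf5(path) -> Trajectory:
    with h5py.File(path, "r") as h5:
        config = None
        if "config_json" in h5.attrs:
            config = config_from_dict(json.loads(h5.attrs["config_json"]))
        traj = Trajectory(config=config)
        for key in sorted(h5["frames"].keys()):
            g = h5["frames"][key]
            traj.frames.append(
                Frame(
                    t=int(g.attrs["t"]),
                    ids=g["ids"][()].astype(np.int64),
                    r=g["r"][()],
                    v=g["v"][()],
                    frames=g["frames"][()],
                )
            )
    return traj


# -- configuration ----------------------------------------------------------

_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParams)}
_CONFIG_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a config from a plain mapping; unknown keys raise ValueError."""
    data = dict(data)
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    params_data = data.pop("params", {}) or {}
    unknown_p = set(params_data) - _PARAM_KEYS
    if unknown_p:
        raise ValueError(f"unknown model parameter key(s): {sorted(unknown_p)}")
    return SimulationConfig(params=ModelParams(**params_data), **data)


def load_config(path) -> SimulationConfig:
    """Read a YAML (or JSON — a YAML subset) config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return config_from_dict(data)


def write_manifest(path, config: SimulationConfig, outputs: dict, extra: dict | None = None) -> None:
    """JSON manifest: config echo + seed + output paths; suffices to reproduce the run."""
    from . import __version__

    manifest = {
        "tool": "angiosim",
        "version": __version__,
        "seed": config.seed,
        "config": config_to_dict(config),
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")


def write_xyz(traj: Trajectory, path) -> None:
    """Minimal multi-frame XYZ export of cell centres for 3-D viewers."""
    with open(path, "w") as fh:
        for f in traj.frames:
            fh.write(f"{f.n_cells}\n")
            fh.write(f"step={f.t}\n")
            for row in f.r:
                fh.write(f"C {row[0]:.6f} {row[1]:.6f} {row[2]:.6f}\n")
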