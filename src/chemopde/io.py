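"""Dataset serialization: HDF5 array container, long-format CSV, YAML configs."""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np
import pandas as pd
import yaml

from .simulate import RadialGrid, SimulationConfig, SpatioTemporalField

__all__ = [
    "save_run",
    "load_run",
    "fields_to_csv",
    "config_to_yaml",
    "config_from_yaml",
]


def save_run(path, b: SpatioTemporalField, c: SpatioTemporalField | None = None, config: SimulationConfig | None = None):
    """Write fields (+ optional config) to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("b", data=b.values)
        f.create_dataset("times", data=b.times)
        f.create_dataset("r", data=b.grid.r)
        f.attrs["dr"] = b.grid.dr
        f.attrs["coordinate_mode"] = b.grid.coordinate_mode
        if c is not None:
            f.create_dataset("c", data=c.values)
        if config is not None:
            grp = f.create_group("config")
            for key, val in config.to_dict().items():
                grp.attrs[key] = val


def load_run(path):
    """Read fields back; returns (b, c or None, config or None)."""
    with h5py.File(path, "r") as f:
        grid = RadialGrid(
            r=f["r"][:], dr=float(f.attrs["dr"]), coordinate_mode=str(f.attrs["coordinate_mode"])
        )
        times = f["times"][:]
        b = SpatioTemporalField(f["b"][:], times, grid, name="b", units="1/µm³")
        c = None
        if "c" in f:
            c = SpatioTemporalField(f["c"][:], times, grid, name="c", units="µM")
        config = None
        if "config" in f:
            kwargs = {k: v for k, v in f["config"].attrs.items()}
            if "coordinate_mode" in kwargs:
                kwargs["coordinate_mode"] = str(kwargs["coordinate_mode"])
            config = SimulationConfig(**kwargs)
    return b, c, config


def fields_to_csv(path, b: SpatioTemporalField, c: SpatioTemporalField | None = None):
    """Long-format (t, r, b[, c]) CSV export."""
    tt, rr = np.meshgrid(b.times, b.grid.r, indexing="ij")
    data = {"t": tt.ravel(), "r": rr.ravel(), "b": b.values.ravel()}
    if c is not None:
        data["c"] = c.values.ravel()
    pd.DataFrame(data).to_csv(path, index=False)


def config_to_yaml(path, config: SimulationConfig):
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as f:
        raw = yaml.safe_load(f)
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**raw)
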