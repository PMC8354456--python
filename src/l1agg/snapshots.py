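"""HDF5 snapshot serialization and run manifests."""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import h5py
import numpy as np

from .config import parameter_hash
from .grid import FieldState, PeriodicGrid
from .model import ModelParameters

__all__ = ["write_snapshot", "read_snapshot", "RunManifest", "SnapshotError"]


class SnapshotError(IOError):
    """Corrupt or incomplete snapshot file."""


@dataclass
class RunManifest:
    """Provenance record sufficient to rerun a deterministic stage."""

    config: dict = dc_field(default_factory=dict)
    parameter_hash: str = ""
    seeds: list[int] = dc_field(default_factory=list)
    version: str = "l1agg 0.1.0"
    timings: dict = dc_field(default_factory=dict)
    outputs: list[str] = dc_field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def write_snapshot(state: FieldState, path: str | Path, grid: PeriodicGrid,
                   params: ModelParameters,
                   manifest: RunManifest | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rho", data=state.rho)
        f.create_dataset("U_a", data=state.U_a)
        if state.U_r is not None:
            f.create_dataset("U_r", data=state.U_r)
        f.attrs["t"] = state.t
        f.attrs["dim"] = grid.dim
        f.attrs["extent"] = np.asarray(grid.extent)
        f.attrs["parameter_hash"] = parameter_hash(params)
        f.attrs["written"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    if manifest is not None:
        manifest.outputs.append(str(path))


def read_snapshot(path: str | Path, params: ModelParameters | None = None
                  ) -> tuple[FieldState, PeriodicGrid]:
    """Read a snapshot back; warns if the parameter hash does not match
    the supplied parameter set."""
    try:
        with h5py.File(path, "r") as f:
            rho = f["rho"][...]
            U_a = f["U_a"][...]
            U_r = f["U_r"][...] if "U_r" in f else None
            t = float(f.attrs["t"])
            extent = tuple(float(x) for x in f.attrs["extent"])
            stored_hash = str(f.attrs.get("parameter_hash", ""))
    except (KeyError, OSError) as e:
        raise SnapshotError(f"cannot read snapshot {path}: {e}") from e
    grid = PeriodicGrid(extent=extent, shape=rho.shape)
    if params is not None and stored_hash and parameter_hash(params) != stored_hash:
        warnings.warn(f"snapshot {path} was written with a different "
                      "parameter set", stacklevel=2)
    return FieldState(t, rho, U_a, U_r), grid
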