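"""Artifact I/O: state snapshots (HDF5), series CSV, results JSON.

Every artifact carries a format version and enough provenance (model,
grid, time, config) to reproduce or resume a run.  Round trips are
bit-identical for snapshots and value-preserving for tabular outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd

from .grid import Grid
from .integrator import TissueState
from .models.bocf import BOCFState
from .models.tnnp import TNNPState

SNAPSHOT_FORMAT_VERSION = 1

__all__ = [
    "write_snapshot", "read_snapshot",
    "write_series_csv", "read_series_csv",
    "write_results_json", "read_results_json",
]


def write_snapshot(path, state: TissueState, *, config: Dict | None = None,
                   mode: str = "w"):
    """Write a TissueState (all fields + clock + provenance) to HDF5."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, mode) as f:
        f.attrs["format_version"] = SNAPSHOT_FORMAT_VERSION
        f.attrs["model"] = state.model
        f.attrs["t"] = state.t
        f.attrs["n_x"] = state.grid.n_x
        f.attrs["n_y"] = state.grid.n_y
        f.attrs["h"] = state.grid.h
        if config is not None:
            f.attrs["config_json"] = json.dumps(config, sort_keys=True)
        grp = f.create_group("fields")
        for name in state._field_names():
            grp.create_dataset(name, data=getattr(state.cell, name))


def read_snapshot(path) -> TissueState:
    """Read a snapshot back; raises on unknown format versions."""
    with h5py.File(path, "r") as f:
        ver = int(f.attrs["format_version"])
        if ver != SNAPSHOT_FORMAT_VERSION:
            raise ValueError(
                f"snapshot format version {ver} != supported "
                f"{SNAPSHOT_FORMAT_VERSION}")
        grid = Grid(n_x=int(f.attrs["n_x"]), n_y=int(f.attrs["n_y"]),
                    h=float(f.attrs["h"]))
        model = str(f.attrs["model"])
        fields = {k: np.asarray(v) for k, v in f["fields"].items()}
        cell = BOCFState(**fields) if model == "bocf" else TNNPState(**fields)
        return TissueState(model=model, grid=grid, cell=cell,
                           t=float(f.attrs["t"]))


def write_series_csv(path, t: np.ndarray, counts: np.ndarray):
    """Spiral-count series as CSV with columns (t_seconds, n_spiral)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"t_seconds": np.asarray(t, dtype=float),
                  "n_spiral": np.asarray(counts, dtype=int)}
                 ).to_csv(path, index=False)


def read_series_csv(path) -> Tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return (df["t_seconds"].to_numpy(dtype=float),
            df["n_spiral"].to_numpy(dtype=int))


def write_results_json(path, results: Dict):
    """Analysis results (fits, statistics) as a versioned JSON document."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"format_version": 1, **results}
    path.write_text(json.dumps(doc, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


def read_results_json(path) -> Dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != 1:
        raise ValueError(f"results format version {doc.get('format_version')}"
                         " != supported 1")
    return doc


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
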