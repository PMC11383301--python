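"""File I/O: parameter YAML/JSON, tidy CSV time series, deterministic JSON."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import RateParameters, WellMixedTrajectory
from .spatial import FieldState

__all__ = [
    "load_rate_parameters",
    "dump_rate_parameters",
    "write_json",
    "timeseries_to_frame",
    "profile_to_frame",
    "config_hash",
]


def load_rate_parameters(path) -> RateParameters:
    """Read kinetic rates from a unit-annotated YAML/JSON mapping.

    Expected keys: k_on_per_um2_s, k_off_by_size_per_s (ordered list),
    k_ass_um2_s, k_diss_per_s, optional n_max.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
    koff = np.asarray(raw["k_off_by_size_per_s"], dtype=float)
    n_max = int(raw.get("n_max", max(len(koff), 50)))
    if len(koff) < n_max:
        koff = np.concatenate([koff, np.zeros(n_max - len(koff))])
    return RateParameters(k_on=float(raw["k_on_per_um2_s"]),
                          k_off_by_size=koff[:n_max],
                          k_ass=float(raw["k_ass_um2_s"]),
                          k_diss=float(raw["k_diss_per_s"]), n_max=n_max)


def dump_rate_parameters(params: RateParameters, path) -> None:
    data = {
        "k_on_per_um2_s": float(params.k_on),
        "k_off_by_size_per_s": [float(v) for v in params.k_off_by_size],
        "k_ass_um2_s": float(params.k_ass),
        "k_diss_per_s": float(params.k_diss),
        "n_max": int(params.n_max),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def write_json(data: dict, path) -> None:
    """Deterministic JSON: sorted keys, fixed float representation."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(data, fh, sort_keys=True, indent=2, default=default)
        fh.write("\n")


def timeseries_to_frame(traj: WellMixedTrajectory) -> pd.DataFrame:
    """Tidy (time, n, A_n) table from a well-mixed integration."""
    nmax = traj.A.shape[1]
    t = np.repeat(traj.t, nmax)
    n = np.tile(np.arange(1, nmax + 1), len(traj.t))
    return pd.DataFrame({"time_s": t, "n": n, "A_n": traj.A.ravel()})


def profile_to_frame(state: FieldState) -> pd.DataFrame:
    """Tidy (x, n, A_n) table from a spatial state."""
    nmax, nc = state.A.shape
    return pd.DataFrame({
        "x_um": np.tile(state.grid.x, nmax),
        "n": np.repeat(np.arange(1, nmax + 1), nc),
        "A_n": state.A.ravel(),
    })


def config_hash(config: dict) -> str:
    """Stable hash of a configuration mapping for run manifests."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
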