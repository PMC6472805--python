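"""Configuration files, run containers and snapshot export.

Configs are flat YAML key/value files mirroring the dataclass fields; unknown
keys are an error (typos should not silently fall back to defaults) and
parameters whose defaults are modeling assumptions are reported at warning
level when left unset.  Time series go into an HDF5 container
(/profiles, /stress, /events, /meta); network snapshots are written as node
CSVs plus an optional legacy-VTK polyline file for visualization.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .config import (
    ASSUMED_CONTINUUM_PARAMS,
    ASSUMED_SIM_PARAMS,
    ContinuumConfig,
    SimConfig,
)
from .network import FiberNetwork

logger = logging.getLogger("ecmdyn")


class ConfigError(ValueError):
    pass


def _load_into(cls, raw: dict, assumed: frozenset):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(raw) - fields)
    if unknown:
        raise ConfigError(f"unknown config keys for {cls.__name__}: {', '.join(unknown)}")
    missing_assumed = sorted(assumed - set(raw))
    if missing_assumed:
        logger.warning(
            "%s: using assumed defaults for: %s (no published baseline; see docs/methods.md)",
            cls.__name__,
            ", ".join(missing_assumed),
        )
    return cls(**raw)


def load_config(path, kind: str = "auto"):
    """Load a YAML config into a :class:`SimConfig` or :class:`ContinuumConfig`.

    ``kind`` is "network", "continuum", or "auto" (a ``model:`` key in the
    file, defaulting to network).  An empty file yields all defaults.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    model = raw.pop("model", None)
    if kind == "auto":
        kind = model or "network"
    if kind == "network":
        return _load_into(SimConfig, raw, ASSUMED_SIM_PARAMS)
    if kind == "continuum":
        return _load_into(ContinuumConfig, raw, ASSUMED_CONTINUUM_PARAMS)
    raise ConfigError(f"unknown config kind {kind!r}")


def save_config(config, path) -> None:
    raw = config.to_dict()
    raw["model"] = "continuum" if isinstance(config, ContinuumConfig) else "network"
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


# ----------------------------------------------------------------------
def network_to_csv(net: FiberNetwork, nodes_path, segments_path=None) -> None:
    """Tabular snapshot: node positions/flags and segment connectivity."""
    nodes = pd.DataFrame(
        {
            "node": np.arange(net.n_nodes),
            "x": net.positions[:, 0],
            "y": net.positions[:, 1],
            "z": net.positions[:, 2],
            "fixed": net.fixed.astype(int),
        }
    )
    nodes.to_csv(nodes_path, index=False)
    if segments_path is not None:
        segs = pd.DataFrame(
            {
                "segment": np.arange(net.n_segments),
                "node_a": net.seg_nodes[:, 0],
                "node_b": net.seg_nodes[:, 1],
                "fiber": net.seg_fiber,
                "rest_length": net.rest_length,
            }
        )
        segs.to_csv(segments_path, index=False)


def network_to_vtk(net: FiberNetwork, path) -> None:
    """Legacy-VTK (ASCII) polyline export of the fiber chains."""
    lines = [
        "# vtk DataFile Version 3.0",
        "ecmdyn fiber network snapshot",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {net.n_nodes} float",
    ]
    for p in net.positions:
        lines.append(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}")
    n_lines = len(net.fiber_nodes)
    size = sum(len(c) + 1 for c in net.fiber_nodes)
    lines.append(f"LINES {n_lines} {size}")
    for chain in net.fiber_nodes:
        lines.append(" ".join([str(len(chain))] + [str(int(i)) for i in chain]))
    lines.append(f"POINT_DATA {net.n_nodes}")
    lines.append("SCALARS fixed int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(int(f)) for f in net.fixed)
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
def save_timeseries(series, path) -> None:
    """Write a :class:`~ecmdyn.loading.NetworkTimeSeries` to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("profiles/t", data=series.t)
        f.create_dataset("profiles/bin_edges", data=series.bin_edges)
        f.create_dataset("profiles/values", data=series.profiles)
        f.create_dataset("stress/values", data=series.stress)
        f.attrs["stress_plane_z"] = series.stress_plane_z
        f.create_dataset("meta/bound_fraction", data=series.bound_fraction)
        f.create_dataset("meta/config_json", data=json.dumps(series.config))
        if series.events:
            ev = np.array(
                [(e.time, e.crosslink, e.tension) for e in series.events]
            )
            f.create_dataset("events/unbind", data=ev)


def load_timeseries(path):
    from .loading import NetworkTimeSeries

    with h5py.File(path, "r") as f:
        return NetworkTimeSeries(
            t=f["profiles/t"][:],
            bin_edges=f["profiles/bin_edges"][:],
            profiles=f["profiles/values"][:],
            stress=f["stress/values"][:],
            bound_fraction=f["meta/bound_fraction"][:],
            stress_plane_z=float(f.attrs["stress_plane_z"]),
            config=json.loads(f["meta/config_json"][()]),
        )


def events_to_csv(series, path) -> None:
    df = pd.DataFrame(
        [
            {"time": e.time, "crosslink": e.crosslink, "tension": e.tension}
            for e in series.events
        ]
    )
    df.to_csv(path, index=False)


# ----------------------------------------------------------------------
def write_manifest(out_dir, config, seed: int, outputs: list, started: float) -> Path:
    """RunManifest: config snapshot, seed, timings and produced files."""
    out_dir = Path(out_dir)
    manifest = {
        "config": config.to_dict(),
        "model": "continuum" if isinstance(config, ContinuumConfig) else "network",
        "seed": seed,
        "elapsed_s": time.time() - started,
        "outputs": [str(p) for p in outputs],
    }
    missing = [p for p in outputs if not Path(p).exists()]
    if missing:
        raise RuntimeError(f"manifest lists missing outputs: {missing}")
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
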