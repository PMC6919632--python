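"""File formats: cell tables (CSV/TSV), network JSON, results JSON, fixtures.

Cell tables are plain CSV/TSV with a header row of channel names and one
row per cell; an optional ``time`` column is split off into the snapshot
metadata.  Linear-space tables must be strictly positive (fluorescence
intensities); pass ``already_log=True`` for pre-transformed data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .generate import TOY_NETWORKS, toy_network
from .networks import ReactionNetwork
from .simulate import EnsembleSnapshot, integrate_ensemble, sample_initial_conditions

__all__ = [
    "RunConfig",
    "read_cell_table",
    "write_cell_table",
    "make_fixtures",
    "provenance",
    "write_json",
]


@dataclass
class RunConfig:
    """Pipeline run configuration, loadable from YAML or JSON.

    Referenced input paths are checked at validation time; seeds are
    carried into every provenance block.
    """

    inputs: list[str] = field(default_factory=list)
    seed: int = 0
    gap: str | int = "auto"  # "auto" or a fixed ESS dimension
    gmm_k: str | int = "auto"
    gmm_k_max: int = 4
    comparison_dimension: int = 10
    output_dir: str = "."

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix.lower() in {".yml", ".yaml"} else json.loads(text)
        cfg = cls(**data)
        missing = [p for p in cfg.inputs if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config references missing inputs: {missing}")
        return cfg


def read_cell_table(path: str | Path, already_log: bool = False) -> EnsembleSnapshot:
    """Read a CSV/TSV cell x channel table into a snapshot."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with open(path) as fh:  # pandas mangles duplicate headers, so check raw
        header = fh.readline().rstrip("\n").split(sep)
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate channel names {dupes}")
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty table")
    time = 0.0
    if "time" in df.columns:
        tcol = df.pop("time")
        time = float(tcol.iloc[0])
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric body ({exc})") from exc
    if np.any(~np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"{path}: non-finite value at row {bad[0]}, column {df.columns[bad[1]]}")
    if not already_log and np.any(values <= 0):
        bad = np.argwhere(values <= 0)[0]
        raise ValueError(
            f"{path}: nonpositive value at row {bad[0]}, column {df.columns[bad[1]]} "
            "(use already_log=True for log-transformed tables)"
        )
    return EnsembleSnapshot(values, list(df.columns), time=time, log_space=already_log)


def write_cell_table(snapshot: EnsembleSnapshot, path: str | Path, include_time: bool = False) -> None:
    snapshot.to_csv(path, include_time=include_time)


def provenance(seed: int | None = None, config: dict | None = None) -> dict:
    """Machine-readable provenance block written next to every CLI output."""
    blob = json.dumps(config or {}, sort_keys=True).encode()
    return {
        "esskit_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config or {},
    }


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return super().default(obj)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, cls=_NumpyEncoder))


def make_fixtures(output_dir: str | Path, seed: int = 0, n_cells: int = 300, t_final: float = 100.0) -> list[Path]:
    """Write every toy network as JSON plus a simulated snapshot for each.

    Snapshots use the default lognormal initial conditions (log-mean 4,
    log-variance 4) integrated to ``t_final``; reruns with the same seed
    are identical.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for i, name in enumerate(sorted(TOY_NETWORKS)):
        net = toy_network(name)
        net_path = out / f"{name}.json"
        net.to_json(net_path)
        written.append(net_path)
        init = sample_initial_conditions(net, n_cells, seed=seed + i)
        snap = integrate_ensemble(net, init, [t_final]).final()
        snap_path = out / f"{name}_snapshot.csv"
        snap.to_csv(snap_path, include_time=True)
        written.append(snap_path)
    write_json(provenance(seed=seed, config={"n_cells": n_cells, "t_final": t_final}), out / "provenance.json")
    written.append(out / "provenance.json")
    return written
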