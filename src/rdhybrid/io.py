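"""Plain-text output writers and the run configuration format.

All outputs are TSV/CSV plus a JSON metadata document, so runs can be
inspected and diffed without binary tooling.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .model import ReactionNetwork, network_from_dict
from .simulate import SimulationConfig, TrajectoryRecord


def _check_writable(path) -> None:
    d = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(d):
        raise FileNotFoundError(f"output directory {d} does not exist")
    if not os.access(d, os.W_OK):
        raise PermissionError(f"output directory {d} is not writable")


def timeseries_frame(record: TrajectoryRecord) -> pd.DataFrame:
    """Long-format table: time, per-species totals and per-region counts."""
    cols = {"time": record.times}
    for i, name in enumerate(record.species):
        cols[f"{name}_total"] = record.totals()[:, i]
        cols[f"{name}_population"] = record.population_totals[:, i]
        cols[f"{name}_particles"] = record.particle_totals[:, i]
        cols[f"{name}_nucleus"] = record.nucleus_pool[:, i]
        cols[f"{name}_membrane"] = record.membrane_pool[:, i]
    return pd.DataFrame(cols)


def histogram_frame(record: TrajectoryRecord, which: str = "radial") -> pd.DataFrame:
    edges = record.radial_edges if which == "radial" else record.x_edges
    hist = record.radial_hist if which == "radial" else record.x_hist
    rows = []
    for ti, t in enumerate(record.times):
        for bi in range(len(edges) - 1):
            row = {"time": t, "bin_lo": edges[bi], "bin_hi": edges[bi + 1]}
            for i, name in enumerate(record.species):
                row[name] = hist[ti, bi, i]
            rows.append(row)
    cols = ["time", "bin_lo", "bin_hi", *record.species]
    return pd.DataFrame(rows, columns=cols)


def write_outputs(record: TrajectoryRecord, out_dir: str, metadata: dict | None = None) -> dict:
    """Write time series, histograms and run metadata; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "timeseries": os.path.join(out_dir, "timeseries.tsv"),
        "radial": os.path.join(out_dir, "radial_hist.tsv"),
        "profile_x": os.path.join(out_dir, "x_profile.tsv"),
        "metadata": os.path.join(out_dir, "metadata.json"),
    }
    for p in paths.values():
        _check_writable(p)
    timeseries_frame(record).to_csv(paths["timeseries"], sep="\t", index=False)
    histogram_frame(record, "radial").to_csv(paths["radial"], sep="\t", index=False)
    histogram_frame(record, "x").to_csv(paths["profile_x"], sep="\t", index=False)
    meta = dict(metadata or {})
    if record.config is not None:
        cfg = asdict(record.config)
        cfg.pop("obstacles", None)
        meta["config"] = cfg
    meta["audit"] = record.audit[-1] if record.audit else {}
    meta["species"] = record.species
    with open(paths["metadata"], "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return paths


def read_timeseries(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_particle_snapshot(engine, path, t: float) -> None:
    """CSV snapshot (id, species, x, y, z, t) of all live particles."""
    _check_writable(path)
    live = np.flatnonzero(engine.alive)
    df = pd.DataFrame({
        "id": engine.ids[live],
        "species": [engine.network.species[i].name for i in engine.species[live]],
        "x": engine.pos[live, 0],
        "y": engine.pos[live, 1],
        "z": engine.pos[live, 2],
        "t": t,
    })
    df.to_csv(path, index=False)


# -- configuration files ------------------------------------------------------


def load_config(path) -> tuple[ReactionNetwork, SimulationConfig]:
    """Parse a YAML run description into a network and a SimulationConfig.

    Sections: ``species``, ``reactions`` (see the model schema),
    ``geometry`` (cell_diameter, nucleus_diameter, L), ``run`` (dt, t_end,
    seed, record_interval), ``modes`` and ``init``; see the README for a
    worked example.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    network = network_from_dict(doc)
    geo = doc.get("geometry", {})
    run = doc.get("run", {})
    if "seed" not in run:
        raise ValueError("config must set run.seed for reproducibility")
    mode = doc.get("modes", "population")
    if isinstance(mode, dict):
        (kind, names), = mode.items()
        mode = (kind, names)
    init = [(e["species"], int(e["count"]), e.get("where", "cytoplasm"))
            for e in doc.get("init", [])]
    ctrl = doc.get("controller", {})
    cfg = SimulationConfig(
        cell_diameter=float(geo.get("cell_diameter", 10.0)),
        nucleus_diameter=float(geo.get("nucleus_diameter", 0.0)),
        grid_l=int(geo.get("L", 10)),
        dt=float(run.get("dt", 2.6e-5)),
        t_end=float(run.get("t_end", 1.0)),
        seed=int(run["seed"]),
        mode=mode,
        init=init,
        record_interval=float(run.get("record_interval", 0.1)),
        controller_threshold=int(ctrl.get("threshold", 0)),
        controller_interval=int(ctrl.get("interval", 100)),
    )
    return network, cfg
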