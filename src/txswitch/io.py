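"""File I/O: time-series CSV, parameter/posterior JSON, config YAML."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import CellParams, SwitchFunction, TimeSeries

__all__ = ["read_timeseries_csv", "write_timeseries_csv", "params_to_dict",
           "params_from_dict", "save_truth", "save_store", "load_config"]


def write_timeseries_csv(path, data):
    """Write cells as CSV with columns cell_id, time_h, intensity."""
    rows = []
    for ts in data:
        rows.append(pd.DataFrame({"cell_id": ts.cell_id,
                                  "time_h": ts.times,
                                  "intensity": ts.values}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_timeseries_csv(path):
    df = pd.read_csv(path)
    need = {"cell_id", "time_h", "intensity"}
    if not need.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(need)}")
    out = []
    for cid, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("time_h")
        out.append(TimeSeries(g["time_h"].to_numpy(),
                              g["intensity"].to_numpy(), cell_id=str(cid)))
    return out


def params_to_dict(p: CellParams) -> dict:
    return {
        "switch_times": p.switch_fn.times.tolist(),
        "rates": p.switch_fn.rates.tolist(),
        "horizon": p.switch_fn.horizon,
        "alpha": p.alpha, "delta_m": p.delta_m, "delta_p": p.delta_p,
        "kappa": p.kappa, "sigma_eps": p.sigma_eps,
        "M0": p.M0, "P0": p.P0,
    }


def params_from_dict(d: dict) -> CellParams:
    fn = SwitchFunction(np.asarray(d["switch_times"], float),
                        np.asarray(d["rates"], float), d["horizon"])
    return CellParams(fn, alpha=d["alpha"], delta_m=d["delta_m"],
                      delta_p=d["delta_p"], kappa=d["kappa"],
                      sigma_eps=d["sigma_eps"], M0=d["M0"], P0=d["P0"])


def save_truth(path, truth: dict):
    """Sidecar JSON with the generating parameters (never read by fit)."""
    out = {"params": [params_to_dict(p) for p in truth["params"]],
           "grid": np.asarray(truth["grid"]).tolist()}
    Path(path).write_text(json.dumps(out, indent=1))


def save_store(prefix, store):
    """Posterior store as CSV files under a common prefix: fixed-dimension
    parameters and hyper-parameters wide, switch configurations long."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    for ci, cid in enumerate(store.cell_ids):
        df = pd.DataFrame(store.params[ci], columns=list(store.PARAM_NAMES))
        df.insert(0, "draw", np.arange(len(df)))
        df.insert(0, "k", store.k[ci])
        df.to_csv(f"{prefix}_params_{cid}.csv", index=False)
        rows = []
        for d, (s, lb) in enumerate(zip(store.switch_times[ci],
                                        store.log_rates[ci])):
            for j, t in enumerate(np.concatenate(([0.0], s))):
                rows.append((d, j, t, float(np.exp(lb[j]))))
        pd.DataFrame(rows, columns=["draw", "segment", "start_time_h",
                                    "rate"]).to_csv(
            f"{prefix}_switches_{cid}.csv", index=False)
    pd.DataFrame(store.hyper, columns=list(store.HYPER_NAMES)).to_csv(
        f"{prefix}_hyper.csv", index=False)


def write_trajectory_csv(path, traj):
    """Exact-trajectory export: one row per reaction (time, type, M, P)."""
    pd.DataFrame({"time_h": traj.times, "reaction_type": traj.types,
                  "M": traj.states[:, 0],
                  "P": traj.states[:, 1]}).to_csv(path, index=False)


def write_envelopes_csv(path, report):
    """Envelope-report export: (time, species, representation, lo, hi)."""
    rows = []
    for (rep, sp), (lo, hi) in report.envelopes.items():
        for t, a, b in zip(report.grid, lo, hi):
            rows.append((t, sp, rep, a, b))
    pd.DataFrame(rows, columns=["time_h", "species", "representation",
                                "lo", "hi"]).to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
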