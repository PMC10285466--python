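"""Run persistence: array archives per snapshot, CSV series, JSON manifest."""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grid_env import EnvironmentLandscape, GridSpec, ScalarField
from .solver import Snapshot, Trajectory

__all__ = ["save_run", "load_run"]


def _series_frame(traj: Trajectory) -> pd.DataFrame:
    from .metrics import tip_track

    track = tip_track(traj)
    return pd.DataFrame(
        {
            "time_h": track.times_h,
            "tip_x": track.x_px,
            "tip_y": track.y_px,
            "sum_phi": [s.sum_phi for s in traj.snapshots],
        }
    )


def save_run(traj: Trajectory, run_dir, config: dict | None = None) -> Path:
    """Write a trajectory to a run directory; returns the directory path."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    index = []
    for k, s in enumerate(traj.snapshots):
        fname = f"snapshot_{k:04d}.npz"
        arrays = {"phi": s.phi}
        if s.hydrogel is not None:
            arrays["hydrogel"] = s.hydrogel
        np.savez_compressed(run_dir / fname, **arrays)
        index.append(
            {
                "file": fname,
                "t_h": s.t_h,
                "t_insilico": s.t_insilico,
                "step_index": s.step_index,
                "sum_phi": s.sum_phi,
                "has_hydrogel": s.hydrogel is not None,
            }
        )
    np.savez_compressed(
        run_dir / "environment.npz",
        hydrogel=traj.env_initial.hydrogel.values,
        nu_c=traj.env_initial.nu_c.values,
        C0=traj.env_initial.C0.values,
    )
    _series_frame(traj).to_csv(run_dir / "series.csv", index=False)
    if traj.events:
        pd.DataFrame(traj.events).to_csv(run_dir / "events.csv", index=False)
    manifest = {
        "version": __version__,
        "saved_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "grid": {
            "nx": traj.grid.nx,
            "ny": traj.grid.ny,
            "dx_um": traj.grid.dx_um,
            "time_unit_h": traj.grid.time_unit_h,
            "dt": traj.grid.dt,
        },
        "env": {"gamma": traj.env_initial.gamma, "floor": traj.env_initial.floor},
        "config": config,
        "snapshots": index,
        "n_events": len(traj.events),
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return run_dir


def load_run(run_dir) -> tuple[Trajectory, dict]:
    """Load a run directory back into a Trajectory and its manifest."""
    run_dir = Path(run_dir)
    mpath = run_dir / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.json in {run_dir}")
    with open(mpath) as fh:
        manifest = json.load(fh)
    grid = GridSpec(**manifest["grid"])
    with np.load(run_dir / "environment.npz") as z:
        env = EnvironmentLandscape(
            ScalarField(z["hydrogel"], "hydrogel_density"),
            ScalarField(z["nu_c"], "nu_c"),
            gamma=manifest["env"]["gamma"],
            floor=manifest["env"]["floor"],
        )
    traj = Trajectory(grid=grid, env_initial=env)
    missing = [e["file"] for e in manifest["snapshots"] if not (run_dir / e["file"]).exists()]
    if missing:
        raise FileNotFoundError(f"run directory incomplete; missing {missing}")
    for entry in manifest["snapshots"]:
        with np.load(run_dir / entry["file"]) as z:
            phi = z["phi"]
            hydro = z["hydrogel"] if entry["has_hydrogel"] else None
        traj.snapshots.append(
            Snapshot(
                t_h=entry["t_h"],
                t_insilico=entry["t_insilico"],
                step_index=entry["step_index"],
                phi=phi,
                sum_phi=entry["sum_phi"],
                hydrogel=hydro,
            )
        )
    events_path = run_dir / "events.csv"
    if events_path.exists():
        traj.events = pd.read_csv(events_path).to_dict("records")
    return traj, manifest
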