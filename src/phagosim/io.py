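"""Configuration files, trajectory/metric output, VTK snapshots, manifests.

Config files are TOML with explicit unit suffixes in key names (the mix of
mN/m, nm/s and µm makes implicit units dangerous); tensions are converted to
the internal pN/µm system exactly once, at parse time.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .biphasic import ConstitutiveParams
from .errors import ConfigurationError, InputError
from .mesh import TAG_NAMES, Mesh
from .scenarios import ScenarioConfig, Trajectory, make_scenario
from .state import FieldState

_SCENARIO_KEYS = {f.name for f in dataclasses.fields(ScenarioConfig)}
_PARAM_KEYS = {f.name for f in dataclasses.fields(ConstitutiveParams)}


def load_config(path) -> tuple[ScenarioConfig, ConstitutiveParams]:
    """Read a TOML config with ``[scenario]`` and ``[parameters]`` tables.

    A ``preset`` key in the scenario table starts from the named preset;
    any other key overrides the corresponding field.  Unknown keys are
    rejected with the offending name.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    scen_tbl = dict(raw.pop("scenario", {}))
    par_tbl = dict(raw.pop("parameters", {}))
    if raw:
        raise ConfigurationError(f"unknown config table(s): {sorted(raw)}")

    preset = scen_tbl.pop("preset", None)
    if preset is not None:
        cfg = make_scenario(preset)
    else:
        cfg = ScenarioConfig()
    for key, val in scen_tbl.items():
        if key not in _SCENARIO_KEYS:
            raise ConfigurationError(f"unknown scenario key: {key!r}")
        cfg = dataclasses.replace(cfg, **{key: val})
    cfg.validate()

    params = ConstitutiveParams()
    for key, val in par_tbl.items():
        if key not in _PARAM_KEYS:
            raise ConfigurationError(f"unknown parameter key: {key!r}")
        params = dataclasses.replace(params, **{key: val})
    params.validate()
    return cfg, params


def dump_config(cfg: ScenarioConfig, params: ConstitutiveParams, path):
    """Emit a config file equivalent to the given objects (editable preset)."""
    lines = ["[scenario]"]
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, str):
            lines.append(f'{f.name} = "{v}"')
        elif isinstance(v, bool):
            lines.append(f"{f.name} = {str(v).lower()}")
        else:
            lines.append(f"{f.name} = {v!r}")
    lines.append("")
    lines.append("[parameters]")
    for f in dataclasses.fields(params):
        lines.append(f"{f.name} = {getattr(params, f.name)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

_TRAJ_COLUMNS = ["time_s", "position_um", "tension_mN_per_m", "engulfed_fraction"]


def write_trajectory_csv(traj, path):
    """Write a trajectory (or benchmark trace) as CSV at full float precision."""
    pos = getattr(traj, "target_position", None)
    if pos is None:
        pos = traj.position
    data = np.column_stack(
        [
            np.asarray(traj.time, float),
            np.asarray(pos, float),
            np.asarray(traj.tension, float),
            np.asarray(traj.engulfed_fraction, float),
        ]
    )
    np.savetxt(
        path, data, fmt="%.17g", delimiter=",",
        header=",".join(_TRAJ_COLUMNS), comments="",
    )


def read_trajectory_csv(path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"trajectory file missing columns: {missing}")
    return Trajectory(
        time=df["time_s"].to_numpy(),
        target_position=df["position_um"].to_numpy(),
        tension=df["tension_mN_per_m"].to_numpy(),
        engulfed_fraction=df["engulfed_fraction"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# VTK snapshots
# ---------------------------------------------------------------------------

def write_vtk_snapshot(mesh: Mesh, state: FieldState, path, viscosity=None):
    """Legacy ASCII VTK unstructured grid: theta/messenger/viscosity as cell
    data, velocities and pressure as point data.

    (Pressure is piecewise-constant in the discretization but emitted per
    point for viewer convenience, averaged from adjacent cells; the exact
    element values are in the cell-data block.)
    """
    quads = mesh.quads
    n, m = mesh.n_nodes, mesh.n_elements
    lines = [
        "# vtk DataFile Version 3.0",
        "phagosim axisymmetric cell snapshot (r z 0)",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    for r, z in mesh.coords:
        lines.append(f"{r:.10g} {z:.10g} 0")
    lines.append(f"CELLS {m} {5 * m}")
    for q in quads:
        lines.append("4 " + " ".join(str(i) for i in q))
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["9"] * m)   # VTK_QUAD

    lines.append(f"CELL_DATA {m}")
    for name, arr in (
        ("theta", state.theta),
        ("messenger_cell", np.mean(state.messenger[quads], axis=1)),
        ("viscosity", viscosity if viscosity is not None else np.zeros(m)),
        ("pressure_cell", state.pressure),
    ):
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.10g}" for v in np.asarray(arr, float))

    lines.append(f"POINT_DATA {n}")
    for name, arr in (
        ("v_network", state.v_network),
        ("v_solvent", state.v_solvent),
    ):
        lines.append(f"VECTORS {name} double")
        lines.extend(f"{vr:.10g} {vz:.10g} 0" for vr, vz in np.asarray(arr, float))
    p_nodal = np.zeros(n)
    counts = np.zeros(n)
    np.add.at(p_nodal, quads.ravel(), np.repeat(state.pressure, 4))
    np.add.at(counts, quads.ravel(), 1.0)
    p_nodal /= np.maximum(counts, 1.0)
    lines.append("SCALARS pressure double 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(f"{v:.10g}" for v in p_nodal)

    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(path, scenario: ScenarioConfig, params: ConstitutiveParams,
                   outputs: list[str], seed: int | None = None) -> dict:
    """Write a JSON run manifest (config hash, code version, outputs) before
    the run starts; rerunning a manifest reproduces its outputs."""
    from . import __version__

    blob = json.dumps(
        {"scenario": dataclasses.asdict(scenario), "parameters": dataclasses.asdict(params)},
        sort_keys=True,
    )
    manifest = {
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "code_version": __version__,
        "scenario": scenario.name,
        "resolution": scenario.resolution,
        "seed": scenario.seed if seed is None else seed,
        "outputs": list(outputs),
        "wall_start": datetime.now(timezone.utc).isoformat(),
        "config": json.loads(blob),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
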