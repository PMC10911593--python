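"""Tidy tabular writers for outcomes, sweeps, and trajectories.

Every writer emits a plain CSV whose data rows are a pure function of the
inputs (re-running a fixture reproduces them byte for byte) plus an optional
JSON mirror.  A header comment block records the package version, the
scenario content hash, and the tolerances in force, so results remain
auditable without the original shell session.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

import wolbnet
from wolbnet.dynamics import OutcomeRecord, Trajectory
from wolbnet.experiments import BasinBoundary, SweepResult

__all__ = [
    "outcome_frame",
    "sweep_frame",
    "trajectory_frame",
    "basin_frame",
    "write_results",
]


def _header(scenario_hash: str | None, extra: dict | None = None) -> str:
    meta = {"package": f"wolbnet {wolbnet.__version__}"}
    if scenario_hash:
        meta["scenario_hash"] = scenario_hash
    if extra:
        meta.update(extra)
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def outcome_frame(record: OutcomeRecord, compartments_per_habitat: int | None = None) -> pd.DataFrame:
    """One row per habitat: label, carrier proportion, terminal populations."""
    n = len(record.labels)
    state = np.asarray(record.steady, dtype=float)
    width = state.size // n if compartments_per_habitat is None else compartments_per_habitat
    rows = []
    for j in range(n):
        row = {"habitat": j, "label": record.labels[j], "proportion": record.proportions[j],
               "horizon": record.horizon, "converged": record.converged}
        if width == 2:  # two-compartment layout is [x..., y...]
            row["x_star"] = state[j]
            row["y_star"] = state[n + j]
        else:
            for k in range(width):
                row[f"c{k}_star"] = state[width * j + k]
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_frame(result: SweepResult) -> pd.DataFrame:
    """Long-format sweep table keyed by (parameter value, habitat)."""
    rows = []
    n = len(result.outcomes[0].labels)
    for val, rec in zip(result.grid, result.outcomes):
        state = np.asarray(rec.steady, dtype=float)
        for j in range(n):
            rows.append({
                result.parameter: val, "habitat": j, "label": rec.labels[j],
                "proportion": rec.proportions[j],
                "x_star": state[j], "y_star": state[n + j],
            })
    return pd.DataFrame(rows)


def trajectory_frame(traj: Trajectory, n_habitats: int, compartments: tuple[str, ...]) -> pd.DataFrame:
    """Tidy (time, habitat, compartment, value) table of a trajectory.

    For the two-compartment models pass ``compartments=("x", "y")`` — the
    flat layout groups by compartment first.  For the nine-compartment model
    the layout groups by habitat first.
    """
    rows = []
    width = len(compartments)
    for it, t in enumerate(traj.t):
        state = traj.states[:, it]
        for j in range(n_habitats):
            for k, name in enumerate(compartments):
                if width == 2:
                    value = state[k * n_habitats + j]
                else:
                    value = state[width * j + k]
                rows.append({"time": t, "habitat": j, "compartment": name, "value": value})
    return pd.DataFrame(rows)


def basin_frame(boundary: BasinBoundary) -> pd.DataFrame:
    return pd.DataFrame({"x_A": boundary.x_A, "x_B_boundary": boundary.x_B_boundary})


def write_results(
    frame: pd.DataFrame,
    path,
    fmt: str = "csv",
    scenario_hash: str | None = None,
    extra_meta: dict | None = None,
) -> Path:
    """Write a result table as commented CSV (default) or JSON mirror."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(_header(scenario_hash, extra_meta))
            frame.to_csv(fh, index=False)
    elif fmt == "json":
        payload = {"meta": {"package": f"wolbnet {wolbnet.__version__}",
                            "scenario_hash": scenario_hash, **(extra_meta or {})},
                   "rows": json.loads(frame.to_json(orient="records"))}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
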