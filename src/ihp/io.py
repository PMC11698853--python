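"""Plain-text serialization: configs, Q tables, diagrams, trajectories.

Everything is written as inspectable CSV/YAML/JSON at full double
precision, so write-then-read round-trips are lossless and any run can be
reproduced bitwise from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diagram import N_STATES, DecisionDiagram
from .models import IHPTrajectory
from .params import BathParams, PotentialParams, TheoryParams, TrainConfig

_SECTIONS = {
    "bath": BathParams,
    "train": TrainConfig,
    "potential": PotentialParams,
    "theory": TheoryParams,
}


def load_config(path: str | Path) -> tuple[BathParams, TrainConfig, PotentialParams, TheoryParams]:
    """Read a YAML config with optional sections ``bath``, ``train``,
    ``potential`` and ``theory``; missing keys fall back to the package
    defaults, unknown sections or keys raise a descriptive error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping of sections")
    for section in raw:
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section {section!r}")
    built = {}
    for section, cls in _SECTIONS.items():
        entries = raw.get(section) or {}
        if not isinstance(entries, dict):
            raise ValueError(f"section {section!r} must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        for key in entries:
            if key not in valid:
                raise ValueError(f"unknown key {key!r} in section {section!r}")
        built[section] = cls(**entries)
    return built["bath"], built["train"], built["potential"], built["theory"]


def save_qmatrix(path: str | Path, q: np.ndarray) -> None:
    pd.DataFrame(q, columns=["no_go", "go"]).to_csv(path, index=False, float_format="%.17g")


def load_qmatrix(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["no_go", "go"] or len(df) != N_STATES:
        raise ValueError("not a Q-matrix file (need 360 rows: no_go, go)")
    return df.to_numpy(dtype=float)


def save_diagram(path: str | Path, diagram: DecisionDiagram) -> None:
    """Write the per-bin table as CSV and the arc summary next to it as
    ``<path>.json``."""
    path = Path(path)
    pd.DataFrame(
        {
            "state": np.arange(1, N_STATES + 1),
            "h_go": diagram.go_probability,
            "go": diagram.go_mask.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.17g")
    summary = {
        "anticipation_angle": diagram.anticipation_angle,
        "go_angle": diagram.go_angle,
        "n_cycles_aggregated": diagram.n_cycles_aggregated,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(summary, indent=2))


def load_diagram(path: str | Path) -> DecisionDiagram:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    summary = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return DecisionDiagram(
        go_mask=df["go"].to_numpy(bool),
        go_probability=df["h_go"].to_numpy(float),
        anticipation_angle=float(summary["anticipation_angle"]),
        go_angle=float(summary["go_angle"]),
        n_cycles_aggregated=int(summary["n_cycles_aggregated"]),
    )


def save_bath_state(path: str | Path, state, time: float | None = None) -> None:
    """Columnar snapshot of a bath configuration (time, id, x, y, phi)."""
    t = state.time if time is None else time
    pd.DataFrame(
        {
            "time": np.full(state.n_particles, t),
            "id": np.arange(state.n_particles),
            "x": state.positions[:, 0],
            "y": state.positions[:, 1],
            "phi": state.angles,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def load_bath_state(path: str | Path):
    from .bath import BathState

    df = pd.read_csv(path, float_precision="round_trip")
    time = float(df["time"].iloc[0]) if len(df) else 0.0
    return BathState(
        positions=df[["x", "y"]].to_numpy(float),
        angles=df["phi"].to_numpy(float),
        time=time,
    )


def save_trajectory(path: str | Path, traj: IHPTrajectory) -> None:
    pd.DataFrame(
        {"time": traj.times, "x": traj.positions[:, 0], "y": traj.positions[:, 1]}
    ).to_csv(path, index=False, float_format="%.17g")


def load_trajectory(path: str | Path) -> IHPTrajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    return IHPTrajectory(
        times=df["time"].to_numpy(float),
        positions=df[["x", "y"]].to_numpy(float),
    )


def save_msd(path: str | Path, times: np.ndarray, values: np.ndarray, stderr: np.ndarray | None = None) -> None:
    data = {"time": times, "msd": values}
    if stderr is not None:
        data["stderr"] = stderr
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def write_manifest(path: str | Path, *, seed: int, command: str, parameters: dict) -> None:
    """Record everything needed to reproduce a run bitwise."""
    from . import __version__

    def _clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    manifest = {
        "command": command,
        "seed": seed,
        "parameters": _clean(parameters),
        "version": __version__,
        "created": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
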