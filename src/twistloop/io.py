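"""Configuration schema, trajectory/observable/contact-map readers and writers.

Formats are plain text throughout: YAML configs with per-module sections,
extended-XYZ trajectory frames with per-bead role labels (F fibre, P phantom
fibre, C cohesin, X CTCF), TSV observables tables, and whitespace-delimited
dense matrices for contact maps. Every run can write a manifest (config +
seed + package version) sufficient to reproduce the trajectory.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import DynamicsConfig, Trajectory
from .forcefield import ForceFieldParams
from .scenarios import Scenario, make_scenario
from .units import UnitSystem

__all__ = [
    "RunConfig",
    "parse_config",
    "serialize_config",
    "write_config",
    "write_trajectory",
    "read_trajectory",
    "write_contact_map",
    "read_contact_map",
    "write_manifest",
]

_COORD_FMT = "%.6f"  # 1e-6 sigma; topology measures are insensitive below this


@dataclasses.dataclass
class RunConfig:
    """Validated run description: scenario + force field + dynamics."""

    scenario: Scenario
    forcefield: ForceFieldParams
    dynamics: DynamicsConfig
    units: UnitSystem

    def __eq__(self, other) -> bool:
        return serialize_config(self) == serialize_config(other)


_SECTION_FIELDS = {
    "units": {f.name for f in dataclasses.fields(UnitSystem)},
    "forcefield": {f.name for f in dataclasses.fields(ForceFieldParams)} - {"units"},
    "dynamics": {f.name for f in dataclasses.fields(DynamicsConfig)},
    "scenario": {f.name for f in dataclasses.fields(Scenario)} | {"name"},
}


def parse_config(path: str | Path | None = None, text: str | None = None) -> RunConfig:
    """Parse and validate a YAML run config; defaults fill missing keys.

    Unknown sections or keys are rejected with the offending name; range
    violations surface as the underlying constructor errors naming the key.
    """
    if text is None:
        text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping of sections")
    unknown = set(raw) - set(_SECTION_FIELDS)
    if unknown:
        raise ValueError(f"unknown config section(s): {', '.join(sorted(unknown))}")
    for section, keys in _SECTION_FIELDS.items():
        extra = set(raw.get(section, {}) or {}) - keys
        if extra:
            raise ValueError(
                f"unknown key(s) in [{section}]: {', '.join(sorted(extra))}"
            )

    units = UnitSystem(**(raw.get("units") or {}))
    try:
        ff = ForceFieldParams(units=units, **(raw.get("forcefield") or {}))
    except (TypeError, ValueError) as e:
        raise ValueError(f"forcefield config invalid: {e}") from e
    try:
        dyn = DynamicsConfig(**(raw.get("dynamics") or {}))
    except (TypeError, ValueError) as e:
        raise ValueError(f"dynamics config invalid: {e}") from e

    sc_raw = dict(raw.get("scenario") or {})
    name = sc_raw.pop("name", "fig1")
    n_beads = sc_raw.pop("n_beads", 300)
    scenario = make_scenario(name, n_beads=n_beads, **sc_raw)
    return RunConfig(scenario=scenario, forcefield=ff, dynamics=dyn, units=units)


def serialize_config(cfg: RunConfig) -> str:
    """YAML text that :func:`parse_config` round-trips exactly."""
    d = {
        "units": dataclasses.asdict(cfg.units),
        "forcefield": {
            k: v for k, v in dataclasses.asdict(cfg.forcefield).items() if k != "units"
        },
        "dynamics": dataclasses.asdict(cfg.dynamics),
        "scenario": cfg.scenario.to_dict(),
    }
    return yaml.safe_dump(d, sort_keys=True)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(serialize_config(cfg))


def write_manifest(cfg: RunConfig, seed: int, path: str | Path) -> None:
    """Reproducibility manifest: config, seed and code version."""
    Path(path).write_text(
        serialize_config(cfg) + yaml.safe_dump({"seed": seed, "version": __version__})
    )


# -- trajectories -----------------------------------------------------------


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Extended-XYZ frames plus a sidecar ``<path>.obs.tsv`` observables table."""
    path = Path(path)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            pos = traj.positions[f]
            fh.write(f"{len(pos)}\n")
            fh.write(
                f'time={traj.times[f]:.6f} circular={traj.circular} n_fiber={traj.n_fiber} '
                f'Properties=species:S:1:pos:R:3\n'
            )
            for role, (x, y, z) in zip(traj.roles, pos):
                fh.write(f"{role} {x:.6f} {y:.6f} {z:.6f}\n")
    if traj.observables is not None:
        traj.observables.to_csv(path.with_suffix(path.suffix + ".obs.tsv"),
                                sep="\t", index=False)


def read_trajectory(path: str | Path) -> Trajectory:
    """Read frames written by :func:`write_trajectory`; detects truncation."""
    path = Path(path)
    traj = Trajectory()
    lines = path.read_text().splitlines()
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i])
        except ValueError as e:
            raise IOError(f"corrupt trajectory at frame {frame}: bad atom count") from e
        if i + 1 + nat >= len(lines) + 1:
            raise IOError(f"corrupt trajectory: frame {frame} truncated")
        header = dict(
            kv.split("=", 1) for kv in lines[i + 1].split() if "=" in kv
        )
        pos = np.empty((nat, 3))
        roles = np.empty(nat, dtype="<U1")
        for k in range(nat):
            parts = lines[i + 2 + k].split()
            if len(parts) != 4:
                raise IOError(f"corrupt trajectory: frame {frame}, atom {k}")
            roles[k] = parts[0]
            pos[k] = [float(v) for v in parts[1:]]
        traj.times.append(float(header.get("time", frame)))
        traj.positions.append(pos)
        traj.roles = roles
        traj.circular = header.get("circular", "True") == "True"
        traj.n_fiber = int(header.get("n_fiber", nat))
        i += 2 + nat
        frame += 1
    obs = path.with_suffix(path.suffix + ".obs.tsv")
    if obs.exists():
        traj.observables = pd.read_csv(obs, sep="\t")
    return traj


# -- contact maps -----------------------------------------------------------


def write_contact_map(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, matrix, fmt="%.6f")


def read_contact_map(path: str | Path) -> np.ndarray:
    m = np.loadtxt(path)
    return np.atleast_2d(m)
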