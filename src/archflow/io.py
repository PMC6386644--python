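"""File formats and pipeline configuration.

Waveforms travel as CSV with header ``time_s,flow_L_per_min`` (clinical
units at the boundary, SI inside). Meshes travel as STL with per-face
pressure/shear fields in a sidecar CSV ``face_index,pressure_Pa,
shear_x_Pa,shear_y_Pa,shear_z_Pa`` whose row order equals the STL facet
order (STL carries no attributes). Configuration is strict-schema YAML:
unknown keys are rejected, defaults are explicit, and a config
round-trips through write-then-read identically. Output files embed the
config hash and seed in a comment header so every run is attributable.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import units
from .force import ForceVector, classify_direction, graft_surface_area
from .meshes import MeshError, TriSurface
from .waveform import FlowWaveform, InvalidWaveformError

__all__ = [
    "FormatError",
    "ConfigError",
    "DEFAULT_CONFIG",
    "read_waveform_csv",
    "write_waveform_csv",
    "read_mesh_with_fields",
    "write_mesh_with_fields",
    "load_config",
    "save_config",
    "validate_config",
    "config_hash",
    "force_report",
    "write_force_report",
]

WAVEFORM_HEADER = "time_s,flow_L_per_min"
FIELD_COLUMNS = ["face_index", "pressure_Pa", "shear_x_Pa", "shear_y_Pa", "shear_z_Pa"]


class FormatError(ValueError):
    """Raised for malformed input files; carries the offending line."""


class ConfigError(ValueError):
    """Raised for configs violating the schema."""


# -- waveform CSV -------------------------------------------------------


def write_waveform_csv(w: FlowWaveform, path: str | Path, comment: str | None = None) -> None:
    path = Path(path)
    lines = []
    if comment:
        lines.append(f"# {comment}")
    lines.append(WAVEFORM_HEADER)
    for t, q in zip(w.times, w.flows_l_min):
        lines.append(f"{float(t)!r},{float(q)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_waveform_csv(path: str | Path) -> FlowWaveform:
    """Parse one closed cycle of flow; errors name the offending line."""
    path = Path(path)
    raw = path.read_text().splitlines()
    rows: list[tuple[float, float]] = []
    header_seen = False
    for lineno, line in enumerate(raw, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if not header_seen:
            if stripped != WAVEFORM_HEADER:
                raise FormatError(
                    f"{path}:{lineno}: expected header {WAVEFORM_HEADER!r}, got {stripped!r}"
                )
            header_seen = True
            continue
        parts = stripped.split(",")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            t, q = float(parts[0]), float(parts[1])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric value in {stripped!r}")
        if rows and t <= rows[-1][0]:
            raise FormatError(
                f"{path}:{lineno}: time {t} not increasing (previous {rows[-1][0]})"
            )
        rows.append((t, q))
    if not header_seen:
        raise FormatError(f"{path}: missing header {WAVEFORM_HEADER!r}")
    if len(rows) < 32:
        raise FormatError(f"{path}: waveform needs >= 32 rows, found {len(rows)}")
    times = np.array([r[0] for r in rows])
    flows = np.array([r[1] for r in rows]) * units.L_PER_MIN_TO_M3_S
    try:
        return FlowWaveform(times, flows, period=float(times[-1]))
    except InvalidWaveformError as exc:
        raise FormatError(f"{path}: {exc}")


# -- mesh + per-face fields ---------------------------------------------


def write_mesh_with_fields(
    mesh: TriSurface, stl_path: str | Path, field_csv_path: str | Path,
    binary: bool = False, comment: str | None = None,
) -> None:
    import trimesh

    if mesh.face_pressure is None or mesh.face_shear is None:
        raise MeshError("mesh has no fields to write")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(stl_path), file_type="stl" if binary else "stl_ascii")
    df = pd.DataFrame(
        {
            "face_index": np.arange(len(mesh.faces)),
            "pressure_Pa": mesh.face_pressure,
            "shear_x_Pa": mesh.face_shear[:, 0],
            "shear_y_Pa": mesh.face_shear[:, 1],
            "shear_z_Pa": mesh.face_shear[:, 2],
        }
    )
    with open(field_csv_path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, index=False)


def read_mesh_with_fields(stl_path: str | Path, field_csv_path: str | Path) -> TriSurface:
    """Load STL geometry plus sidecar fields; row order = facet order."""
    import trimesh

    tm = trimesh.load(str(stl_path), file_type="stl", process=False)
    df = pd.read_csv(field_csv_path, comment="#")
    if list(df.columns) != FIELD_COLUMNS:
        raise FormatError(
            f"{field_csv_path}: expected columns {FIELD_COLUMNS}, got {list(df.columns)}"
        )
    if len(df) != len(tm.faces):
        raise FormatError(
            f"field/facet count mismatch: {len(df)} field rows vs {len(tm.faces)} STL facets"
        )
    df = df.sort_values("face_index")
    shear = df[["shear_x_Pa", "shear_y_Pa", "shear_z_Pa"]].to_numpy()
    return TriSurface(
        np.asarray(tm.vertices), np.asarray(tm.faces),
        face_pressure=df["pressure_Pa"].to_numpy(), face_shear=shear,
    )


# -- configuration ------------------------------------------------------

DEFAULT_CONFIG: dict[str, Any] = {
    "schema": 1,
    "seed": 0,
    "units": {"flow": "L/min", "pressure": "mmHg", "velocity": "cm/s", "area": "cm2"},
    "windkessel": {
        "prox_fraction": 0.09,
        "c_bracket": [1e-3, 10.0],
        "pp_tol_mmhg": 0.25,
        "steps_per_cycle": 1000,
        "n_cycles": 6,
    },
    "network": {
        "topology": "pre_tevar",
        "bypass_resistance": 0.0,
        "profile_factor": 2.0,
        "outlets": [],
    },
    "force": {"peak": "pressure", "frame": {"ventral": "+x", "left": "+y", "cranial": "+z"}},
    "stats": {"rounding": "half_away_from_zero", "percent_from_printed_means": True},
}


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    """Fill defaults and reject unknown keys; returns a new dict."""

    def merge(defaults: dict, given: dict, crumb: str) -> dict:
        unknown = set(given) - set(defaults)
        if unknown:
            raise ConfigError(f"unknown config key(s) at {crumb or 'top level'}: {sorted(unknown)}")
        out = {}
        for key, default in defaults.items():
            if key not in given:
                out[key] = copy.deepcopy(default)
            elif isinstance(default, dict) and key != "outlets":
                if not isinstance(given[key], dict):
                    raise ConfigError(f"{crumb}{key} must be a mapping")
                out[key] = merge(default, given[key], f"{crumb}{key}.")
            else:
                out[key] = copy.deepcopy(given[key])
        return out

    merged = merge(DEFAULT_CONFIG, config, "")
    if merged["schema"] != 1:
        raise ConfigError(f"unsupported schema version {merged['schema']}")
    return merged


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return validate_config(raw)


def save_config(config: dict[str, Any], path: str | Path) -> None:
    validate_config(config)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def config_hash(config: dict[str, Any]) -> str:
    """Stable short hash of the canonical config serialization."""
    canonical = yaml.safe_dump(validate_config(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


# -- structured reports -------------------------------------------------


def force_report(mesh: TriSurface, force: ForceVector) -> dict[str, Any]:
    label, boundary = classify_direction(force)
    return {
        "components_N": [float(v) for v in force.components],
        "magnitude_N": force.magnitude,
        "pressure_part_N": [float(v) for v in force.pressure_part],
        "shear_part_N": [float(v) for v in force.shear_part],
        "direction": label,
        "direction_boundary_case": boundary,
        "surface_area_cm2": graft_surface_area(mesh),
    }


def write_force_report(report: dict[str, Any], path: str | Path, meta: dict | None = None) -> None:
    payload = dict(report)
    if meta:
        payload["meta"] = meta
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
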