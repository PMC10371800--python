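"""Configuration loading with explicit units, and result writers.

Configs are YAML or JSON.  Every dimensional quantity may be given either as
a bare number (already in canonical internal units) or as a string with a
unit suffix, e.g. ``"1 L/min"`` or ``"250 mmol/L"``.  Canonical internal
units are hours, litres, mmol/L, L/h and 1e9 cells/L; the single conversion
applied at the I/O boundary is minutes-based flow to hours (x60).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .control import ControlConfig
from .kinetics import KineticParameters
from .twin import FeedPolicy, ReactorState

log = logging.getLogger("fedflux")

__all__ = [
    "UnitError",
    "parse_quantity",
    "load_config_file",
    "load_twin_config",
    "load_policy",
    "load_control_config",
    "dump_policy",
    "write_trajectory",
    "write_manifest",
]

#: accepted unit -> (canonical unit, multiplicative factor)
_UNIT_TABLE: dict[str, tuple[str, float]] = {
    "h": ("h", 1.0),
    "hour": ("h", 1.0),
    "hours": ("h", 1.0),
    "L": ("L", 1.0),
    "mmol/L": ("mmol/L", 1.0),
    "mM": ("mmol/L", 1.0),
    "L/h": ("L/h", 1.0),
    "L/min": ("L/h", 60.0),
    "mmol/min": ("mmol/h", 60.0),
    "mmol/h": ("mmol/h", 1.0),
    "1e9cells/L": ("1e9cells/L", 1.0),
    "mg/L": ("mg/L", 1.0),
    "1/h": ("1/h", 1.0),
    "h^-1": ("1/h", 1.0),
}


class UnitError(ValueError):
    """An unknown unit key in a config; the message names the key."""


def parse_quantity(value) -> float:
    """Resolve a config value to canonical units.

    Bare numbers pass through; strings like ``"0.05 L/min"`` are converted.
    """
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        parts = value.split()
        if len(parts) != 2:
            raise UnitError(f"cannot parse quantity {value!r}; expected 'NUMBER UNIT'")
        num, unit = parts
        if unit not in _UNIT_TABLE:
            raise UnitError(f"unknown unit {unit!r} in {value!r}")
        _, factor = _UNIT_TABLE[unit]
        out = float(num) * factor
        if factor != 1.0:
            log.info("converted %s -> %g (canonical units)", value, out)
        return out
    raise UnitError(f"cannot parse quantity of type {type(value).__name__}")


def load_config_file(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)


def _resolve(obj):
    """Recursively resolve quantities in a config tree."""
    if isinstance(obj, dict):
        return {k: _resolve(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_resolve(v) for v in obj]
    if isinstance(obj, str) and any(ch.isdigit() for ch in obj) and " " in obj:
        return parse_quantity(obj)
    return obj


def load_twin_config(path: str | Path) -> tuple[KineticParameters, ReactorState, dict]:
    """Read kinetic parameters, initial state and feed concentrations."""
    raw = load_config_file(path)
    raw.pop("units", None)  # descriptive annotations, not quantities
    raw = _resolve(raw)
    pdata = {
        k: (float(v) if isinstance(v, str) and v in {"inf", "Infinity"} else v)
        for k, v in raw.get("parameters", {}).items()
    }
    fields = {f.name for f in dataclasses.fields(KineticParameters)}
    unknown = set(pdata) - fields
    if unknown:
        raise ValueError(f"unknown kinetic parameters: {sorted(unknown)}")
    p = KineticParameters(**pdata)
    p.validate()
    s = raw["initial_state"]
    x0 = ReactorState(
        t=float(s.get("t", 0.0)),
        V=float(s["V"]),
        Xv=float(s["Xv"]),
        Xd=float(s.get("Xd", 0.0)),
        C={k: float(v) for k, v in s["C"].items()},
        P=float(s.get("P", 0.0)),
    )
    x0.validate()
    feed = {k: float(v) for k, v in raw.get("feed_concentrations", {}).items()}
    return p, x0, feed


def load_policy(path: str | Path, feed_other: dict | None = None) -> FeedPolicy:
    raw = _resolve(load_config_file(path))
    return FeedPolicy(
        knots=np.asarray(raw["knots_h"], dtype=float),
        F_in=np.asarray(raw["F_in_L_per_h"], dtype=float),
        F_out=np.asarray(raw["F_out_L_per_h"], dtype=float),
        C_feed_glc=np.asarray(raw["C_feed_glc_mmol_per_L"], dtype=float),
        C_feed_other=dict(raw.get("C_feed_other_mmol_per_L", feed_other or {})),
    )


def dump_policy(policy: FeedPolicy, path: str | Path) -> None:
    data = {
        "knots_h": policy.knots.tolist(),
        "F_in_L_per_h": policy.F_in.tolist(),
        "F_out_L_per_h": policy.F_out.tolist(),
        "C_feed_glc_mmol_per_L": policy.C_feed_glc.tolist(),
        "C_feed_other_mmol_per_L": policy.C_feed_other,
    }
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def load_control_config(path: str | Path) -> ControlConfig:
    raw = _resolve(load_config_file(path))
    cfg = ControlConfig()
    u_bounds = dict(cfg.u_bounds)
    for key, val in raw.pop("u_bounds", {}).items():
        u_bounds[key] = (parse_quantity(val[0]), parse_quantity(val[1]))
    known = {f.name for f in dataclasses.fields(ControlConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown control config keys: {sorted(unknown)}")
    for key, val in raw.items():
        if key == "v_cap_schedule" and val is not None:
            val = (np.asarray(val[0], float), np.asarray(val[1], float))
        if key == "v_bounds" and val is not None:
            val = (float(val[0]), float(val[1]))
        setattr(cfg, key, val)
    cfg.u_bounds = u_bounds
    cfg.validate()
    return cfg


def write_trajectory(traj, out_dir: str | Path, stem: str = "trajectory") -> None:
    """Wide and tidy CSVs of a simulation trajectory plus a totals JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wide = traj.to_frame()
    wide.to_csv(out_dir / f"{stem}_wide.csv", index=False)
    tidy = wide.melt(id_vars=["t"], var_name="variable", value_name="value")
    tidy.to_csv(out_dir / f"{stem}_tidy.csv", index=False)
    totals = {
        "total_glucose_fed_mmol": traj.total_glucose_fed,
        "final_antibody_mass_mg": traj.final_antibody_mass,
        "ivcd_1e9cells_h_per_L": traj.ivcd,
        "final_volume_L": traj.final_state.V,
    }
    (out_dir / f"{stem}_totals.json").write_text(
        json.dumps(totals, indent=2, sort_keys=True) + "\n"
    )


def write_manifest(out_dir: str | Path, seed: int, config_paths: dict) -> None:
    """Run manifest: config hashes, seed and package version."""
    from . import __version__

    digest = {}
    for name, p in config_paths.items():
        p = Path(p)
        if p.exists():
            digest[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    manifest = {"seed": seed, "version": __version__, "config_sha256": digest}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
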