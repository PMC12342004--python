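"""File formats and run bookkeeping: concentration tables (CSV), YAML
configuration, JSON results, and per-run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import SimulationResult, LOSARTAN_POTASSIUM_G_PER_MOL

__all__ = [
    "FormatError",
    "ObservedTable",
    "read_concentration_table",
    "write_concentration_table",
    "default_config",
    "load_config",
    "config_hash",
    "RunManifest",
]

TIME_COL = "time_h"
CP_COL = "Cp_nM"
CM_COL = "Cm_nM"


class FormatError(ValueError):
    """A delimited input file violates the expected schema."""


@dataclass
class ObservedTable:
    """Observed concentration-time data read from a delimited file."""

    time_h: np.ndarray
    Cp_nM: np.ndarray | None
    Cm_nM: np.ndarray | None
    path: str = ""

    @property
    def single_analyte(self) -> bool:
        return (self.Cp_nM is None) != (self.Cm_nM is None)


def read_concentration_table(path) -> ObservedTable:
    """Read a comma-delimited table with header ``time_h`` plus one or both
    of ``Cp_nM``/``Cm_nM``.  Empty cells are allowed (missing samples);
    times must be strictly increasing and concentrations non-negative."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such concentration table: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if TIME_COL not in df.columns:
        raise FormatError(f"{path}: missing required column {TIME_COL!r} "
                          f"(expected {TIME_COL}, {CP_COL} and/or {CM_COL})")
    conc_cols = [c for c in (CP_COL, CM_COL) if c in df.columns]
    if not conc_cols:
        raise FormatError(f"{path}: need at least one concentration column "
                          f"({CP_COL} or {CM_COL}); units are nM")
    t = df[TIME_COL].to_numpy(dtype=float)
    if np.any(np.isnan(t)) or np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: {TIME_COL} must be strictly increasing")
    cols = {}
    for c in (CP_COL, CM_COL):
        if c in df.columns:
            vals = df[c].to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] < 0):
                raise FormatError(f"{path}: negative concentration in {c}")
            cols[c] = vals
        else:
            cols[c] = None
    return ObservedTable(time_h=t, Cp_nM=cols[CP_COL], Cm_nM=cols[CM_COL], path=str(path))


def write_concentration_table(source, path) -> Path:
    """Write a simulation result or observed table as CSV (full precision,
    so read(write(x)) round-trips finite values exactly)."""
    path = Path(path)
    if isinstance(source, SimulationResult):
        df = source.to_frame()
    elif isinstance(source, ObservedTable):
        data = {TIME_COL: source.time_h}
        if source.Cp_nM is not None:
            data[CP_COL] = source.Cp_nM
        if source.Cm_nM is not None:
            data[CM_COL] = source.Cm_nM
        df = pd.DataFrame(data)
    elif isinstance(source, pd.DataFrame):
        df = source
    else:
        raise TypeError(f"cannot write {type(source).__name__} as a concentration table")
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")  # bit-exact round trip
    return path


def default_config() -> dict:
    """Single source of truth for the reference scenario configuration."""
    from .reference import SHARED_REFERENCE, PYLORIC_B, SOLVER_DEFAULTS

    return {
        "genotype": "*1/*1",
        "parameters": {**SHARED_REFERENCE, "b": PYLORIC_B},  # k_m from genotype
        "dosing": {"time_h": 0.0, "dose_mg": 50.0,
                   "salt_molar_mass_g_per_mol": LOSARTAN_POTASSIUM_G_PER_MOL},
        "solver": dict(SOLVER_DEFAULTS),
    }


_KNOWN_SECTIONS = {"genotype", "parameters", "dosing", "solver"}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML config merged over the defaults; unknown keys are errors."""
    cfg = default_config()
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"no such config file: {path}")
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise FormatError(f"{path}: top level must be a mapping")
        for key, value in user.items():
            if key not in _KNOWN_SECTIONS:
                raise FormatError(f"{path}: unknown config section {key!r} "
                                  f"(known: {sorted(_KNOWN_SECTIONS)})")
            if isinstance(cfg.get(key), dict):
                bad = set(value) - set(cfg[key]) - {"k_m"}
                if bad:
                    raise FormatError(f"{path}: unknown keys {sorted(bad)} in section {key!r}")
                cfg[key].update(value)
            else:
                cfg[key] = value
    if overrides:
        for dotted, value in overrides.items():
            section, _, name = dotted.partition(".")
            if name:
                if section not in cfg or name not in cfg[section] and name != "k_m":
                    raise FormatError(f"unknown override {dotted!r}")
                cfg[section][name] = value
            else:
                if section not in _KNOWN_SECTIONS:
                    raise FormatError(f"unknown override {dotted!r}")
                cfg[section] = value
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record written once per CLI run."""

    command: str
    config_hash: str
    seed: int | None
    package_version: str
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    outputs: list = field(default_factory=list)

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
        return path
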