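"""Configuration loading, result serialization, and run manifests.

Config files are JSON (YAML accepted when PyYAML can parse the file) with
three optional sections::

    {
      "constants": {"x_z": 1.15, ...},        # ModelConstants overrides
      "isoform":   {"label": ..., "k_on": ..., "k_off": ..., "delta_plus": ...},
      "engine":    {"v": ..., "N": ..., "seed": ...}
    }

Every physical quantity is range-checked by the owning dataclass; unknown
keys are rejected. Tabular results go to CSV with a header row and
deterministic column order, stats and manifests to JSON; writes go through a
temp-file rename so a crash never leaves a truncated file.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd

from .constants import DEFAULT_CONSTANTS, ModelConstants
from .engine import EngineConfig
from .isoforms import IsoformConfig


@dataclass
class ConfigBundle:
    constants: ModelConstants
    isoform: IsoformConfig | None = None
    engine: EngineConfig | None = None
    provenance: dict[str, str] = field(default_factory=dict)


def _build(cls, section: dict, name: str, overrides: dict | None = None):
    allowed = {f.name for f in dataclasses.fields(cls)}
    merged = dict(section)
    if overrides:
        merged.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(merged) - allowed
    if unknown:
        raise ValueError(
            f"unknown keys in '{name}' section: {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    return cls(**merged)


def load_config(path: str | Path | None = None, **overrides: dict) -> ConfigBundle:
    """Load and validate a configuration bundle.

    ``overrides`` may carry per-section dicts (``constants=...``,
    ``isoform=...``, ``engine=...``) that take precedence over file values;
    an absent or empty file yields pure defaults. The returned bundle's
    ``provenance`` records where each section came from.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            raw = json.loads(text) if text.strip() else {}
        except json.JSONDecodeError:
            import yaml

            raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - {"constants", "isoform", "engine"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    provenance = {}
    for section in ("constants", "isoform", "engine"):
        src = []
        if raw.get(section):
            src.append(f"file:{path}")
        if overrides.get(section):
            src.append("override")
        provenance[section] = "+".join(src) or "defaults"
    constants = _build(
        ModelConstants, raw.get("constants", {}), "constants", overrides.get("constants")
    )
    isoform = None
    if raw.get("isoform") or overrides.get("isoform"):
        isoform = _build(IsoformConfig, raw.get("isoform", {}), "isoform", overrides.get("isoform"))
    engine = None
    if raw.get("engine") or overrides.get("engine"):
        engine = _build(EngineConfig, raw.get("engine", {}), "engine", overrides.get("engine"))
        dT = constants.dX / engine.v
        for rate_name, rate in (("k_on", isoform.k_on if isoform else None),
                                ("k_off", isoform.k_off if isoform else None)):
            if rate is not None and rate * dT > 1.0:
                raise ValueError(
                    f"{rate_name}*dT = {rate * dT:.3f} > 1 at v={engine.v} nm/s with "
                    f"dX={constants.dX} nm: per-step probability overflow"
                )
    return ConfigBundle(constants=constants, isoform=isoform, engine=engine, provenance=provenance)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit: code version, root
    seed, constants, isoform and run parameters, convergence flags."""

    tool: str
    version: str
    seed: int
    constants: dict
    isoform: dict | None = None
    parameters: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    timestamp: str = ""

    @classmethod
    def create(
        cls,
        seed: int,
        constants: ModelConstants,
        isoform: IsoformConfig | None = None,
        **parameters,
    ) -> "RunManifest":
        from . import __version__

        return cls(
            tool="myoswarm",
            version=__version__,
            seed=seed,
            constants=dataclasses.asdict(constants),
            isoform=dataclasses.asdict(isoform) if isoform else None,
            parameters=parameters,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def write_json(obj, path: str | Path) -> Path:
    """Serialize a dataclass/dict/array-bearing object to pretty JSON atomically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if hasattr(o, "tolist"):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o).__name__}")

    _atomic_write(path, json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
    return path


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> Path:
    """Write a DataFrame to CSV with a header row, fixed column order and
    explicit numeric precision, atomically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _atomic_write(path, df.to_csv(index=False, float_format=float_format))
    return path


def read_master_curve_points(path: str | Path) -> pd.DataFrame:
    """Reload a master-curve points table written by :func:`write_table`."""
    df = pd.read_csv(path)
    required = {"isoform", "N", "E_star", "mean_P"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"master-curve table missing columns: {sorted(missing)}")
    return df
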