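"""Configuration loading, trace serialization and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional, Union

import pandas as pd
import yaml

from .errors import ConfigError, TraceError

__all__ = ["RunManifest", "load_config", "write_trace", "read_trace"]

_PKG_VERSION = "0.1.0"


@dataclass
class RunManifest:
    """Provenance of a single run: command, config hash, seed, version."""

    command: str
    config_hash: str
    seed: Optional[int]
    version: str = _PKG_VERSION
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))
    outputs: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "timestamp": self.timestamp,
            "outputs": list(self.outputs),
        }


def config_hash(config: dict) -> str:
    """Stable sha256 of a canonical JSON rendering of the config."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: Union[str, Path], allowed_keys: Optional[Iterable[str]] = None) -> dict:
    """Parse a YAML/JSON config file into a dict, rejecting unknown keys.

    YAML is a superset of JSON so a single parser covers both; parse and
    validation failures raise :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    if allowed_keys is not None:
        unknown = sorted(set(data) - set(allowed_keys))
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    return data


def write_trace(
    trace,
    path: Union[str, Path],
    fmt: str = "csv",
    manifest: Optional[RunManifest] = None,
) -> None:
    """Serialize a trace to CSV (stable column order, full float precision)
    or JSON (with an embedded manifest block).

    CSV floats are written with Python's shortest round-trip repr, so a
    read-back reproduces the values bit for bit.
    """
    frame = trace.to_frame() if hasattr(trace, "to_frame") else trace
    if not isinstance(frame, pd.DataFrame):
        raise TraceError("trace must expose to_frame() or be a DataFrame")
    if len(frame) == 0:
        raise TraceError("refusing to write an empty trace")
    path = Path(path)
    if fmt == "csv":
        frame.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "json":
        payload: dict[str, Any] = {
            "manifest": (manifest.to_dict() if manifest else RunManifest(
                command="write_trace", config_hash="", seed=None
            ).to_dict()),
            "columns": {c: frame[c].tolist() for c in frame.columns},
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ConfigError(f"unknown trace format {fmt!r}")
    if manifest is not None:
        side = path.with_suffix(path.suffix + ".manifest.json")
        side.write_text(json.dumps(manifest.to_dict(), indent=1))


def read_trace(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a trace written by :func:`write_trace`."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return pd.DataFrame(payload["columns"])
    return pd.read_csv(path, float_precision="round_trip")
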