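"""Configuration files, validation, and result serialization.

YAML configs with paper-default values; CSV/JSON outputs with embedded
provenance (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .embryo import BoundaryProblem, EmbryoGradient
from .promoter import PromoterArchitecture

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "load_architecture",
    "save_architecture",
    "write_results",
    "read_results",
]

_ALLOWED_KEYS = {
    "L0",
    "x0",
    "decay_length",
    "delta_x",
    "error_rate",
    "cycle",
    "seed",
    "architecture",
}


@dataclass
class RunConfig:
    """Validated run configuration with paper defaults."""

    L0: float = 5.6
    x0: float = 45.0
    decay_length: float = 20.0
    delta_x: float = 2.0
    error_rate: float = 0.32
    cycle: int = 11
    seed: int | None = None
    architecture: dict | None = None

    def __post_init__(self) -> None:
        if self.L0 <= 0 or self.decay_length <= 0:
            raise ValueError("L0 and decay_length must be positive")
        if not 0 < self.error_rate < 0.5:
            raise ValueError("error_rate must lie in (0, 0.5)")
        if self.delta_x < 0:
            raise ValueError("delta_x must be nonnegative")
        if self.cycle < 1:
            raise ValueError("cycle must be >= 1")

    def gradient(self) -> EmbryoGradient:
        return EmbryoGradient(L0=self.L0, x0=self.x0, decay_length=self.decay_length)

    def problem(self) -> BoundaryProblem:
        return BoundaryProblem.from_gradient(
            self.gradient(), self.delta_x, self.error_rate
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Read and validate a YAML config; missing keys take paper defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))


def load_architecture(path) -> tuple[PromoterArchitecture, int]:
    """Read an architecture YAML/JSON with keys N, mu, nu, k."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"architecture file {path} must be a mapping")
    unknown = set(raw) - {"N", "mu", "nu", "k"}
    if unknown:
        raise ValueError(f"unknown architecture keys: {sorted(unknown)}")
    mu, nu = raw["mu"], raw["nu"]
    if "N" in raw and raw["N"] != len(mu):
        raise ValueError("N inconsistent with rate lists")
    k = int(raw.get("k", 1))
    arch = PromoterArchitecture(mu, nu)
    if not 1 <= k <= arch.N:
        raise ValueError("activation rule k out of range")
    return arch, k


def save_architecture(arch: PromoterArchitecture, k: int, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {"N": arch.N, "k": int(k), "mu": list(arch.mu), "nu": list(arch.nu)},
            sort_keys=False,
        )
    )


def _provenance(seed=None, config_hash=None) -> dict:
    return {
        "package": "promsprt",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash,
    }


def write_results(result, path, format: str | None = None, seed=None, config_hash=None):
    """Serialize a result table (CSV) or mapping (JSON) deterministically.

    CSV files carry a provenance comment line; JSON embeds a provenance
    object.  Floats are written at full precision.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        if not isinstance(result, pd.DataFrame):
            raise TypeError("CSV output requires a DataFrame")
        with open(path, "w") as fh:
            fh.write(f"# provenance: {json.dumps(_provenance(seed, config_hash))}\n")
            result.to_csv(fh, index=False, float_format="%.17g")
    elif format == "json":
        payload = {"provenance": _provenance(seed, config_hash), "result": result}
        path.write_text(json.dumps(payload, indent=2, default=_json_default))
    else:
        raise ValueError("format must be 'csv' or 'json'")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_results(path) -> pd.DataFrame:
    """Round-trip reader for CSV results written by :func:`write_results`."""
    return pd.read_csv(path, comment="#")
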