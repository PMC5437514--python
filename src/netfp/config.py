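"""Run configuration: defaults, validation, file/flag resolution.

Defaults mirror the method's standard settings: GO similarity measure,
APCluster node mapping, 10 permutation cycles ("fast" mode; "normal" mode
raises this to 100). Precedence when resolving: CLI flags > config file >
defaults. The resolved config is fully explicit and serialized into every
output artifact so runs can be reproduced exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .exceptions import ConfigError

MEASURES = ("go", "precomputed")
ALGORITHMS = ("apcluster", "greedy", "external")
MODES = ("fast", "normal")

#: permutation cycles per mode; "fast" is the published default of 10
MODE_N_PERM = {"fast": 10, "normal": 100}


@dataclass(frozen=True)
class RunConfig:
    measure: str = "go"
    algorithm: str = "apcluster"
    n_perm: int = 10
    seed: int = 0
    tau: float = 0.5
    w_topo: float = 0.5
    damping: float = 0.9
    preference: float | str = "median"
    min_sim: float = 0.5
    alpha: float = 0.05
    mode: str = "fast"
    max_iter: int = 1000
    convergence_window: int = 50
    external_cmd: str = ""

    def validate(self) -> "RunConfig":
        if self.measure not in MEASURES:
            raise ConfigError(f"measure must be one of {MEASURES}, got {self.measure!r}")
        if self.algorithm not in ALGORITHMS:
            raise ConfigError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_perm < 2:
            raise ConfigError(f"n_perm must be >= 2, got {self.n_perm}")
        for key in ("tau", "w_topo", "min_sim", "alpha"):
            v = getattr(self, key)
            if not 0.0 <= float(v) <= 1.0:
                raise ConfigError(f"{key} must lie in [0,1], got {v}")
        if not 0.5 <= self.damping < 1.0:
            raise ConfigError(f"damping must lie in [0.5, 1), got {self.damping}")
        if self.preference != "median":
            try:
                float(self.preference)
            except (TypeError, ValueError):
                raise ConfigError(
                    f"preference must be a number or 'median', got {self.preference!r}")
        if self.max_iter < 1 or self.convergence_window < 1:
            raise ConfigError("max_iter and convergence_window must be >= 1")
        return self

    def snapshot(self) -> dict:
        """JSON-serializable, fully materialized configuration."""
        return asdict(self)


_FIELD_TYPES = {f.name: f.type for f in fields(RunConfig)}
_INT_KEYS = {"n_perm", "seed", "max_iter", "convergence_window"}
_FLOAT_KEYS = {"tau", "w_topo", "damping", "min_sim", "alpha"}


def _coerce(key: str, value):
    if key not in _FIELD_TYPES:
        raise ConfigError(f"unknown configuration key: {key!r}")
    if key in _INT_KEYS:
        try:
            return int(value)
        except (TypeError, ValueError):
            raise ConfigError(f"{key} must be an integer, got {value!r}")
    if key in _FLOAT_KEYS:
        try:
            return float(value)
        except (TypeError, ValueError):
            raise ConfigError(f"{key} must be a number, got {value!r}")
    if key == "preference" and value != "median":
        try:
            return float(value)
        except (TypeError, ValueError):
            raise ConfigError(f"preference must be a number or 'median', got {value!r}")
    return value


def read_config_file(path: str | Path) -> dict:
    """Read a flat key=value or JSON config file into a raw dict."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if text.lstrip().startswith("{"):
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: JSON config must be an object")
        return raw
    raw = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}:{lineno}: expected key=value")
        key, value = stripped.split("=", 1)
        raw[key.strip()] = value.strip()
    return raw


def resolve_config(flags: dict | None = None,
                   config_file: str | Path | None = None) -> RunConfig:
    """Materialize a validated RunConfig with flags > file > defaults.

    Setting ``mode`` (without an explicit n_perm at the same layer or above)
    also sets the mode's permutation count.
    """
    merged: dict = {}
    layers = []
    if config_file is not None:
        layers.append(read_config_file(config_file))
    if flags:
        layers.append({k: v for k, v in flags.items() if v is not None})
    for layer in layers:
        if "mode" in layer and "n_perm" not in layer and "n_perm" not in merged:
            mode = layer["mode"]
            if mode in MODE_N_PERM:
                merged["n_perm"] = MODE_N_PERM[mode]
        for key, value in layer.items():
            merged[key] = _coerce(key, value)
    return RunConfig(**merged).validate()
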