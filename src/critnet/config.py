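"""Run configuration, validation, and reproducible output writing.

Configurations are plain YAML or TOML mappings with four blocks (network,
drive, solver, integrator) plus an output block and a seed.  Validation is
schema-driven: unknown keys are rejected by name, every default is explicit
in the schema, and the fully resolved configuration is echoed into the run
manifest so each figure-scale run is auditable.  All experiments are
deterministic; the seed is consumed only by the synthetic fixture noise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "config_from_mapping", "dump_config", "write_outputs"]


# (default, type) per key; None default means "resolved later / optional"
_SCHEMA: dict[str, dict[str, tuple]] = {
    "network": {
        "topology": ("line", str),
        "n_neurons": (64, int),
        "coupling_strength": (1.0, float),
        "long_range": ([], list),
        "matrix_csv": (None, str),
    },
    "drive": {
        "mode_rank": (1, int),
        "target_omega": (None, float),
        "center": (None, int),
        "strengths": ([2.0**i for i in range(-10, 3)], list),
        "max_half_length": (None, int),
        "half_length": (14, int),
    },
    "solver": {
        "tolerance": (1e-10, float),
        "max_iterations": (100, int),
        "damping": (True, bool),
    },
    "integrator": {
        "rtol": (1e-9, float),
        "atol": (1e-12, float),
        "horizon": (600.0, float),
        "floor_rel": (1e-7, float),
        "n_samples": (3000, int),
    },
    "output": {
        "directory": ("results", str),
        "precision": (12, int),
    },
}


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved, validated run configuration."""

    network: dict = field(default_factory=dict)
    drive: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    integrator: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)
    seed: int = 0


def _coerce(block: str, key: str, value, typ):
    if value is None:
        return None
    if typ is float and isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if typ is int and isinstance(value, int) and not isinstance(value, bool):
        return int(value)
    if typ is bool and isinstance(value, bool):
        return value
    if typ is str and isinstance(value, str):
        return value
    if typ is list and isinstance(value, (list, tuple)):
        return list(value)
    raise ConfigError(f"{block}.{key}: expected {typ.__name__}, got {value!r}")


def config_from_mapping(raw: dict) -> RunConfig:
    """Validate a parsed mapping against the schema, filling all defaults."""
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - set(_SCHEMA) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown configuration block(s): {sorted(unknown)}")
    blocks = {}
    for block, fields_ in _SCHEMA.items():
        given = raw.get(block, {}) or {}
        if not isinstance(given, dict):
            raise ConfigError(f"block '{block}' must be a mapping")
        bad = set(given) - set(fields_)
        if bad:
            raise ConfigError(f"unknown key(s) in '{block}': {sorted(bad)}")
        resolved = {}
        for key, (default, typ) in fields_.items():
            value = given.get(key, default)
            resolved[key] = _coerce(block, key, value, typ)
        blocks[block] = resolved
    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        raise ConfigError(f"seed must be an integer, got {seed!r}")
    return RunConfig(seed=seed, **blocks)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or TOML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text()
    if path.suffix in (".toml", ".tml"):
        import tomllib

        try:
            raw = tomllib.loads(text)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"TOML parse error in {path}: {exc}") from exc
    else:
        import yaml

        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"YAML parse error in {path}: {exc}") from exc
    return config_from_mapping(raw or {})


def dump_config(config: RunConfig) -> dict:
    """Plain-dict form; ``config_from_mapping(dump_config(c)) == c``."""
    return asdict(config)


def _config_hash(config: RunConfig) -> str:
    canon = json.dumps(dump_config(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_outputs(
    frames: dict[str, pd.DataFrame],
    config: RunConfig,
    failures: list[dict] | None = None,
    directory: str | Path | None = None,
) -> dict:
    """Write experiment CSVs plus a JSON run manifest.

    ``frames`` maps basenames (without extension) to DataFrames.  Numeric
    content is printed with the configured number of significant digits, so
    re-running an identical configuration byte-reproduces the CSVs.  The
    manifest records the resolved configuration, its hash, package and
    library versions, and any non-converged cells; callers exit nonzero
    when ``failures`` is nonempty.
    """
    import scipy

    from . import __version__

    outdir = Path(directory if directory is not None else config.output["directory"])
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ConfigError(f"cannot create output directory {outdir}: {exc}") from exc
    precision = int(config.output["precision"])
    fmt = f"%.{precision}g"
    paths = {}
    for name, frame in frames.items():
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False, float_format=fmt)
        paths[name] = str(p)
    failures = failures or []
    manifest = {
        "critnet_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "config": dump_config(config),
        "config_hash": _config_hash(config),
        "outputs": paths,
        "n_failures": len(failures),
        "failures": failures,
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = str(mpath)
    return paths
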