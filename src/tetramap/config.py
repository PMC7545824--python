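"""Flat key=value configuration files.

Every :class:`~tetramap.simulate.SimConfig` field is a key, plus the
triage keys ``frequency_cutoff`` and ``keep_at_cutoff``. Unknown keys are
errors (fail fast on typos). Example::

    seed = 1
    n_mutations = 60
    mean_coverage = 30
    artifact_frequency_beta = 8,8
    frequency_cutoff = 80
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from .simulate import SimConfig
from .triage import TriageConfig

__all__ = ["ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Bad configuration file: unknown key, bad value, or syntax."""


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _coerce(name: str, raw: str, ftype) -> object:
    raw = raw.strip()
    try:
        if ftype is int:
            return int(raw)
        if ftype is float:
            return float(raw)
        if ftype is bool:
            if raw.lower() not in _BOOL:
                raise ValueError(f"not a boolean: {raw!r}")
            return _BOOL[raw.lower()]
        if ftype is str:
            return raw
        # tuple[float, float] (the Beta shape pair)
        parts = [p for p in raw.replace("(", "").replace(")", "").split(",") if p.strip()]
        return tuple(float(p) for p in parts)
    except ValueError as exc:
        raise ConfigError(f"key {name!r}: {exc}") from exc


def _parse_lines(path: Path) -> dict[str, str]:
    pairs: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path} line {lineno}: expected key = value")
        key, value = stripped.split("=", 1)
        key = key.strip()
        if key in pairs:
            raise ConfigError(f"{path} line {lineno}: duplicate key {key!r}")
        pairs[key] = value
    return pairs


_FIELD_TYPES = {
    "seed": int,
    "n_chromosomes": int,
    "chromosome_length": int,
    "n_genes": int,
    "genetic_map_rate": float,
    "n_background_snps": int,
    "n_outcross_snps": int,
    "n_mutations": int,
    "causative_gene": str,
    "mean_coverage": float,
    "base_error_rate": float,
    "min_alt_reads": int,
    "artifact_variant_rate": float,
    "artifact_frequency_beta": tuple,
    "n_tetrads": int,
    "backcross_generations": int,
}

_TRIAGE_TYPES = {"frequency_cutoff": float, "keep_at_cutoff": bool}


def load_config(path) -> tuple[SimConfig, TriageConfig]:
    """Read a flat key=value file into (SimConfig, TriageConfig)."""
    pairs = _parse_lines(Path(path))
    sim_kwargs = {}
    triage_kwargs = {}
    for key, raw in pairs.items():
        if key in _FIELD_TYPES:
            sim_kwargs[key] = _coerce(key, raw, _FIELD_TYPES[key])
        elif key in _TRIAGE_TYPES:
            triage_kwargs[key] = _coerce(key, raw, _TRIAGE_TYPES[key])
        else:
            raise ConfigError(f"unknown configuration key {key!r}")
    try:
        return SimConfig(**sim_kwargs), TriageConfig(**triage_kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(cfg: SimConfig, triage_cfg: TriageConfig, path) -> None:
    """Write a config file that :func:`load_config` reads back identically."""
    lines = []
    for f in dataclasses.fields(cfg):
        value = getattr(cfg, f.name)
        if isinstance(value, tuple):
            value = ",".join(str(v) for v in value)
        lines.append(f"{f.name} = {value}")
    for f in dataclasses.fields(triage_cfg):
        lines.append(f"{f.name} = {getattr(triage_cfg, f.name)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
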