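"""TOML configuration: named parameter profiles, run configuration, round trip.

A run configuration holds a full :class:`~memtug.model.ModelParameters` set
(optionally seeded from a named profile), an optional unit system, an
optional scan specification, and run housekeeping (output directory, seed,
verbosity).  The reference profile ``paper2011`` describes a gramicidin A
dimer in a solvent-free monoglyceride bilayer; see docs/methods.md for the
provenance of each number.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import tomllib

from .errors import ConfigError
from .model import ModelParameters, UnitSystem, beta_from_hooke

__all__ = [
    "PROFILES",
    "ScanSpec",
    "RunConfig",
    "get_profile",
    "load_config",
    "loads_config",
    "validate_config",
    "dump_config",
]

# Reference parameter profiles.  "beta" may be given directly or derived
# from a junction Hookean constant "k" via beta = sqrt(k / (2*D_e)).
PROFILES: dict[str, dict[str, float]] = {
    # Gramicidin A in a solvent-free monoglyceride bilayer, reduced time
    # units (A = 1) and thermal energy units (kBT = 1):
    #   D_e  = ln(100) kBT   bond depth from the ~1:100 dimer:monomer ratio
    #   r_e  = 1.3 nm        centre-of-mass separation of the two monomers
    #   k    = 920 kBT/nm^2  hydrogen-bonded junction stiffness (~3.8 N/m)
    #   l0   = 2.17 nm       dimer hydrophobic length
    #   d    = 2.85 nm       bilayer hydrophobic thickness
    #   H_B  = 12 kBT/nm^2   phenomenological bilayer spring coefficient
    "paper2011": {
        "D_e": math.log(100.0),
        "r_e": 1.3,
        "k": 920.0,
        "l0": 2.17,
        "d": 2.85,
        "H_B": 12.0,
        "A": 1.0,
        "kBT": 1.0,
        "coupling_slope": 1.0,
    },
}

_MODEL_FIELDS = ("D_e", "r_e", "beta", "l0", "d", "H_B", "A", "kBT", "coupling_slope")
_MODEL_DEFAULTS = {"A": 1.0, "kBT": 1.0, "coupling_slope": 1.0}


@dataclass(frozen=True)
class ScanSpec:
    """Sweep specification: variable ('thickness' | 'stiffness'), inclusive
    range and number of points."""

    variable: str
    min: float
    max: float
    n: int = 9

    def __post_init__(self) -> None:
        if self.variable not in ("thickness", "stiffness"):
            raise ConfigError(
                f"scan.variable must be 'thickness' or 'stiffness', got {self.variable!r}"
            )
        if not (math.isfinite(self.min) and math.isfinite(self.max)) or self.max < self.min:
            raise ConfigError(f"scan range [min={self.min!r}, max={self.max!r}] is invalid")
        if self.n < 1:
            raise ConfigError(f"scan.n must be >= 1, got {self.n!r}")

    def values(self) -> list[float]:
        if self.n == 1:
            return [float(self.min)]
        step = (self.max - self.min) / (self.n - 1)
        return [float(self.min + i * step) for i in range(self.n)]


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration for one run."""

    params: ModelParameters
    units: Optional[UnitSystem] = None
    scan: Optional[ScanSpec] = None
    outdir: str = "."
    seed: int = 0
    verbosity: int = 1


def get_profile(name: str) -> ModelParameters:
    """Resolve a named profile into a validated parameter set."""
    if name not in PROFILES:
        raise ConfigError(f"unknown profile {name!r}; available: {sorted(PROFILES)}")
    return _build_params(dict(PROFILES[name]))


def _build_params(raw: dict) -> ModelParameters:
    raw = dict(raw)
    k = raw.pop("k", None)
    if k is not None and "beta" not in raw:
        try:
            raw["beta"] = beta_from_hooke(float(k), float(raw.get("D_e", float("nan"))))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"cannot derive beta from k: {exc}") from exc
    unknown = set(raw) - set(_MODEL_FIELDS)
    if unknown:
        raise ConfigError(f"unknown model field(s): {sorted(unknown)}")
    missing = {f for f in _MODEL_FIELDS if f not in raw and f not in _MODEL_DEFAULTS}
    if missing:
        raise ConfigError(f"missing required model field(s): {sorted(missing)}")
    merged = {**_MODEL_DEFAULTS, **raw}
    try:
        return ModelParameters(**{f: float(merged[f]) for f in _MODEL_FIELDS})
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def loads_config(text: str) -> RunConfig:
    """Parse a TOML document into a validated :class:`RunConfig`."""
    try:
        doc = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"invalid TOML: {exc}") from exc

    model = dict(doc.get("model", {}))
    profile = model.pop("profile", None)
    if profile is not None:
        base = dict(PROFILES.get(profile) or {})
        if not base:
            raise ConfigError(f"unknown profile {profile!r}; available: {sorted(PROFILES)}")
        if "beta" in model or "k" in model:
            base.pop("k", None)
            base.pop("beta", None)
        base.update(model)
        model = base
    params = _build_params(model)

    units = None
    if "units" in doc:
        u = doc["units"]
        try:
            units = UnitSystem(
                energy_label=str(u.get("energy_label", "kBT")),
                energy_scale=float(u.get("energy_scale", 1.0)),
                length_label=str(u.get("length_label", "nm")),
                length_scale=float(u.get("length_scale", 1.0)),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid [units] section: {exc}") from exc

    scan = None
    if "scan" in doc:
        s = doc["scan"]
        try:
            scan = ScanSpec(
                variable=str(s["variable"]),
                min=float(s["min"]),
                max=float(s["max"]),
                n=int(s.get("n", 9)),
            )
        except KeyError as exc:
            raise ConfigError(f"[scan] section missing field {exc.args[0]!r}") from exc

    run = doc.get("run", {})
    return RunConfig(
        params=params,
        units=units,
        scan=scan,
        outdir=str(run.get("outdir", ".")),
        seed=int(run.get("seed", 0)),
        verbosity=int(run.get("verbosity", 1)),
    )


def load_config(path) -> RunConfig:
    """Read and validate a TOML run configuration from ``path``."""
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path!r}: {exc}") from exc
    return loads_config(text)


def validate_config(cfg: RunConfig) -> RunConfig:
    """Re-run all invariants on an in-memory configuration."""
    ModelParameters(**asdict(cfg.params))
    if cfg.units is not None:
        UnitSystem(**asdict(cfg.units))
    if cfg.scan is not None:
        ScanSpec(**asdict(cfg.scan))
    return cfg


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, int):
        return str(v)
    if isinstance(v, float):
        return repr(v)  # shortest round-trip representation
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def dump_config(cfg: RunConfig) -> str:
    """Serialize a run configuration to TOML (round-trips exactly)."""
    lines = ["[model]"]
    for name in _MODEL_FIELDS:
        lines.append(f"{name} = {_toml_value(getattr(cfg.params, name))}")
    if cfg.units is not None:
        lines += ["", "[units]"]
        for name in ("energy_label", "energy_scale", "length_label", "length_scale"):
            lines.append(f"{name} = {_toml_value(getattr(cfg.units, name))}")
    if cfg.scan is not None:
        lines += ["", "[scan]"]
        for name in ("variable", "min", "max", "n"):
            lines.append(f"{name} = {_toml_value(getattr(cfg.scan, name))}")
    lines += [
        "",
        "[run]",
        f"outdir = {_toml_value(cfg.outdir)}",
        f"seed = {_toml_value(cfg.seed)}",
        f"verbosity = {_toml_value(cfg.verbosity)}",
        "",
    ]
    return "\n".join(lines)
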