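"""YAML run configuration: forcefield, system, protocol, analysis blocks.

A config round-trips losslessly through YAML; the seed is mandatory and
every source of randomness in a run flows from it.  Schema violations
raise :class:`ConfigError` naming the offending key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import IntegratorConfig
from .forcefield import BEAD_TYPES, ForceFieldTable, default_force_table

PROTOCOL_DEFAULTS = {"ensemble": "NVT", "dt": 0.01, "steps": 10000, "stride": 1000,
                     "target_pressure": 23.7}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int
    forcefield: dict = field(default_factory=lambda: {"condition": "good"})
    system: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    def __post_init__(self):
        proto = dict(PROTOCOL_DEFAULTS)
        proto.update(self.protocol)
        self.protocol = proto
        if self.protocol["dt"] <= 0:
            raise ConfigError(f"protocol.dt must be positive, got {self.protocol['dt']}")
        if self.protocol["ensemble"] not in ("NVT", "NPT"):
            raise ConfigError(f"protocol.ensemble must be NVT or NPT, got {self.protocol['ensemble']!r}")
        if int(self.protocol["steps"]) < 0:
            raise ConfigError("protocol.steps must be non-negative")

    def build_forcefield(self) -> ForceFieldTable:
        ffc = dict(self.forcefield)
        condition = ffc.pop("condition", "good")
        if "f" in ffc:
            return ForceFieldTable.from_dict(ffc)
        f_ws = ffc.pop("f_WS", None)
        kwargs = {}
        for key in ("gamma", "bond_k", "bond_l0", "bend_k", "cutoff"):
            if key in ffc:
                kwargs[key] = ffc.pop(key)
        if ffc:
            raise ConfigError(f"unknown forcefield key(s): {sorted(ffc)}")
        table = default_force_table(condition, **kwargs)
        if f_ws is not None:
            iw, isol = BEAD_TYPES.index("W"), BEAD_TYPES.index("S")
            table.f[iw, isol] = table.f[isol, iw] = float(f_ws)
        return table

    def integrator_config(self) -> IntegratorConfig:
        p = self.protocol
        return IntegratorConfig(dt=float(p["dt"]), ensemble=p["ensemble"],
                                target_pressure=float(p.get("target_pressure", 23.7)))

    def build_state(self):
        """Construct the initial state from the ``system`` block."""
        from . import builders

        sys = dict(self.system)
        builder = sys.pop("builder", None)
        if builder is None:
            raise ConfigError("system.builder is required (bulk|slab|planar_bilayer|vesicle)")
        sys.setdefault("seed", self.seed)
        if builder == "bulk":
            return builders.build_bulk(**sys)
        if builder == "slab":
            return builders.build_slab(**sys)
        if builder == "planar_bilayer":
            return builders.build_planar_bilayer(**sys)
        if builder == "vesicle":
            return builders.build_vesicle(builders.VesicleSpec(**sys))
        raise ConfigError(f"unknown system.builder {builder!r}")

    def to_dict(self) -> dict:
        return {"seed": self.seed, "forcefield": self.forcefield, "system": self.system,
                "protocol": self.protocol, "analysis": self.analysis}

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    if "seed" not in raw:
        raise ConfigError(f"{path}: 'seed' is mandatory")
    known = {"seed", "forcefield", "system", "protocol", "analysis"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown top-level key(s): {sorted(unknown)}")
    return RunConfig(seed=int(raw["seed"]),
                     forcefield=raw.get("forcefield", {"condition": "good"}) or {},
                     system=raw.get("system", {}) or {},
                     protocol=raw.get("protocol", {}) or {},
                     analysis=raw.get("analysis", {}) or {})
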