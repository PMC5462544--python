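"""Run configuration: reference parameter values, YAML loading, metadata.

Defaults are the reference parameter set of the model (lengths in nm,
moduli in kBT): rflat 500, rrim 30, h 15, Rd 5, kappa_ld 20,
kappa_lo 80, alpha_kbar -0.83, Phi in [0, 0.4], Js in [0, 0.033] nm^-1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "write_metadata"]


@dataclass
class RunConfig:
    # geometry (nm)
    rflat: float = 500.0
    rrim: float = 30.0
    h: float = 15.0
    # nanodomains
    Rd: float = 5.0
    Phi: float = 0.2
    # elastic (kBT, nm^-1)
    kappa_ld: float = 20.0
    kappa_lo: float = 80.0
    alpha_kbar: float = -0.83
    Js: float = 0.02
    js_mid_mode: str = "rim_only"
    # scan grids
    Phi_min: float = 0.0
    Phi_max: float = 0.4
    n_Phi: int = 21
    Js_min: float = 0.0
    Js_max: float = 0.033
    n_Js: int = 34
    n_grid: int = 200
    boundary_tol: float = 1e-4
    # kinetics
    t0_ms: float = 1.0
    feasibility_barrier: float = 25.0
    # DAG
    phi_DAG: float = 0.014
    zeta_DAG: float = -1.0
    a_DAG: float = 0.6
    n_phi_DAG: int = 6
    n_Js_dag: int = 12

    def validate(self) -> None:
        checks = {
            "rflat": self.rflat > self.rrim,
            "rrim": self.rrim > self.h,
            "h": self.h > 0,
            "Rd": self.Rd > 0,
            "Phi": 0.0 <= self.Phi <= 1.0,
            "kappa_ld": 0 < self.kappa_ld <= self.kappa_lo,
            "Js": self.Js >= 0,
            "js_mid_mode": self.js_mid_mode in ("rim_only", "homogeneous"),
            "n_grid": self.n_grid >= 100,
            "phi_DAG": 0.0 <= self.phi_DAG <= 0.05,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ConfigError(f"invalid configuration value(s): {', '.join(bad)}")

    def overrides(self) -> dict:
        """Fields that differ from the defaults (echoed into metadata)."""
        default = RunConfig()
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if getattr(self, f.name) != getattr(default, f.name)
        }


class ConfigError(ValueError):
    pass


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML key-value config file, apply keyword overrides, validate."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must be a key-value mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def write_metadata(cfg: RunConfig, path: str | Path, command: str) -> None:
    """Write the fully resolved configuration next to the outputs."""
    from . import __version__

    meta = {
        "package": "golgimorph",
        "version": __version__,
        "command": command,
        "config": dataclasses.asdict(cfg),
        "overrides": cfg.overrides(),
    }
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
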