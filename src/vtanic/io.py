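"""Configuration loading/validation and deterministic result writers.

Run configurations are JSON documents validated by pydantic models with
unknown keys rejected (the error names the offending key).  A minimal
configuration only names a scenario preset; everything else is defaulted.
Results are written as CSV with a fixed column schema at 10 significant
digits plus a JSON sidecar carrying the summary metrics, a configuration
hash and the software version, so repeated runs of the same configuration
produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .circuit import BlockadeFlags, CircuitParams
from .protocols import (
    TRACE_COLUMNS,
    NicotineApplication,
    Protocol,
    SimResult,
    run_protocol,
    scenario_defaults,
)
from .receptors import ReceptorParams, _params_from_dict, _params_to_dict, load_preset

__all__ = [
    "RunConfig",
    "load_config",
    "build_protocol",
    "write_result",
    "config_hash",
    "ConfigError",
]


class ConfigError(ValueError):
    """A configuration file failed validation."""


class ApplicationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    onset_s: float = Field(ge=0, default=60.0)
    duration_s: float = Field(gt=0)
    concentration_uM: float = Field(ge=0)
    pk_tau_s: float = Field(gt=0, default=60.0)


class CircuitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    r: Optional[float] = Field(default=None, ge=0, le=1)
    nu_ach_uM: Optional[float] = Field(default=None, ge=0)
    nu_glu: Optional[float] = Field(default=None, ge=0, le=1)
    w_gaba: float = Field(ge=0, default=1.0)
    w_glu: float = Field(ge=0, default=1.0)
    w_a4b2: float = Field(ge=0, default=1.0)
    i_intr: float = 1.0
    i0_da: float = 0.0
    i0_g: float = 0.0
    tau_da_ms: float = Field(gt=0, default=20.0)
    tau_g_ms: float = Field(gt=0, default=20.0)


class BlockadeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    a4b2: bool = False
    a7: bool = False
    glu: bool = False
    gaba: bool = False


class RunConfig(BaseModel):
    """Validated, fully-defaulted simulation configuration."""

    model_config = ConfigDict(extra="forbid")

    scenario: Optional[
        Literal["direct_stimulation", "disinhibition",
                "in_vitro_ipsc", "in_vitro_epsc"]
    ] = None
    receptors: dict[Literal["a4b2", "a7"], dict] = Field(default_factory=dict)
    circuit: CircuitConfig = Field(default_factory=CircuitConfig)
    applications: Optional[list[ApplicationConfig]] = None
    blockade: BlockadeConfig = Field(default_factory=BlockadeConfig)
    eta: Optional[float] = Field(default=None, ge=0, le=1)
    horizon_s: Optional[float] = Field(default=None, gt=0)
    dt_ms: float = Field(gt=0, default=10.0)
    qss_activation: bool = True
    seed: int = 0            # recorded for provenance; the model is deterministic

    @model_validator(mode="after")
    def _needs_geometry(self) -> "RunConfig":
        if self.scenario is None and self.circuit.r is None:
            raise ValueError("either a scenario preset or circuit.r must be given")
        return self

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True, separators=(",", ":"))


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration.

    Raises ConfigError with the offending key's location on schema or unit
    violations.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except FileNotFoundError:
        raise ConfigError(f"configuration file not found: {path}")
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: invalid JSON: {exc}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"]) or "<root>"
            lines.append(f"{loc}: {err['msg']}")
        raise ConfigError(f"{path}: " + "; ".join(lines))


def _receptor_from_config(cfg: RunConfig, name: str) -> ReceptorParams:
    base = load_preset(name)
    overrides = cfg.receptors.get(name)
    if not overrides:
        return base
    d = _params_to_dict(base)
    unknown = set(overrides) - set(d)
    if unknown:
        raise ConfigError(f"receptors.{name}: unknown keys {sorted(unknown)}")
    d.update(overrides)
    try:
        return _params_from_dict(d)
    except ValueError as exc:
        raise ConfigError(f"receptors.{name}: {exc}")


def build_protocol(cfg: RunConfig) -> Protocol:
    """Materialize a validated configuration into a Protocol."""
    defaults = scenario_defaults(cfg.scenario) if cfg.scenario else {}
    c = cfg.circuit
    try:
        circuit = CircuitParams(
            r=c.r if c.r is not None else defaults["r"],
            nu_ach=c.nu_ach_uM if c.nu_ach_uM is not None
            else defaults.get("nu_ach_uM", 0.1),
            nu_glu=c.nu_glu if c.nu_glu is not None else defaults.get("nu_glu", 0.0),
            w_gaba=c.w_gaba, w_glu=c.w_glu, w_a4b2=c.w_a4b2,
            i_intr=c.i_intr, i0_da=c.i0_da, i0_g=c.i0_g,
            tau_da=c.tau_da_ms * 1e-3, tau_g=c.tau_g_ms * 1e-3,
        )
    except ValueError as exc:
        raise ConfigError(f"circuit: {exc}")
    blockade = BlockadeFlags(
        a4b2=cfg.blockade.a4b2,
        a7=cfg.blockade.a7,
        glu=cfg.blockade.glu or defaults.get("glu_blocked", False),
        gaba=cfg.blockade.gaba or defaults.get("gaba_blocked", False),
    )
    if cfg.applications is None:
        duration = defaults.get("nic_duration_s", 120.0)
        apps = (NicotineApplication(onset=60.0, duration=duration,
                                    concentration=1.0),)
    else:
        apps = tuple(
            NicotineApplication(onset=a.onset_s, duration=a.duration_s,
                                concentration=a.concentration_uM,
                                pk_tau=a.pk_tau_s)
            for a in cfg.applications
        )
    return Protocol(
        circuit=circuit,
        a4b2=_receptor_from_config(cfg, "a4b2"),
        a7=_receptor_from_config(cfg, "a7"),
        applications=apps,
        blockade=blockade,
        eta=cfg.eta,
        horizon=cfg.horizon_s,
        dt=cfg.dt_ms * 1e-3,
        qss_activation=cfg.qss_activation,
        label=cfg.scenario or "custom",
    )


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(cfg.canonical_json().encode()).hexdigest()[:16]


def write_result(
    result: SimResult,
    csv_path,
    json_path=None,
    cfg: RunConfig | None = None,
) -> None:
    """Write the trajectory CSV (fixed schema) and an optional JSON sidecar.

    Floats are rendered at 10 significant digits so repeated runs of the
    same configuration are byte-identical across platforms.
    """
    from . import __version__
    from .metrics import compute_metrics

    frame = result.frame[TRACE_COLUMNS]
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    if len(frame) == 0:
        csv_path.write_text(",".join(TRACE_COLUMNS) + "\n")
        return
    frame.to_csv(csv_path, index=False, float_format="%.10g", lineterminator="\n")
    if json_path is not None:
        sidecar = {
            "version": __version__,
            "config_hash": config_hash(cfg) if cfg is not None else None,
            "label": result.protocol.label,
            "baseline": {k: round(v, 10) for k, v in result.baseline.items()},
            "metrics": {},
        }
        for pop in ("da", "gaba", "i_gaba", "i_glu"):
            m = compute_metrics(result, pop)
            sidecar["metrics"][pop] = {
                "peak_rel_change_pct": round(m.peak_rel_change, 6),
                "time_of_peak_s": round(m.time_of_peak, 6),
                "net_change_integral": round(m.net_change_integral, 6),
                "halfmax_duration_s": round(m.halfmax_duration, 6),
                "post_washout_min_pct": round(m.post_washout_min, 6),
                "degenerate": m.degenerate,
            }
        Path(json_path).write_text(json.dumps(sidecar, indent=1) + "\n")
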