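"""Nicotine pharmacokinetics and named experimental protocols.

Bath-applied or injected nicotine does not reach the receptors instantly:
the concentration at the site follows the applied square pulse through a
first-order lag with a time constant of one minute, so it builds up as
``1 - exp(-t/tau)`` during the application and decays exponentially after
washout.

On top of this pharmacokinetic layer the module defines the protocols the
model is interrogated with:

* slice-like (in vitro) IPSC and EPSC protocols — low afferent drive, one
  transmission pathway pharmacologically blocked, the relative change of the
  GABAergic or glutamatergic input current to DA cells is read out;
* in-vivo scenario presets — *direct stimulation* (α4β2 action mostly on DA
  cells, r = 0.8, low cholinergic rate 0.1 µM, 10-min nicotine) and
  *disinhibition* (α4β2 action mostly on GABA cells, r = 0.2, high
  cholinergic rate 1.77 µM, 2-min nicotine);
* parameter sweeps over the cholinergic rate, nicotine dose, receptor
  balance r, or the ACh-desensitization fraction η.

The in-vitro afferent drives are not free: they are anchored by the
calibration routines in :mod:`vtanic.metrics` so that 1 µM nicotine evokes a
300% peak increase of the GABAergic input and a 325% peak increase of the
glutamatergic input.  The calibrated values are shipped in
``presets/scenarios.json`` and can be regenerated with
``vtanic calibrate``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .circuit import BlockadeFlags, CircuitParams, run_trajectory, steady_state
from .receptors import ReceptorParams, load_preset

__all__ = [
    "NicotineApplication",
    "Protocol",
    "SimResult",
    "nic_at_site",
    "run_protocol",
    "scenario_protocol",
    "scenario_defaults",
    "in_vitro_ipsc",
    "in_vitro_epsc",
    "sweep",
    "eta_sweep",
    "TRACE_COLUMNS",
]

TRACE_COLUMNS = [
    "time_s", "nic_site_uM", "a_a4b2", "s_a4b2", "a_a7", "s_a7",
    "i_glu", "i_gaba", "i_a4b2", "nu_da", "nu_g", "nu_da_norm", "nu_g_norm",
]


@dataclass(frozen=True)
class NicotineApplication:
    """One timed nicotine application (bath perfusion or injection)."""

    onset: float                   # s
    duration: float                # s
    concentration: float           # applied concentration, µM
    pk_tau: float = 60.0           # first-order lag time constant, s

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("onset must be non-negative")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if not self.pk_tau > 0:
            raise ValueError("pk_tau must be positive")


def nic_at_site(t, applications: Sequence[NicotineApplication]):
    """Nicotine concentration at the receptor site (µM) at time(s) ``t``.

    Each application contributes a first-order-lagged square pulse;
    overlapping applications are summed.  The result is continuous and
    non-negative for all t ≥ 0.
    """
    tt = np.asarray(t, dtype=float)
    out = np.zeros_like(tt)
    for app in applications:
        rise = tt - app.onset
        fall = tt - (app.onset + app.duration)
        c_end = app.concentration * -np.expm1(-app.duration / app.pk_tau)
        during = (rise >= 0) & (fall < 0)
        after = fall >= 0
        contrib = np.zeros_like(tt)
        contrib[during] = app.concentration * -np.expm1(-rise[during] / app.pk_tau)
        contrib[after] = c_end * np.exp(-fall[after] / app.pk_tau)
        out += contrib
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Protocol:
    """A complete, self-contained simulation specification."""

    circuit: CircuitParams
    a4b2: ReceptorParams = field(default_factory=lambda: load_preset("a4b2"))
    a7: ReceptorParams = field(default_factory=lambda: load_preset("a7"))
    applications: tuple[NicotineApplication, ...] = ()
    blockade: BlockadeFlags = BlockadeFlags()
    horizon: float | None = None   # s; default: last washout + 6 * tau_max(α4β2)
    eta: float | None = None       # overrides the α4β2 eta when set
    dt: float = 0.010              # s
    qss_activation: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if self.eta is not None and not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must be in [0, 1]")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.horizon is not None and self.applications:
            if self.horizon < self.last_application_end:
                raise ValueError("horizon must cover all applications")

    @property
    def a4b2_effective(self) -> ReceptorParams:
        return self.a4b2 if self.eta is None else self.a4b2.with_eta(self.eta)

    @property
    def onset(self) -> float:
        return min((a.onset for a in self.applications), default=0.0)

    @property
    def last_application_end(self) -> float:
        return max((a.onset + a.duration for a in self.applications), default=0.0)

    @property
    def effective_horizon(self) -> float:
        if self.horizon is not None:
            return self.horizon
        return self.last_application_end + 6.0 * self.a4b2.tau_max


@dataclass(frozen=True)
class SimResult:
    """Aligned trajectories plus the analytic pre-application baseline."""

    frame: pd.DataFrame
    baseline: dict[str, float]
    protocol: Protocol

    @property
    def onset(self) -> float:
        return self.protocol.onset

    @property
    def washout(self) -> float:
        return self.protocol.last_application_end

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()


def run_protocol(proto: Protocol) -> SimResult:
    """Simulate a protocol from its analytic baseline; fully deterministic."""
    a4b2 = proto.a4b2_effective
    horizon = proto.effective_horizon
    n = int(round(horizon / proto.dt))
    t = np.arange(n + 1) * proto.dt
    nic = np.atleast_1d(nic_at_site(t, proto.applications))
    init = steady_state(proto.circuit, a4b2, proto.a7, nic=float(nic[0]),
                        blockade=proto.blockade)
    tr = run_trajectory(
        proto.circuit, a4b2, proto.a7, nic, proto.dt,
        blockade=proto.blockade, qss_activation=proto.qss_activation, init=init,
    )
    baseline = {
        "nu_da": init.nu_da,
        "nu_g": init.nu_g,
        "i_glu": float(tr["i_glu"][0]),
        "i_gaba": float(tr["i_gaba"][0]),
        "i_a4b2": float(tr["i_a4b2"][0]),
    }
    frame = pd.DataFrame({"time_s": t, **{k: tr[k] for k in (
        "nic_site_uM", "a_a4b2", "s_a4b2", "a_a7", "s_a7",
        "i_glu", "i_gaba", "i_a4b2", "nu_da", "nu_g")}})
    for col, base in (("nu_da_norm", init.nu_da), ("nu_g_norm", init.nu_g)):
        src = col.removesuffix("_norm")
        frame[col] = frame[src] / base if base > 1e-12 else np.nan
    return SimResult(frame=frame, baseline=baseline, protocol=proto)


# ---------------------------------------------------------------------------
# scenario presets

def _scenario_table() -> dict:
    text = resources.files("vtanic.presets").joinpath("scenarios.json").read_text()
    return json.loads(text)


def scenario_defaults(name: str) -> dict:
    """Raw preset values (r, nu_ach, nu_glu, nic duration) for a scenario."""
    table = _scenario_table()
    if name not in table:
        raise KeyError(f"unknown scenario {name!r}; have {sorted(table)}")
    return dict(table[name])


def scenario_protocol(
    name: str,
    nic_dose: float = 1.0,
    duration: float | None = None,
    eta: float | None = None,
    blockade: BlockadeFlags = BlockadeFlags(),
    horizon: float | None = None,
    dt: float = 0.010,
    **circuit_overrides,
) -> Protocol:
    """Build a Protocol for a named scenario preset.

    ``name`` is one of ``direct_stimulation``, ``disinhibition``,
    ``in_vitro_ipsc``, ``in_vitro_epsc``.  ``circuit_overrides`` are applied
    on top of the preset's CircuitParams fields.
    """
    d = scenario_defaults(name)
    if duration is None:
        duration = d["nic_duration_s"]
    blockade = replace(
        blockade,
        glu=blockade.glu or d.get("glu_blocked", False),
        gaba=blockade.gaba or d.get("gaba_blocked", False),
    )
    circuit = CircuitParams(
        r=circuit_overrides.pop("r", d["r"]),
        nu_ach=circuit_overrides.pop("nu_ach", d["nu_ach_uM"]),
        nu_glu=circuit_overrides.pop("nu_glu", d["nu_glu"]),
        **circuit_overrides,
    )
    apps = ()
    if nic_dose > 0:
        apps = (NicotineApplication(onset=60.0, duration=duration,
                                    concentration=nic_dose),)
    return Protocol(circuit=circuit, applications=apps, blockade=blockade,
                    eta=eta, horizon=horizon, dt=dt, label=name)


def in_vitro_ipsc(
    nic_dose: float = 1.0,
    blockade: BlockadeFlags = BlockadeFlags(),
    horizon: float | None = None,
    **overrides,
) -> SimResult:
    """Slice IPSC protocol: Glu transmission blocked, GABA input read out.

    Returns the full SimResult; the relative GABAergic input change is
    ``result.column('i_gaba') / result.baseline['i_gaba'] - 1``.
    """
    proto = scenario_protocol("in_vitro_ipsc", nic_dose=nic_dose,
                              blockade=blockade, horizon=horizon, **overrides)
    return run_protocol(proto)


def in_vitro_epsc(
    nic_dose: float = 1.0,
    blockade: BlockadeFlags = BlockadeFlags(),
    horizon: float | None = None,
    **overrides,
) -> SimResult:
    """Slice EPSC protocol: GABA contribution blocked, Glu input read out."""
    proto = scenario_protocol("in_vitro_epsc", nic_dose=nic_dose,
                              blockade=blockade, horizon=horizon, **overrides)
    return run_protocol(proto)


# ---------------------------------------------------------------------------
# sweeps

_SWEEPABLE = ("nu_ach", "nic_dose", "r", "eta")


def _apply_parameter(proto: Protocol, parameter: str, value: float) -> Protocol:
    if parameter == "nu_ach":
        return replace(proto, circuit=replace(proto.circuit, nu_ach=value))
    if parameter == "r":
        return replace(proto, circuit=replace(proto.circuit, r=value))
    if parameter == "eta":
        return replace(proto, eta=value)
    if parameter == "nic_dose":
        apps = tuple(replace(a, concentration=value) for a in proto.applications)
        return replace(proto, applications=apps)
    raise ValueError(f"parameter must be one of {_SWEEPABLE}")


def sweep(
    proto: Protocol,
    parameter: str,
    grid: Iterable[float],
    population: str = "da",
) -> pd.DataFrame:
    """Run a protocol across a parameter grid and summarize each response.

    One row per grid point with the peak relative change, time of peak, net
    change integral, and width-at-half-maximum of the chosen population's
    normalized trace.  Per-point failures are recorded in the ``error``
    column and the sweep continues.
    """
    from .metrics import compute_metrics

    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    rows = []
    for value in grid:
        row = {parameter: value, "error": ""}
        try:
            result = run_protocol(_apply_parameter(proto, parameter, value))
            m = compute_metrics(result, population)
            row.update(
                peak_rel_change_pct=m.peak_rel_change,
                time_of_peak_s=m.time_of_peak,
                net_change_integral=m.net_change_integral,
                halfmax_duration_s=m.halfmax_duration,
                post_washout_min_pct=m.post_washout_min,
            )
        except (ValueError, FloatingPointError, KeyError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def eta_sweep(
    scenario: str,
    eta_grid: Iterable[float],
    nic_dose: float = 1.0,
    **kwargs,
) -> dict[float, SimResult]:
    """DA/GABA responses for a grid of ACh-desensitization fractions η."""
    out = {}
    for eta in eta_grid:
        if not 0.0 <= eta <= 1.0:
            raise ValueError("eta values must be in [0, 1]")
        proto = scenario_protocol(scenario, nic_dose=nic_dose, eta=eta, **kwargs)
        out[eta] = run_protocol(proto)
    return out
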