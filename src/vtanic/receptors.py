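"""Two-gate kinetics of nicotinic acetylcholine receptors (nAChRs).

The receptor is described by two independent gating variables:

* ``a`` — fraction of receptors with the *activation* gate open, driven by
  acetylcholine (ACh) and nicotine (Nic) on a millisecond time scale;
* ``s`` — fraction of receptors in the *sensitized* (i.e. not desensitized)
  state, driven into desensitization by nicotine — and by ACh when
  acetylcholinesterase activity is low (``eta`` > 0) — on a
  seconds-to-minutes time scale.

Only receptors that are simultaneously activated and sensitized conduct, so
the normalized open fraction is the product ``a * s``.  Both gates relax
exponentially toward Hill-type steady states:

    a_inf(c) = c^n_a / (EC50^n_a + c^n_a),       c = ACh + alpha * Nic
    s_inf(c) = IC50^n_d / (IC50^n_d + c^n_d),    c = Nic + eta * ACh

with a constant activation time constant ``tau_a`` and a
concentration-dependent desensitization time constant

    tau_s(c) = tau_0 + (tau_max - tau_0) * K_tau^n_tau / (K_tau^n_tau + c^n_tau)

that falls from ``tau_max`` (recovery in the absence of ligand) to ``tau_0``
(fastest desensitization at saturating agonist).  ``alpha`` > 1 expresses the
higher potency of nicotine relative to ACh in evoking a response, so the
activation drive is measured in ACh-equivalent µM while the desensitization
drive is in nicotine-equivalent µM (IC50 values are tabulated "by Nic").

Internal canonical units are seconds and µM throughout.  Two parameter
presets, ``a4b2`` (high-affinity, slowly recovering) and ``a7``
(low-affinity, rapidly desensitizing), ship with the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Callable

import numpy as np

__all__ = [
    "ReceptorParams",
    "ReceptorState",
    "AgonistLevels",
    "load_preset",
    "save_params",
    "load_params",
    "activation_drive",
    "desensitization_drive",
    "a_inf",
    "s_inf",
    "tau_s",
    "step_receptor",
    "open_fraction",
    "pulse_trace",
    "peak_pulse_response",
    "half_max_concentration",
    "pretreatment_reduction",
]


@dataclass(frozen=True)
class ReceptorParams:
    """Kinetic and pharmacological constants of one nAChR subtype.

    Times in seconds, concentrations in µM.  ``eta`` is the fraction of the
    ACh concentration that contributes to desensitization (0 = ACh is
    hydrolyzed too fast to desensitize, 1 = ACh and Nic desensitize to equal
    amounts).
    """

    subtype: str
    ec50: float      # half-maximum activation concentration (ACh), µM
    alpha: float     # nicotine potency factor (ACh-equivalents per µM Nic), > 1
    n_a: float       # Hill coefficient of activation
    ic50: float      # half-maximum desensitization concentration (Nic), µM
    n_d: float       # Hill coefficient of desensitization
    tau_a: float     # activation time constant, s
    k_tau: float     # midpoint concentration of tau_s sigmoid, µM
    n_tau: float     # Hill coefficient of the tau_s sigmoid
    tau_max: float   # recovery time constant at zero ligand, s
    tau_0: float     # fastest desensitization time constant, s
    eta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ec50", "ic50", "tau_a", "k_tau", "tau_max", "tau_0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("n_a", "n_d", "n_tau"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be a positive Hill coefficient")
        if not self.alpha > 1:
            raise ValueError("alpha must exceed 1 (nicotine is the more potent agonist)")
        if not self.tau_0 < self.tau_max:
            raise ValueError("tau_0 must be smaller than tau_max")
        if not self.tau_a < self.tau_0:
            raise ValueError("tau_a must be much smaller than tau_0 "
                             "(activation is the fast gate)")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must be in [0, 1]")

    def with_eta(self, eta: float) -> "ReceptorParams":
        return replace(self, eta=eta)


@dataclass(frozen=True)
class ReceptorState:
    """Instantaneous gate fractions; ``open_fraction`` is their product."""

    a: float
    s: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.s)):
            raise FloatingPointError("non-finite receptor state")
        if not (0.0 <= self.a <= 1.0 and 0.0 <= self.s <= 1.0):
            raise ValueError("gate fractions must lie in [0, 1]")


@dataclass(frozen=True)
class AgonistLevels:
    """Agonist concentrations at the receptor, µM.

    ``ach`` is the mean endogenous cholinergic input rate expressed as a
    concentration; ``nic`` is nicotine at the receptor site.
    """

    ach: float = 0.0
    nic: float = 0.0

    def __post_init__(self) -> None:
        if self.ach < 0 or self.nic < 0:
            raise ValueError("agonist concentrations must be non-negative")


# ---------------------------------------------------------------------------
# parameter presets and (de)serialization

_UNIT_FIELDS = {
    # json key           attribute   factor json->internal (s, µM)
    "EC50_uM": ("ec50", 1.0),
    "alpha": ("alpha", 1.0),
    "n_a": ("n_a", 1.0),
    "IC50_uM": ("ic50", 1.0),
    "n_d": ("n_d", 1.0),
    "tau_a_ms": ("tau_a", 1e-3),
    "K_tau_uM": ("k_tau", 1.0),
    "n_tau": ("n_tau", 1.0),
    "tau_max_min": ("tau_max", 60.0),
    "tau_0_ms": ("tau_0", 1e-3),
    "eta": ("eta", 1.0),
}


def _params_from_dict(d: dict) -> ReceptorParams:
    unknown = set(d) - set(_UNIT_FIELDS) - {"subtype"}
    if unknown:
        raise ValueError(f"unknown receptor parameter keys: {sorted(unknown)}")
    kwargs = {"subtype": d["subtype"]}
    for key, (attr, factor) in _UNIT_FIELDS.items():
        if key in d:
            kwargs[attr] = d[key] * factor
    return ReceptorParams(**kwargs)


def _params_to_dict(p: ReceptorParams) -> dict:
    d = {"subtype": p.subtype}
    for key, (attr, factor) in _UNIT_FIELDS.items():
        d[key] = getattr(p, attr) / factor
    return d


def load_preset(name: str) -> ReceptorParams:
    """Load a shipped parameter preset (``"a4b2"`` or ``"a7"``)."""
    ref = resources.files("vtanic.presets").joinpath(f"{name}.json")
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:
        raise KeyError(f"no receptor preset named {name!r}") from exc
    return _params_from_dict(json.loads(text))


def load_params(path) -> ReceptorParams:
    with open(path) as fh:
        return _params_from_dict(json.load(fh))


def save_params(p: ReceptorParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(_params_to_dict(p), fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# steady-state relations

def activation_drive(levels: AgonistLevels, p: ReceptorParams) -> float:
    """Effective activating concentration, ACh-equivalent µM: ACh + alpha*Nic."""
    return levels.ach + p.alpha * levels.nic


def desensitization_drive(levels: AgonistLevels, p: ReceptorParams) -> float:
    """Effective desensitizing concentration, Nic-equivalent µM: Nic + eta*ACh."""
    return levels.nic + p.eta * levels.ach


def a_inf(c_act, p: ReceptorParams):
    """Steady-state activation, Hill function of the activation drive."""
    c = np.asarray(c_act, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    cn = c ** p.n_a
    out = cn / (p.ec50 ** p.n_a + cn)
    return float(out) if out.ndim == 0 else out


def s_inf(c_des, p: ReceptorParams):
    """Steady-state sensitization; decreasing Hill function, s_inf(0) = 1."""
    c = np.asarray(c_des, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    kn = p.ic50 ** p.n_d
    out = kn / (kn + c ** p.n_d)
    return float(out) if out.ndim == 0 else out


def tau_s(c_des, p: ReceptorParams):
    """Concentration-dependent desensitization/recovery time constant (s)."""
    c = np.asarray(c_des, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    kn = p.k_tau ** p.n_tau
    out = p.tau_0 + (p.tau_max - p.tau_0) * kn / (kn + c ** p.n_tau)
    return float(out) if out.ndim == 0 else out


def open_fraction(state: ReceptorState) -> float:
    """Normalized conducting fraction a*s (desensitized receptors pass no current)."""
    return state.a * state.s


def equilibrium_state(levels: AgonistLevels, p: ReceptorParams) -> ReceptorState:
    """Analytic steady state of both gates at constant agonist levels."""
    return ReceptorState(
        a=a_inf(activation_drive(levels, p), p),
        s=s_inf(desensitization_drive(levels, p), p),
    )


# ---------------------------------------------------------------------------
# time stepping

def step_receptor(
    state: ReceptorState,
    levels: AgonistLevels,
    dt: float,
    p: ReceptorParams,
    qss_activation: bool = False,
) -> ReceptorState:
    """Advance both gates by ``dt`` seconds under piecewise-constant agonists.

    The update is the exact exponential relaxation toward the steady state,
    so it is unconditionally stable for any ``dt``.  With ``qss_activation``
    the fast gate is slaved to its steady state (appropriate when resolving
    only the seconds-to-minutes desensitization dynamics).
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    ca = activation_drive(levels, p)
    cd = desensitization_drive(levels, p)
    ai = a_inf(ca, p)
    si = s_inf(cd, p)
    if qss_activation:
        a = ai
    else:
        a = ai + (state.a - ai) * math.exp(-dt / p.tau_a)
    s = si + (state.s - si) * math.exp(-dt / tau_s(cd, p))
    if not (math.isfinite(a) and math.isfinite(s)):
        raise FloatingPointError("receptor integration produced non-finite state")
    return ReceptorState(a=a, s=s)


def pulse_trace(
    p: ReceptorParams,
    ach_pulse: float,
    pulse_s: float = 0.2,
    nic_background: float = 0.0,
    dt: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Open-fraction trace during an ACh pulse on a nicotine background.

    The receptor is pre-equilibrated analytically with (ACh=0,
    Nic=``nic_background``); activation is integrated with its full dynamics
    (no quasi-steady-state shortcut).  Returns ``(t, open_fraction)`` over the
    pulse.
    """
    if not pulse_s > 0:
        raise ValueError("pulse duration must be positive")
    rest = AgonistLevels(ach=0.0, nic=nic_background)
    state = equilibrium_state(rest, p)
    levels = AgonistLevels(ach=ach_pulse, nic=nic_background)
    n = int(round(pulse_s / dt))
    t = np.arange(n + 1) * dt
    a = np.empty(n + 1)
    s = np.empty(n + 1)
    a[0], s[0] = state.a, state.s
    for i in range(n):
        state = step_receptor(state, levels, dt, p)
        a[i + 1], s[i + 1] = state.a, state.s
    return t, a * s


def peak_pulse_response(
    ach_pulse: float,
    p: ReceptorParams,
    pulse_s: float = 0.2,
    nic_background: float = 0.0,
    dt: float = 1e-4,
) -> float:
    """Maximum open fraction during a brief ACh pulse (default 200 ms)."""
    _, open_frac = pulse_trace(p, ach_pulse, pulse_s, nic_background, dt)
    return float(open_frac.max())


def half_max_concentration(
    curve: Callable[[float], float],
    c_lo: float = 1e-3,
    c_hi: float = 1e5,
    rel_tol: float = 1e-4,
) -> float:
    """Concentration at 50% of a saturating dose–response curve's maximum.

    ``curve`` maps concentration (µM) to response.  The asymptotic maximum is
    probed at ``c_hi``; the curve must be monotone increasing and saturating
    over the scanned range, otherwise a ValueError is raised.  Bisection to
    ``rel_tol`` relative accuracy.
    """
    grid = np.geomspace(c_lo, c_hi, 9)
    vals = [curve(c) for c in grid]
    if any(b < a - 1e-9 * abs(a) for a, b in zip(vals, vals[1:])):
        raise ValueError("dose-response curve is not monotone over the scanned range")
    top = vals[-1]
    if top <= 0 or (top - vals[-2]) > 0.05 * top:
        raise ValueError("dose-response curve does not saturate on the scanned range")
    target = 0.5 * top
    lo, hi = c_lo, c_hi
    if curve(lo) > target:
        raise ValueError("half-maximum lies below the scanned range")
    while (hi - lo) > rel_tol * hi:
        mid = math.sqrt(lo * hi)
        if curve(mid) < target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def pretreatment_reduction(
    p: ReceptorParams,
    nic_pre: float = 0.5,
    pulse_s: float = 0.2,
    dt: float = 1e-4,
) -> float:
    """Percent reduction of the half-maximal ACh pulse response by nicotine.

    Locates the ACh concentration that gives the half-maximal peak response
    to a 200 ms pulse with no nicotine, then re-simulates the identical pulse
    with the receptor pre-equilibrated to a constant ``nic_pre`` µM
    background.  Returns ``100 * (1 - peak_with / peak_without)``.
    """
    if nic_pre < 0:
        raise ValueError("nic_pre must be non-negative")
    if nic_pre == 0:
        return 0.0
    c_half = half_max_concentration(
        lambda c: peak_pulse_response(c, p, pulse_s, 0.0, dt)
    )
    peak_without = peak_pulse_response(c_half, p, pulse_s, 0.0, dt)
    peak_with = peak_pulse_response(c_half, p, pulse_s, nic_pre, dt)
    return 100.0 * (1.0 - peak_with / peak_without)
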