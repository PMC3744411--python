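"""Mean-field model of the VTA dopamine/GABA microcircuit.

Two neural populations are described by their mean firing rates: the
dopaminergic output population (``nu_da``) and the local GABAergic
interneuron population (``nu_g``).  Each rate relaxes with a membrane time
constant toward a threshold-linear transfer of its total input current:

    tau_da * d(nu_da)/dt = -nu_da + Phi(I_Glu + r * I_a4b2 - I_GABA + I_intr + I0_da)
    tau_g  * d(nu_g)/dt  = -nu_g  + Phi(I_Glu + (1 - r) * I_a4b2 + I0_g)

with Phi(I) = max(I, 0).  The currents are built from the receptor open
fractions and the afferent drives:

* ``I_GABA = w_gaba * nu_g`` — local inhibition of DA cells;
* ``I_Glu  = w_glu * (nu_glu + a7 - nu_glu * a7)`` — glutamatergic input,
  a probabilistic-OR saturation of afferent firing and presynaptic α7 nAChR
  activation (either input alone can fully activate transmission);
* ``I_a4b2 = w_a4b2 * a4b2`` — somatic α4β2 nAChR current, apportioned by
  ``r`` between DA cells (fraction ``r``) and GABA cells (fraction ``1-r``).
  ``r = 1`` places all α4β2 action on DA neurons (pure direct stimulation),
  ``r = 0`` on GABA neurons (pure disinhibition substrate).

``I_intr`` is an intrinsic pacemaker current of DA cells; ``I0_da`` and
``I0_g`` are constant background currents standing in for nicotine-
insensitive inputs.  With the default unit weights the circuit is linear
whenever no rate is clipped at zero, which makes the steady state solvable
in closed form (`steady_state`) and yields the r-cancellation property: the
steady-state DA response to a change in α4β2 drive is proportional to
(2r - 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .receptors import (
    AgonistLevels,
    ReceptorParams,
    ReceptorState,
    a_inf,
    equilibrium_state,
    s_inf,
    tau_s,
)

__all__ = [
    "CircuitParams",
    "CircuitState",
    "BlockadeFlags",
    "phi",
    "glu_drive",
    "assemble_currents",
    "step_circuit",
    "steady_state",
    "run_trajectory",
]


@dataclass(frozen=True)
class CircuitParams:
    """Connectivity, afferent drives, and background currents (a.u., s, µM)."""

    r: float = 0.5           # fraction of α4β2 effect delivered to DA cells
    nu_ach: float = 0.1      # endogenous cholinergic input rate, µM equivalent
    nu_glu: float = 0.0      # normalized afferent glutamatergic activity in [0, 1]
    w_gaba: float = 1.0
    w_glu: float = 1.0
    w_a4b2: float = 1.0
    i_intr: float = 1.0      # intrinsic DA pacemaker current
    i0_da: float = 0.0
    i0_g: float = 0.0
    tau_da: float = 0.020    # membrane time constant, s
    tau_g: float = 0.020

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must be in [0, 1]")
        if not 0.0 <= self.nu_glu <= 1.0:
            raise ValueError("nu_glu must be in [0, 1]")
        if self.nu_ach < 0:
            raise ValueError("nu_ach must be non-negative")
        for name in ("w_gaba", "w_glu", "w_a4b2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tau_da <= 0 or self.tau_g <= 0:
            raise ValueError("membrane time constants must be positive")


@dataclass(frozen=True)
class BlockadeFlags:
    """Pharmacological blockade / knockout switches.

    A blocked receptor subtype contributes zero open fraction to the
    currents (antagonist and knockout are treated identically); blocked
    transmission pathways have their current zeroed.
    """

    a4b2: bool = False
    a7: bool = False
    glu: bool = False
    gaba: bool = False


@dataclass(frozen=True)
class CircuitState:
    """Population rates plus the receptor gate states they depend on."""

    nu_da: float
    nu_g: float
    r_a4b2: ReceptorState
    r_a7: ReceptorState

    def __post_init__(self) -> None:
        if not (math.isfinite(self.nu_da) and math.isfinite(self.nu_g)):
            raise FloatingPointError("non-finite population rate")
        if self.nu_da < 0 or self.nu_g < 0:
            raise ValueError("population rates must be non-negative")


def phi(i: float) -> float:
    """Threshold-linear current-to-rate transfer function."""
    return i if i > 0.0 else 0.0


def glu_drive(nu_glu: float, a7_open: float) -> float:
    """Probabilistic-OR saturation of glutamatergic transmission.

    Either afferent firing or presynaptic α7 activation alone can fully
    activate transmission; the combination saturates at 1.
    """
    if not (0.0 <= nu_glu <= 1.0 and 0.0 <= a7_open <= 1.0):
        raise ValueError("glu_drive inputs must be fractions in [0, 1]")
    return nu_glu + a7_open - nu_glu * a7_open


def assemble_currents(
    state: CircuitState,
    p: CircuitParams,
    blockade: BlockadeFlags = BlockadeFlags(),
) -> tuple[float, float, float, float, float]:
    """Input currents (i_da, i_g, i_gaba, i_glu, i_a4b2) for the present state."""
    open4 = 0.0 if blockade.a4b2 else state.r_a4b2.a * state.r_a4b2.s
    open7 = 0.0 if blockade.a7 else state.r_a7.a * state.r_a7.s
    i_glu = 0.0 if blockade.glu else p.w_glu * glu_drive(p.nu_glu, open7)
    i_gaba = 0.0 if blockade.gaba else p.w_gaba * state.nu_g
    i_a4b2 = p.w_a4b2 * open4
    i_da = i_glu + p.r * i_a4b2 - i_gaba + p.i_intr + p.i0_da
    i_g = i_glu + (1.0 - p.r) * i_a4b2 + p.i0_g
    return i_da, i_g, i_gaba, i_glu, i_a4b2


def step_circuit(
    state: CircuitState,
    p: CircuitParams,
    a4b2: ReceptorParams,
    a7: ReceptorParams,
    nic: float,
    dt: float,
    blockade: BlockadeFlags = BlockadeFlags(),
    qss_activation: bool = True,
) -> CircuitState:
    """Advance the coupled receptor/circuit state by one step of ``dt`` s.

    The receptor gates advance first (exact exponential updates), then both
    population rates relax exponentially toward the threshold-linear
    transfer of the currents assembled from the *pre-step* rates.  The
    scheme is deterministic and unconditionally stable.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    from .receptors import step_receptor  # local import avoids cycle at module load

    levels = AgonistLevels(ach=p.nu_ach, nic=nic)
    r4 = step_receptor(state.r_a4b2, levels, dt, a4b2, qss_activation)
    r7 = step_receptor(state.r_a7, levels, dt, a7, qss_activation)
    i_da, i_g, _, _, _ = assemble_currents(
        replace(state, r_a4b2=r4, r_a7=r7), p, blockade
    )
    e_da = math.exp(-dt / p.tau_da)
    e_g = math.exp(-dt / p.tau_g)
    nu_g = phi(i_g) + (state.nu_g - phi(i_g)) * e_g
    nu_da = phi(i_da) + (state.nu_da - phi(i_da)) * e_da
    if not (math.isfinite(nu_da) and math.isfinite(nu_g)):
        raise FloatingPointError("circuit integration produced non-finite state")
    return CircuitState(nu_da=nu_da, nu_g=nu_g, r_a4b2=r4, r_a7=r7)


def steady_state(
    p: CircuitParams,
    a4b2: ReceptorParams,
    a7: ReceptorParams,
    nic: float = 0.0,
    blockade: BlockadeFlags = BlockadeFlags(),
) -> CircuitState:
    """Analytic fixed point of the circuit at constant agonist levels.

    The GABA population is feedforward (it receives no DA or GABA input), so
    its rate follows directly; the DA rate then follows with clipping at
    zero through the threshold-linear transfer.  Used as the t=0 baseline of
    every protocol.
    """
    levels = AgonistLevels(ach=p.nu_ach, nic=nic)
    r4 = equilibrium_state(levels, a4b2)
    r7 = equilibrium_state(levels, a7)
    open4 = 0.0 if blockade.a4b2 else r4.a * r4.s
    open7 = 0.0 if blockade.a7 else r7.a * r7.s
    i_glu = 0.0 if blockade.glu else p.w_glu * glu_drive(p.nu_glu, open7)
    i_a4b2 = p.w_a4b2 * open4
    nu_g = phi(i_glu + (1.0 - p.r) * i_a4b2 + p.i0_g)
    i_gaba = 0.0 if blockade.gaba else p.w_gaba * nu_g
    nu_da = phi(i_glu + p.r * i_a4b2 - i_gaba + p.i_intr + p.i0_da)
    return CircuitState(nu_da=nu_da, nu_g=nu_g, r_a4b2=r4, r_a7=r7)


def _relax(target: np.ndarray, y0: float, decay: float) -> np.ndarray:
    """Exponential relaxation scan: y[i] = d*y[i-1] + (1-d)*target[i].

    ``target`` must already be aligned so that ``target[i]`` is the value
    toward which the variable relaxes during the step ending at index i;
    ``target[0]`` is ignored.
    """
    if len(target) == 1:
        return np.array([y0])
    z, _ = lfilter([1.0 - decay], [1.0, -decay], target[1:], zi=[decay * y0])
    return np.concatenate(([y0], z))


def _gate_scan(target: np.ndarray, decay: np.ndarray, y0: float) -> np.ndarray:
    """Relaxation scan with per-step decay factors (time-varying tau_s)."""
    out = np.empty_like(target)
    y = y0
    out[0] = y
    t = target
    d = decay
    for i in range(1, len(target)):
        y = t[i - 1] + (y - t[i - 1]) * d[i - 1]
        out[i] = y
    return out


def run_trajectory(
    p: CircuitParams,
    a4b2: ReceptorParams,
    a7: ReceptorParams,
    nic_site: np.ndarray,
    dt: float,
    blockade: BlockadeFlags = BlockadeFlags(),
    qss_activation: bool = True,
    init: CircuitState | None = None,
) -> dict[str, np.ndarray]:
    """Integrate the full model along a nicotine concentration time course.

    ``nic_site[i]`` is the nicotine concentration at the receptor site held
    constant over step i.  The per-step updates are identical to
    `step_circuit`; the implementation is vectorized (the receptor drives
    depend only on the prescribed nicotine trace, and both populations are
    feedforward in the rates, so the scans reduce to linear recurrences).
    Returns a dict of aligned arrays, one entry per output column.
    """
    nic = np.asarray(nic_site, dtype=float)
    if nic.ndim != 1 or len(nic) == 0:
        raise ValueError("nic_site must be a non-empty 1-d array")
    if np.any(nic < 0) or not np.all(np.isfinite(nic)):
        raise ValueError("nicotine trace must be finite and non-negative")
    if not dt > 0:
        raise ValueError("dt must be positive")
    if init is None:
        init = steady_state(p, a4b2, a7, nic=float(nic[0]), blockade=blockade)

    out: dict[str, np.ndarray] = {"nic_site_uM": nic}
    gates: dict[str, np.ndarray] = {}
    for label, rp, state0 in (
        ("a4b2", a4b2, init.r_a4b2),
        ("a7", a7, init.r_a7),
    ):
        c_act = p.nu_ach + rp.alpha * nic
        c_des = nic + rp.eta * p.nu_ach
        ainf = np.atleast_1d(a_inf(c_act, rp))
        sinf = np.atleast_1d(s_inf(c_des, rp))
        if qss_activation:
            # the fast gate is slaved to the level held during the step,
            # i.e. a[i] = a_inf(nic[i-1]); matches step_receptor semantics
            a = np.concatenate(([state0.a], ainf[:-1]))
        else:
            ea = math.exp(-dt / rp.tau_a)
            a = _relax(np.concatenate(([0.0], ainf[:-1])), state0.a, ea)
        dec = np.exp(-dt / np.atleast_1d(tau_s(c_des, rp)))
        s = _gate_scan(sinf, dec, state0.s)
        gates[label] = a * s
        out[f"a_{label}"] = np.asarray(a, dtype=float)
        out[f"s_{label}"] = s

    open4 = np.zeros_like(nic) if blockade.a4b2 else gates["a4b2"]
    open7 = np.zeros_like(nic) if blockade.a7 else gates["a7"]
    if blockade.glu:
        i_glu = np.zeros_like(nic)
    else:
        i_glu = p.w_glu * (p.nu_glu + open7 - p.nu_glu * open7)
    i_a4b2 = p.w_a4b2 * open4

    # rates relax toward Phi of the currents assembled from the post-step
    # gates and the pre-step rates, exactly as in step_circuit
    i_g_in = i_glu + (1.0 - p.r) * i_a4b2 + p.i0_g
    nu_g = _relax(np.maximum(i_g_in, 0.0), init.nu_g, math.exp(-dt / p.tau_g))
    i_gaba = np.zeros_like(nic) if blockade.gaba else p.w_gaba * nu_g
    base_da = i_glu + p.r * i_a4b2 + p.i_intr + p.i0_da
    i_da_in = base_da.copy()
    i_da_in[1:] -= i_gaba[:-1]          # inhibition lags one step (pre-step rate)
    i_da_in[0] -= i_gaba[0]
    nu_da = _relax(np.maximum(i_da_in, 0.0), init.nu_da, math.exp(-dt / p.tau_da))

    if not (np.all(np.isfinite(nu_da)) and np.all(np.isfinite(nu_g))):
        raise FloatingPointError("circuit integration produced non-finite rates")

    out.update(i_glu=i_glu, i_gaba=i_gaba, i_a4b2=i_a4b2, nu_da=nu_da, nu_g=nu_g)
    return out
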