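"""Summary metrics of simulated responses and afferent-drive calibration.

Metrics are computed on traces normalized to the analytic pre-application
baseline: peak relative change, time of the peak, signed net-change
integral, width of the elevation at half of its maximum, and the deepest
post-washout undershoot.  The net-change integral runs from the application
onset to the end of the record; protocols default to a recovery horizon of
6 recovery time constants after the last washout, which captures more than
99% of the exponential tail, so the integral is effectively the total
signed area of the response.

The calibration routines anchor the two free afferent drives of the
slice-like protocols by bisection: the cholinergic rate ``nu_ach`` such
that 1 µM nicotine evokes a 300% peak increase of the GABAergic input to DA
cells, and the glutamatergic rate ``nu_glu`` such that the same dose evokes
a 325% peak increase of the glutamatergic input.  `critical_ach_threshold`
locates, again by bisection, the cholinergic rate at which the net DA
response to nicotine changes sign in the direct-stimulation configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .protocols import SimResult, run_protocol, scenario_protocol

__all__ = [
    "ResponseMetrics",
    "compute_metrics",
    "critical_ach_threshold",
    "calibrate_nu_ach_invitro",
    "calibrate_nu_glu_invitro",
    "elevation_duration",
]

_POPULATIONS = {
    "da": ("nu_da", "nu_da"),
    "gaba": ("nu_g", "nu_g"),
    "i_gaba": ("i_gaba", "i_gaba"),
    "i_glu": ("i_glu", "i_glu"),
}


@dataclass(frozen=True)
class ResponseMetrics:
    """Summary of one normalized response trace."""

    peak_rel_change: float      # %, max of 100*(x/baseline - 1) after onset
    time_of_peak: float         # s
    net_change_integral: float  # signed integral of (x - baseline) dt, onset→end
    halfmax_duration: float     # s between first/last crossing of half-elevation
    post_washout_min: float     # %, deepest relative undershoot after washout
    degenerate: bool = False    # flat trace or zero baseline


def _crossing_times(t: np.ndarray, x: np.ndarray, level: float) -> np.ndarray:
    """Linearly interpolated times where x crosses ``level``."""
    above = x >= level
    idx = np.nonzero(above[1:] != above[:-1])[0]
    if len(idx) == 0:
        return np.array([])
    x0, x1 = x[idx], x[idx + 1]
    frac = (level - x0) / (x1 - x0)
    return t[idx] + frac * (t[idx + 1] - t[idx])


def elevation_duration(t: np.ndarray, x: np.ndarray, baseline: float) -> float:
    """Width of the elevation above baseline at half of its maximum.

    The duration is the time between the first and the last crossing of
    ``baseline + peak_elevation/2``; zero if the trace never rises above
    baseline.
    """
    peak = float(np.max(x) - baseline)
    if peak <= 0:
        return 0.0
    crossings = _crossing_times(t, x, baseline + 0.5 * peak)
    if len(crossings) == 0:
        return 0.0
    return float(crossings[-1] - crossings[0])


def compute_metrics(result: SimResult, population: str = "da") -> ResponseMetrics:
    """Summary metrics of one population's response, relative to baseline."""
    if population not in _POPULATIONS:
        raise KeyError(f"population must be one of {sorted(_POPULATIONS)}")
    col, base_key = _POPULATIONS[population]
    t = result.column("time_s")
    x = result.column(col)
    baseline = result.baseline[base_key]
    onset = result.onset
    washout = result.washout
    if baseline <= 1e-12 or float(np.max(np.abs(x - baseline))) < 1e-9:
        return ResponseMetrics(0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)

    after = t >= onset
    ta, xa = t[after], x[after]
    rel = xa / baseline - 1.0
    i_peak = int(np.argmax(rel))
    net = float(np.trapezoid(xa - baseline, ta))
    duration = elevation_duration(ta, xa, baseline)
    post = t >= washout
    post_min = float(np.min(x[post] / baseline - 1.0)) if post.any() else 0.0
    return ResponseMetrics(
        peak_rel_change=100.0 * float(rel[i_peak]),
        time_of_peak=float(ta[i_peak]),
        net_change_integral=net,
        halfmax_duration=duration,
        post_washout_min=100.0 * post_min,
    )


def _bisect(
    f: Callable[[float], float],
    lo: float,
    hi: float,
    tol: float,
    increasing: bool | None = None,
) -> float:
    """Bisection for the root of f on [lo, hi]; bracket is sign-checked."""
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise ValueError(
            f"no sign change on bracket [{lo}, {hi}]: f(lo)={flo:.4g}, f(hi)={fhi:.4g}"
        )
    rising = fhi > 0 if increasing is None else increasing
    while (hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0.0:
            return mid
        if (fm > 0) == rising:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def critical_ach_threshold(
    nic_dose: float = 1.0,
    r: float = 0.8,
    duration: float | None = None,
    lo: float = 0.05,
    hi: float = 2.0,
    tol: float = 0.005,
    dt: float = 0.010,
) -> float:
    """Cholinergic rate (µM) at which the net DA response to Nic changes sign.

    In the direct-stimulation configuration (r > 0.5) the net (time-
    integrated) DA change is positive below this rate and negative above
    it: nicotine's added activation of α4β2 receptors on DA cells wins at
    low ACh, while its desensitization of the ACh-driven current wins at
    high ACh.  Bisection of the net-change integral over ``nu_ach`` to an
    accuracy of ``tol`` µM.
    """
    if not r > 0.5:
        raise ValueError("the threshold is an upper bound only for r > 0.5")

    def net(nu_ach: float) -> float:
        proto = scenario_protocol(
            "direct_stimulation", nic_dose=nic_dose, duration=duration,
            r=r, nu_ach=nu_ach, dt=dt,
        )
        return compute_metrics(run_protocol(proto), "da").net_change_integral

    return _bisect(net, lo, hi, tol)


def _peak_increase_pct(result: SimResult, population: str) -> float:
    return compute_metrics(result, population).peak_rel_change


def calibrate_nu_ach_invitro(
    target_percent: float = 300.0,
    nic_dose: float = 1.0,
    lo: float = 0.02,
    hi: float = 3.0,
    tol_uM: float = 1e-5,
) -> float:
    """Cholinergic rate giving the target peak GABA-input increase in vitro.

    Runs the slice IPSC protocol (Glu blocked) at 1 µM nicotine and bisects
    over the constant ACh rate until the peak relative increase of the
    GABAergic input to DA cells matches ``target_percent``.  The peak
    increase decreases monotonically with the ACh rate (a stronger baseline
    drive leaves less headroom for further activation), so the root is
    unique on the bracket.
    """
    if target_percent <= 0:
        raise ValueError("target_percent must be positive; the zero-response "
                         "point is a degenerate baseline")

    def f(nu_ach: float) -> float:
        res = _run_invitro("in_vitro_ipsc", nic_dose, nu_ach=nu_ach)
        return _peak_increase_pct(res, "i_gaba") - target_percent

    return _bisect(f, lo, hi, tol_uM)


def calibrate_nu_glu_invitro(
    target_percent: float = 325.0,
    nic_dose: float = 1.0,
    lo: float = 1e-6,
    hi: float = 0.5,
    tol: float = 1e-9,
) -> float:
    """Afferent Glu rate giving the target peak Glu-input increase in vitro.

    Runs the slice EPSC protocol (GABA blocked) at 1 µM nicotine and bisects
    over the baseline glutamatergic rate.  Because the α7 open fraction at
    1 µM nicotine is far below one, a > 4-fold relative increase requires a
    small baseline rate.
    """
    if target_percent <= 0:
        raise ValueError("target_percent must be positive")

    def f(nu_glu: float) -> float:
        res = _run_invitro("in_vitro_epsc", nic_dose, nu_glu=nu_glu)
        return _peak_increase_pct(res, "i_glu") - target_percent

    return _bisect(f, lo, hi, tol)


def _run_invitro(name: str, nic_dose: float, **overrides) -> SimResult:
    # short horizon: the peak occurs during/shortly after the application
    proto = scenario_protocol(name, nic_dose=nic_dose, **overrides)
    proto = replace(proto, horizon=proto.last_application_end + 120.0)
    return run_protocol(proto)
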