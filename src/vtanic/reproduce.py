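"""Bundled experiment families for the ``reproduce`` CLI subcommand.

Each family re-runs one of the model's experiment groups —
receptor kinetics, slice input modulation, in-vivo scenario contrast,
prediction sweeps, receptor-balance sweeps, and ACh-driven desensitization
— and writes one CSV per panel with panel-labeled filenames.  These are
convenience drivers over the library; all quantities they emit are also
reachable through the public API.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import BlockadeFlags
from .metrics import compute_metrics
from .protocols import run_protocol, scenario_protocol, sweep
from .receptors import load_preset, peak_pulse_response, pretreatment_reduction

__all__ = ["FAMILIES"]


def _write(frame: pd.DataFrame, outdir: Path, name: str) -> Path:
    path = outdir / name
    frame.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    return path


def _maybe_plot(plot: bool, frames: dict[str, pd.DataFrame], outdir: Path,
                stem: str) -> list[Path]:
    if not plot:
        return []
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for name, frame in frames.items():
        fig, ax = plt.subplots(figsize=(5, 3.2))
        xcol = frame.columns[0]
        for col in frame.columns[1:]:
            if frame[col].dtype.kind in "fi":
                ax.plot(frame[xcol], frame[col], label=col)
        ax.set_xlabel(xcol)
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = outdir / f"{stem}_{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def receptor_kinetics(outdir: Path, plot: bool = False) -> list[Path]:
    """Receptor responses: wash-in traces, dose–response, Nic pretreatment."""
    written = []
    frames = {}
    for name in ("a4b2", "a7"):
        p = load_preset(name)
        # wash-in of 100 µM nicotine for 200 ms, then washout, full dynamics
        from .receptors import AgonistLevels, ReceptorState, step_receptor

        state = ReceptorState(a=0.0, s=1.0)
        levels_on = AgonistLevels(ach=0.0, nic=100.0)
        levels_off = AgonistLevels(ach=0.0, nic=0.0)
        dt = 1e-4
        rows = []
        for i in range(int(1.0 / dt)):
            tcur = i * dt
            state = step_receptor(state, levels_on if tcur < 0.2 else levels_off,
                                  dt, p)
            rows.append((tcur + dt, state.a, state.s, state.a * state.s))
        trace = pd.DataFrame(rows, columns=["time_s", "a", "s", "open_fraction"])
        written.append(_write(trace, outdir, f"panel_AB_washin_{name}.csv"))
        frames[f"washin_{name}"] = trace

        grid = np.geomspace(0.3, 3000.0, 13)
        peaks0 = [peak_pulse_response(c, p) for c in grid]
        peaks_nic = [peak_pulse_response(c, p, nic_background=0.5) for c in grid]
        dose = pd.DataFrame({"ach_uM": grid, "peak_control": peaks0,
                             "peak_with_0.5uM_nic": peaks_nic})
        written.append(_write(dose, outdir, f"panel_CD_dose_response_{name}.csv"))
        frames[f"dose_{name}"] = dose

    red = pd.DataFrame({
        "subtype": ["a4b2", "a7"],
        "halfmax_reduction_pct": [
            pretreatment_reduction(load_preset("a4b2"), 0.5),
            pretreatment_reduction(load_preset("a7"), 0.5),
        ],
    })
    written.append(_write(red, outdir, "panel_E_pretreatment_reduction.csv"))
    written += _maybe_plot(plot, frames, outdir, "receptor")
    return written


def slice_inputs(outdir: Path, plot: bool = False) -> list[Path]:
    """Slice IPSC/EPSC time courses and dose curves, with blockades."""
    written = []
    frames = {}
    for kind, pop in (("ipsc", "i_gaba"), ("epsc", "i_glu")):
        res = run_protocol(scenario_protocol(f"in_vitro_{kind}"))
        base = res.baseline[pop]
        trace = pd.DataFrame({
            "time_s": res.column("time_s"),
            "nic_site_uM": res.column("nic_site_uM"),
            f"{pop}_rel_change": res.column(pop) / base - 1.0,
        })
        written.append(_write(trace, outdir, f"panel_CD_{kind}_trace.csv"))
        frames[f"{kind}_trace"] = trace

        rows = []
        for dose in (0.1, 0.2, 0.5, 1.0):
            for label, flags in (("control", BlockadeFlags()),
                                 ("a4b2_blocked", BlockadeFlags(a4b2=True)),
                                 ("a7_blocked", BlockadeFlags(a7=True))):
                proto = scenario_protocol(f"in_vitro_{kind}", nic_dose=dose,
                                          blockade=flags)
                m = compute_metrics(run_protocol(proto), pop)
                rows.append({"nic_uM": dose, "condition": label,
                             "peak_increase_pct": m.peak_rel_change,
                             "post_washout_min_pct": m.post_washout_min})
        written.append(_write(pd.DataFrame(rows), outdir,
                              f"panel_EF_{kind}_dose_curve.csv"))
    written += _maybe_plot(plot, frames, outdir, "slice")
    return written


def invivo_scenarios(outdir: Path, plot: bool = False) -> list[Path]:
    """Direct stimulation vs disinhibition: traces, knockouts, durations."""
    written = []
    frames = {}
    for name in ("direct_stimulation", "disinhibition"):
        res = run_protocol(scenario_protocol(name, duration=120.0))
        trace = res.frame[["time_s", "nic_site_uM", "nu_da_norm", "nu_g_norm"]]
        written.append(_write(trace, outdir, f"panel_CF_{name}_trace.csv"))
        frames[name] = trace

        rows = []
        for label, flags in (("wild_type", BlockadeFlags()),
                             ("a4b2_ko", BlockadeFlags(a4b2=True)),
                             ("a7_ko", BlockadeFlags(a7=True))):
            m = compute_metrics(run_protocol(
                scenario_protocol(name, duration=120.0, blockade=flags)), "da")
            rows.append({"genotype": label,
                         "peak_da_increase_pct": m.peak_rel_change})
        written.append(_write(pd.DataFrame(rows), outdir,
                              f"panel_G_{name}_knockouts.csv"))

        rows = []
        for t_nic in (60.0, 120.0, 300.0):
            m = compute_metrics(run_protocol(
                scenario_protocol(name, duration=t_nic)), "da")
            rows.append({"t_nic_s": t_nic,
                         "halfmax_duration_min": m.halfmax_duration / 60.0})
        written.append(_write(pd.DataFrame(rows), outdir,
                              f"panel_H_{name}_durations.csv"))
    written += _maybe_plot(plot, frames, outdir, "invivo")
    return written


def prediction_sweeps(outdir: Path, plot: bool = False) -> list[Path]:
    """DA response vs cholinergic rate and vs nicotine dose, per scenario."""
    written = []
    ach_grid = [0.1, 0.5, 1.0, 1.5, 1.77, 2.0]
    nic_grid = [0.1, 0.2, 0.5, 1.0, 2.0, 3.0]
    for name in ("direct_stimulation", "disinhibition"):
        proto = scenario_protocol(name)
        written.append(_write(sweep(proto, "nu_ach", ach_grid), outdir,
                              f"panel_ABC_{name}_ach_sweep.csv"))
        written.append(_write(sweep(proto, "nic_dose", nic_grid), outdir,
                              f"panel_DEF_{name}_nic_sweep.csv"))
    return written


def receptor_balance(outdir: Path, plot: bool = False) -> list[Path]:
    """Net DA response vs r under low and high afferent input."""
    written = []
    from .protocols import scenario_defaults

    r_grid = [0.0, 0.2, 0.4, 0.5, 0.6, 0.8, 1.0]
    invitro = scenario_defaults("in_vitro_epsc")
    low = scenario_protocol("disinhibition", duration=120.0,
                            nu_ach=invitro["nu_ach_uM"],
                            nu_glu=invitro["nu_glu"])
    high = scenario_protocol("disinhibition", duration=120.0)
    written.append(_write(sweep(low, "r", r_grid), outdir,
                          "panel_A_invitro_r_sweep.csv"))
    written.append(_write(sweep(high, "r", r_grid), outdir,
                          "panel_B_invivo_r_sweep.csv"))
    return written


def ach_desensitization(outdir: Path, plot: bool = False) -> list[Path]:
    """GABA/DA responses when ACh also drives α4β2 desensitization (η > 0)."""
    written = []
    frames = {}
    for name in ("direct_stimulation", "disinhibition"):
        cols = {"time_s": None}
        for eta in (0.0, 0.5, 1.0):
            res = run_protocol(scenario_protocol(name, duration=120.0, eta=eta))
            if cols["time_s"] is None:
                cols["time_s"] = res.column("time_s")
            cols[f"nu_da_norm_eta{eta:g}"] = res.column("nu_da_norm")
            cols[f"nu_g_norm_eta{eta:g}"] = res.column("nu_g_norm")
        frame = pd.DataFrame(cols)
        written.append(_write(frame, outdir, f"panel_{name}_eta_traces.csv"))
        frames[name] = frame
    written += _maybe_plot(plot, frames, outdir, "eta")
    return written


FAMILIES = {
    "2": receptor_kinetics,
    "3": slice_inputs,
    "4": invivo_scenarios,
    "5": prediction_sweeps,
    "6": receptor_balance,
    "7": ach_desensitization,
}
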