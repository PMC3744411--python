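"""The endogenous cholinergic rate decides what nicotine does to DA output.

Sweeps the constant ACh input rate in both scenarios and locates the
direct-stimulation threshold rate below which nicotine produces a net DA
increase.
"""

from vtanic import critical_ach_threshold, scenario_protocol, sweep

grid = [0.1, 0.3, 0.5, 1.0, 1.77]
for name, metric in (("direct_stimulation", "peak_rel_change_pct"),
                     ("disinhibition", "net_change_integral")):
    table = sweep(scenario_protocol(name), "nu_ach", grid)
    print(f"{name} ({metric} vs ACh rate):")
    print(table[["nu_ach", metric]].to_string(index=False))

thr = critical_ach_threshold(nic_dose=1.0, r=0.8)
print(f"\ndirect stimulation: net DA increase requires ACh rate < {thr:.3f} uM")

# Direct stimulation weakens, disinhibition strengthens with rising ACh:
# measuring the sign of this dependence in vivo discriminates the pathways.
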