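"""Slice-like (in vitro) input modulation: IPSC and EPSC protocols.

Runs the two calibrated slice protocols at 1 µM nicotine, prints the peak
relative input changes and the post-washout undershoot, and shows the
blockade dissociation: the GABAergic modulation is α4β2-mediated, the
glutamatergic one is α7-mediated.
"""

from vtanic import BlockadeFlags, compute_metrics, in_vitro_epsc, in_vitro_ipsc

ipsc = compute_metrics(in_vitro_ipsc(), "i_gaba")
print(f"GABA input to DA cells: peak {ipsc.peak_rel_change:+.1f}% "
      f"(target 300%), post-washout {ipsc.post_washout_min:+.1f}%")

blocked = compute_metrics(in_vitro_ipsc(blockade=BlockadeFlags(a4b2=True)),
                          "i_gaba")
print(f"  with a4b2 blocked: degenerate flat trace = {blocked.degenerate}")

epsc = compute_metrics(in_vitro_epsc(), "i_glu")
print(f"Glu input to DA cells: peak {epsc.peak_rel_change:+.1f}% (target 325%)")

same = compute_metrics(in_vitro_epsc(blockade=BlockadeFlags(a4b2=True)), "i_glu")
print(f"  with a4b2 blocked: peak {same.peak_rel_change:+.1f}% (unchanged)")

flat = compute_metrics(in_vitro_epsc(blockade=BlockadeFlags(a7=True)), "i_glu")
print(f"  with a7 blocked: degenerate flat trace = {flat.degenerate}")

# The undershoot after washout reflects receptors still desensitized once
# nicotine is gone; its recovery runs on the 10-minute a4b2 recovery scale.
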