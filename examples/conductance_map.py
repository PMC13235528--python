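"""Interaction of the output neuron's T-type calcium and H conductances.

Runs a small two-parameter grid at a 50 ms inter-stimulus delay.  Spike
count grows roughly one spike per 0.1 nS of gCaT (the T current is the
burst generator), while gH mainly shapes the hyperpolarized state during
the integration window.
"""

from csnsim import run_heatmap

grid = run_heatmap(("CSN.gCaT", [0.4, 0.5, 0.6, 0.7, 0.8]),
                   ("CSN.gH", [2.0, 6.0, 12.0]),
                   delay=50.0)

g_cat_vals, g_h_vals = grid.axis_values
header = "gCaT\\gH " + "".join(f"{g:6.0f}" for g in g_h_vals)
print(header)
for i, g in enumerate(g_cat_vals):
    row = "".join(f"{grid.spike_counts[i, j]:6d}"
                  for j in range(len(g_h_vals)))
    print(f"{g:7.1f} {row}")
print("(cell value = CSN spikes for one deterministic simulation)")
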