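"""Delay-tuning curve of the combination-sensitive output neuron.

Sweeps the gap between S1 offset and S2 onset and counts output spikes
per condition.  The curve rises from a modest count at short gaps to a
peak near 150 ms (delay-dependent priming: T-type calcium availability
and H-current activation accumulate during inhibition) and collapses to
zero by ~260 ms, when the upstream loop has died out before S2 arrives.
"""

from csnsim import run_delay_sweep

grid = run_delay_sweep(delays=[0, 50, 100, 150, 200, 230, 260, 300])
print("delay (ms) -> CSN spikes")
for delay, count, ok in zip(grid.axis_values[0], grid.spike_counts,
                            grid.success):
    bar = "#" * int(count)
    print(f"  {delay:5.0f}      {count}  {bar}{'  <- success' if ok else ''}")
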