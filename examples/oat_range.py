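"""One-at-a-time sensitivity range of the output neuron's T conductance.

Varies CSN gCaT around its 0.4 nS baseline until the network stops
behaving: a value must keep the paired response a proper burst while
every control condition stays silent.  The search brackets the accepted
band by outward multiplicative steps refined by bisection.
"""

from csnsim import run_network_condition, run_oat_search


def network_ok(g_cat: float) -> bool:
    ov = {"CSN": {"gCaT": g_cat}}
    paired, _ = run_network_condition(delay=50.0, neuron_overrides=ov)
    if not paired.success:
        return False
    for cond in ("S2_only", "reversed"):
        control, _ = run_network_condition(condition=cond,
                                           neuron_overrides=ov)
        if control.spike_count > 0:  # e.g. unwanted rebound to S2 alone
            return False
    return True


result = run_oat_search("CSN.gCaT", 0.4, network_ok,
                        max_steps=6, bisection_iters=4)
print(f"accepted range for {result.parameter}: "
      f"[{result.accepted_min}, {result.accepted_max}] nS "
      f"(baseline {result.baseline} nS)")
print("below the minimum the rebound burst fails; above the maximum the")
print("cell loses selectivity (it responds outside the paired condition).")
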