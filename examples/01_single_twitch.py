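"""Pace the cell to steady state at one frequency and inspect the twitch.

Runs the coarse reference cell at 4 Hz under the standard voltage-clamp
protocol (50 ms steps to +10 mV from -40 mV) and prints the headline numbers
of the final steady cycle: the myoplasmic Ca2+ transient, the trigger current
and release flux, SR content swing, normalised force and the whole-cell Ca2+
balance residual (which should be a fraction of a percent of the influx).
"""

from myoffr import analysis, engine, fast_test_config

cfg = fast_test_config()
res = engine.run_to_steady_state(cfg, frequency=4.0)
m = analysis.cycle_metrics(res.final_cycle)

print(f"paced {res.n_cycles_run} cycles at 4 Hz (stop: {res.stop_reason})")
print(f"[Ca2+]_myo      : {m.min_ca:.3f} -> {m.peak_ca:.3f} uM "
      f"(rise {m.r_rise:.0f} uM/s, decay {m.r_decay:.0f} uM/s)")
print(f"peak |I_CaL|    : {m.peak_ical:.3f} uM/ms   peak RyR flux: {m.peak_iryr:.2f} uM/ms")
print(f"jSR free Ca2+   : {m.post_release_jsr:.0f} -> {m.pre_release_jsr:.0f} uM")
print(f"normalised force: {m.min_force:.3f} -> {m.peak_force:.3f} "
      f"(sarcomere shortens to {m.min_sl:.3f} um)")
print(f"Ca balance residual over the cycle: "
      f"{100 * res.balance['relative_residual']:.3f}% of influx")
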