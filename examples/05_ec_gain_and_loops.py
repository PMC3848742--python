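"""EC-coupling gain and the force-Ca2+ phase loop.

The gain of Ca2+-induced Ca2+ release is the ratio of the peak myoplasmic
transient with the RyR release pathway enabled to the transient produced by
the trigger current alone.  The force-Ca2+ phase loop of a steady cycle is
traversed counter-clockwise; where its relaxation limb crosses the
steady-state force-Ca2+ relation defines the contraction-relaxation coupling
point (CRCP), which moves to larger force and Ca2+ as rate increases.
"""

from myoffr import analysis, engine, fast_test_config

cfg = fast_test_config()

gain = analysis.ec_gain(cfg, 4.0, "basal")
print(f"EC-coupling gain at 4 Hz: {gain:.1f} (release-amplified vs trigger-only)")

for f in (4.0, 8.0):
    res = engine.run_to_steady_state(cfg, f)
    loop = analysis.phase_loop(res)
    print(f"{f:3.0f} Hz: loop area {loop['area']:.3f}, "
          f"CRCP at Ca = {loop['crcp_ca']:.3f} uM, force = {loop['crcp_force']:.3f}")
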