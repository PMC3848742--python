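# myoffr

A coupled electromechanical model of an isolated **rat ventricular myocyte
under voltage clamp**, built to study how pacing rate shapes Ca²⁺ cycling and
contraction — the **force–frequency response (FFR)**.

Rat ventricle, paced in the physiological range, shows a *positive* FFR:
peak isometric force grows with stimulation rate up to roughly 8 Hz. The
mechanisms live in the Ca²⁺ subsystem: trigger Ca²⁺ enters through L-type
channels into a ~15 nm dyadic cleft, activates ryanodine receptors on the
junctional SR (Ca²⁺-induced Ca²⁺ release), and the released Ca²⁺ drives the
myofilaments before SERCA resequesters it (85–90% of removal) with NCX and
PMCA extruding the rest. Pacing frequency is decoded by calmodulin-dependent
enzymes — CaMKII (dyadic: facilitation of the L-type current; myoplasmic:
SERCA and phospholamban phosphorylation) and calcineurin — and, with
sympathetic tone, by a frequency-dependent rise in cAMP that upregulates the
L-type conductance, SERCA (via phospholamban) and crossbridge kinetics while
desensitising the myofilaments through troponin-I phosphorylation.

The package implements this as a deterministic fixed-step simulator:

* a 2-D radially symmetric reaction–diffusion dyadic cleft (finite-volume
  grid, stationary buffers, point-source superposition for channel-mouth
  Ca²⁺),
* 6-state Markov L-type channel with Ca-dependent inactivation and
  CaMKII/CaN-dependent facilitation via the modulation term
  ξ = 550 + CaMKII·(1.348 + CaMKII³·²²⁄(3.135·10⁶ − 0.755·CaMKII³·²²)) + CaN,
* 4-state ryanodine receptor with a luminal-sensor refractory mechanism,
* CaM→CaMKII/CaN signalling in two compartments,
* SERCA/phospholamban dynamics (dPLB_dp/dt with base rates 6800/1000 s⁻¹ and
  CaN, CaMKII and F_cAMP,SERCA modifiers),
* a reduced cooperative-activation/crossbridge force model (regulatory Ca²⁺
  binding at konT = 22.22 µM⁻¹s⁻¹, koffHT = 17.36 s⁻¹, koffLT = 173.61 s⁻¹;
  PKA/TnI desensitisation; Q10 = 2.25 on the crossbridge rates),
* a 5-stage Merson Runge–Kutta engine with exact whole-cell Ca²⁺ bookkeeping.

See `docs/methods.md` for the full model description and the reasoning
behind the calibrated reference parameter set.

## Worked example

```bash
python examples/01_single_twitch.py
```

prints, for the coarse (`fast_test`) reference cell paced at 4 Hz:

```
paced 50 cycles at 4 Hz (stop: n_cycles)
[Ca2+]_myo      : 0.272 -> 0.829 uM (rise 1180 uM/s, decay 91 uM/s)
peak |I_CaL|    : 0.549 uM/ms   peak RyR flux: 14.37 uM/ms
jSR free Ca2+   : 684 -> 2129 uM
normalised force: 0.061 -> 0.273 (sarcomere shortens to 1.912 um)
Ca balance residual over the cycle: 0.138% of influx
```

i.e. a diastolic-to-systolic Ca²⁺ transient of ~0.56 µM riding on a 0.27 µM
diastole, a release flux more than twenty-fold the trigger flux (CICR
amplification), a jSR that depletes by ~two-thirds per beat and refills
between beats, and a whole-cell Ca²⁺ ledger that closes to a fraction of a
percent. `examples/02…05` walk through the FFR sweep, CaMKII/CaN frequency
decoding, β-adrenergic stimulation and EC-coupling gain / force–Ca²⁺ phase
loops.

The same runs are available from the shell:

```bash
myoffr simulate --base fast_test --freq 8 --out out/
myoffr ffr --base fast_test --freqs 4,5,6,7,8,9,10 --out ffr.csv
myoffr gain --base fast_test --freq 4
myoffr validate-config my_overrides.yaml
```

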