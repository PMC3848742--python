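# Methods

`myoffr` simulates the Ca²⁺ subsystem and isometric contraction of an
isolated rat ventricular myocyte under voltage clamp, with the pacing-rate
dependence of Ca²⁺ cycling and force as its primary output. This note
documents the model, its assumptions, the calibrated reference parameter
set, the numerics, and what the shipped configurations do and do not show.

## Model overview

The cell is a set of well-stirred compartments — myoplasm, longitudinal SR
(LSR, the SERCA compartment), junctional SR (jSR, the release compartment,
buffered by calsequestrin) and myoplasmic Na⁺ — coupled to one spatially
resolved representative dyadic coupling unit (DCU): the ~15 nm cleft between
the sarcolemmal L-type Ca²⁺ channel (LCC) cluster and the apposed RyR
cluster on the jSR face. All dyads in the cell are assumed identical and in
phase, so the single resolved cleft is scaled by the total dyadic volume
fraction.

Membrane potential is a command waveform (square pulses, default 50 ms to
+10 mV from a −40 mV holding potential); there are no Na⁺- or K⁺-selective
channels and no action-potential mode. The only sarcolemmal Ca²⁺ pathways
are the L-type current, NCX, PMCA and a constant background leak chosen so
the quiescent cell is exactly flux-balanced.

### Dyadic cleft (reaction–diffusion)

The cleft is a radially symmetric cylinder discretised on an `nr × nz`
finite-volume grid (20×20 at 10 nm / 0.76 nm in the `full` configuration,
10×10 at 20 nm / 1.52 nm in `fast_test`). Free Ca²⁺ diffuses with a
barrier-reduced effective coefficient `d_eff` (default 0.10 µm²/ms; the RyR
foot structures act as obstacles, so this is below free-solution values), a
stationary buffer reacts locally (exact exponential relaxation toward the
local isotherm — the reaction is far stiffer than diffusion near open
mouths), and the outer rim exchanges with the myoplasm. Trigger influx
enters uniformly over the sarcolemmal face, release over the jSR face;
sub-grid localisation is handled separately: concentrations at channel
mouths are the grid background plus stationary buffered point-source
increments `Q/(4πDd)·exp(−d/λ)` summed over open channels. These mouth
values drive RyR activation, Ca-dependent inactivation of the LCC, and RyR
recovery gating.

Axial diffusion at sub-nm grid spacing makes the fully explicit scheme
impractically stiff (the bound is tens of ns), so the grid update is
operator-split: explicit conservative radial diffusion plus an
unconditionally stable implicit (Thomas) axial solve per shell; only the
radial bound restricts the sub-step. A fully explicit stepper is retained
for verification, and the two agree on resolved transients.

### L-type channel, CDI and CDF

Six Markov states: two closed, open, fast- and slow-inactivated, and a deep
refractory state. Activation rates are exponential in voltage; recovery
paths are gated to the holding potential. CDI is a separate fast two-state
gate driven by the LCC-mouth Ca²⁺ (so RyR release deepens it within the
beat). CDF enters through the modulation term ξ(CaMKII, CaN): the
activation, open-state-inactivation and deep-recovery rates are scaled by
ξ/ξ_ref, which develops over beats as dyadic CaMKII accumulates — CDI is
fast (within a beat), CDF slow (over beats). The deep refractory state is
the high-rate brake: above ~8 Hz the diastolic interval is too short for
full recovery, so availability and the trigger decline. cAMP scales the
conductance through its saturating-exponential factor. The driving force is
a constant-field (GHK) expression evaluated at the cleft face, so strong
release transiently collapses the trigger's driving force — a physiological
negative feedback that the tiny cleft volume makes prominent.

### RyR release and the luminal sensor

Four-state ring: closed → open → inactivated → refractory → closed. Opening
is steeply Ca²⁺-dependent (Hill 4, midpoint 28 µM at the mouth) and scaled
by dyadic CaMKII; closing and inactivation terminate the spike. Release in
a deterministic mean-field dyad is prone to a spurious stable
"partial-leak" state (a trickle of release keeps the cleft warm enough to
sustain itself); three mechanisms make full termination the only attractor:

* recovery from the refractory state requires a cleared cytosolic face
  (blocked above a few µM at the mouth) — while any release is ongoing the
  refractory state is absorbing;
* the depletion-driven luminal sensor `w` shuts the activation pathway with
  a steep, near all-or-none gate, so release is regenerative while the
  store is replete and terminates completely once it has depleted past the
  gate;
* once the jSR refills past the sensor threshold, `w` decays at a capped
  rate, which sets an inter-beat refractory period for release.

Release flux is permeability × open probability × the jSR-to-face gradient.

### SR compartments, SERCA and PLB

SERCA is a bidirectional saturable flux with forward half-activation
`ec50_f` and Hill coefficient calibrated steep (3.6), so uptake engages
strongly during the transient and weakly at diastolic Ca²⁺; back-flux
through the pump caps SR content. The maximal rate grows with the
phosphorylated-phospholamban fraction (relief of inhibition) and directly
with myoplasmic CaMKII; CaMKII also lowers the forward and raises the
backward half-activation constants. PLB phosphorylation follows the printed
two-state law (base rates 6800/1000 s⁻¹) with the CaN (×10⁻⁴), CaMKII
(×10⁵) and F_cAMP,SERCA modifiers applied multiplicatively and squared.
LSR→jSR transfer is first-order with a ~50 ms time constant (the refilling
delay behind luminal-sensor refractoriness); calsequestrin binding in the
jSR is kinetic.

### CaM / CaMKII / CaN signalling

Each compartment (dyad, myoplasm) carries total CaM partitioned into apo,
Ca₂CaM (C-lobe), Ca₄CaM (N-lobe) and buffered CaM; binding is sequential
and mass-action in [Ca²⁺]². The dyadic CaM buffer is much weaker than the
myoplasmic one, which concentrates responsive CaM at the release site. The
N-lobe off-rate is slow (1.6 s⁻¹), so Ca₄CaM decays on a ~0.6 s timescale:
at low rates it relaxes between beats, at high rates it accumulates toward
saturation — this is the frequency decoder. CaMKII activation is a
first-order ODE on the expected active fraction driven by Ca₄CaM; CaN
activation is driven by a weighted combination of Ca₂CaM and Ca₄CaM with a
slow (0.1 s⁻¹) dissociation, which makes dyadic CaN ~85–90% active already
at 0.5 Hz and nearly constitutive above 4 Hz. Activated levels are carried
in compartment-scoped units calibrated so the printed scaling constants
(×10⁵, ×10⁻⁴, the coefficients of ξ) produce order-one modulations; the
dyadic and myoplasmic pools therefore use different per-fraction rate
constants and are not inter-convertible concentrations.

Numerically, the dyadic CaM chain at cleft Ca²⁺ levels is far too stiff for
the explicit scheme, so it advances by a backward-Euler step inside the
grid sub-step loop; its net Ca²⁺ uptake is removed from the grid in
proportion to local free Ca²⁺, which conserves mass exactly and cannot
drive nodes negative.

### β-adrenergic (cAMP) arm

Sympathetic tone is a frequency-dependent intracellular cAMP level: 2.67 µM
at all rates under basal conditions, a tabulated rise to 29.17 µM at 12 Hz
under maximal stimulation (linear interpolation between anchors, plateau
below 1.67 Hz; a step-function mode is config-selectable). cAMP acts through
four closed-form factors on the L-type conductance, PLB phosphorylation
(plus a small optional direct PKA arm on the pump), crossbridge kinetics and
TnI phosphorylation (myofilament desensitisation). cGMP is carried as a
constant with no downstream coupling. cAMP is constant within a run.

### Myofilament mechanics

A reduced cooperative-activation/crossbridge model: two regulatory troponin
sites with printed rate constants (the low-affinity site is the regulatory
signal), TnI phosphorylation scaling the on-rate, regulatory units switching
between crossbridge non-permitting and permitting states at 500/50 s⁻¹ with
nearest-neighbour cooperativity entering as a capped power of regulatory
occupancy, and a three-state crossbridge cycle whose rates fapp, hf, hb and
gxb carry the cAMP factor and a Q10 of 2.25 (reference temperature 25 °C,
configurable 15–40 °C). Normalised force is the weighted strongly bound
fraction; isometric sarcomere length shortens internally against a series
elastance in proportion to force. The steady-state force–Ca²⁺ relation has
a closed algebraic form used for CRCP extraction and as an independent
check of integrated steady states.

### Na⁺ balance and extrusion

NCX is the standard electrogenic 3:1 formulation (no cAMP dependence; at
the −40 mV holding potential it clamps diastolic Ca²⁺ near its reversal
point). Myoplasmic Na⁺ follows a lumped balance: 3:1 stoichiometric influx
from NCX Ca²⁺ extrusion, a constant background influx, and a shallow
saturable pump-type efflux. Its intrinsic time constant is of order a
minute, as in real myocytes, so cycle-averaged Na⁺ within a
convergence-capped sweep reflects the pacing history as well as the rate —
the sweep protocol (below) is part of the operating definition.

## Numerics

Fixed-step 5-stage Merson Runge–Kutta (order 4; classic RK4 selectable) for
all compartment ODEs; the dyadic grid is operator-split as above, with the
whole-cell trigger and release fluxes frozen over each global step so the
grid and the ODEs see identical fluxes. Runge–Kutta preserves linear
invariants, so all internal Ca²⁺ transfers cancel exactly in the whole-cell
balance; the audited residual of a steady cycle (change in total cell Ca²⁺
vs integrated sarcolemmal fluxes) is well below the 0.5% tolerance, and a
sealed cell conserves total Ca²⁺ to ~1e-8 relative. The `full`
configuration uses the production numerics (1 µs step, 20×20 grid, 150
cycles); `fast_test` (10 µs, 10×10, convergence-stopped pacing capped at 50
cycles) is the desk-scale configuration used by the test-suite and the
acceptance analyses — halving its step changes final-cycle peaks by well
under 0.5%. The model is fully deterministic; the config carries a reserved
seed field that nothing consumes.

Frequency sweeps run as a continuation: frequencies in increasing order,
each run warm-started from the previous frequency's final state. This
mirrors experimental ramp protocols and lets the slow states (Na⁺, CaN,
accumulated Ca₄CaM) operate inside the 50-cycle cap; cold-started single
runs converge to the same fast-state behaviour but need many more cycles
for the slow states.

## Design choices made where the design was open

* The release-channel topologies (6-state LCC, 4-state RyR ring), the
  Saucerman-style CaM scheme's rate constants, the SERCA modulation laws and
  the reduced myofilament internals are not uniquely determined by printed
  constants; they are shipped as a documented reference set calibrated so
  the emergent rate-dependent behaviours (positive FFR peaking at 8 Hz,
  near-flat peak RyR open probability between 0.5 and 4 Hz, ~85→97%
  dyadic CaN activation, ~50% CaMKII modulation, SERCA carrying ≳85% of
  removal) sit at their published operating points.
* The ξ expression is parsed as
  `550 + CaMKII·(1.348 + CaMKII^3.22/(3.135e6 − 0.755·CaMKII^3.22)) + CaN`
  with the denominator clamped positive; the simpler linear form
  (`550 + 6·CaMKII + CaN`) is retained behind `lcc.xi_form`.
* The PLB modifier terms are applied as multiplicative factors on the
  phosphorylation/dephosphorylation base rates (CaN opposes, CaMKII and
  cAMP promote phosphorylation).
* The 500/50 s⁻¹ regulatory switching rates carry no Q10 or cAMP scaling
  (only fapp, hf, hb and gxb are scaled).
* cAMP is applied as a per-run constant resolved from the pacing frequency
  (no inter-run cAMP kinetics).
* CRCP is operationalised as the point where the relaxation limb of the
  force–Ca²⁺ loop crosses the algebraic steady-state force–Ca²⁺ relation.

## What the configurations show — and what they do not

With the shipped reference calibration the model reproduces, as emergent
behaviour: a positive force–frequency relation whose peak force is maximal
at 8 Hz on a 4–10 Hz sweep; an ~1.9-fold increase of the peak myoplasmic
Ca²⁺ transient from 4 to 8 Hz; a near-flat (+0.4%) peak RyR open
probability between 0.5 and 4 Hz; dyadic calcineurin ~90% active at 0.5 Hz
and ~96.5% at 4 Hz (near-constitutive above that); and a ~50% modulation of
cycle-averaged dyadic CaMKII across 0.5–12 Hz. All of these are computed at
the desk-scale problem size (10×10 cleft grid, 10 µs step, sweeps of up to
eleven frequencies with a 50-cycle cap per frequency), which the
self-convergence checks support. Known limitations:

* a single representative, deterministically gated dyad: no spark
  stochasticity, no dyad-to-dyad variability, no wave phenomena;
* voltage clamp only — nothing here speaks to action-potential-driven
  rate dependence;
* the modulation of peak I_CaL across the full 0.5–12 Hz range (~120%) is
  far larger than the ≲20% of the target behaviour: the deep-refractory
  availability brake and CDI needed to bend trigger and force downward past
  8 Hz cost trigger flatness at the extremes of the range, and flattening
  the trigger reopens a monotone force–frequency relation;
* the SERCA share of systolic removal at 1 Hz computes to ~82% rather than
  ≥85% — at low rate the EC-coupling amplification (release per unit
  trigger) in this cell is at the low end, and raising it destabilises the
  mid-frequency operating points;
* the β-adrenergic force increment over basal grows toward 8 Hz instead of
  peaking at 5 Hz: the opposing arms (TnI desensitisation vs cAMP-scaled
  conductance, uptake and crossbridge kinetics) do not cross over
  mid-range at the shipped strengths;
* myoplasmic Na⁺ is deliberately slow (minute-scale, as in real myocytes);
  within the capped sweep protocol its 0.5→4 Hz rise computes to ~21%
  rather than ~30%, even with the effective-volume speedup of the lumped
  pool;
* above ~10 Hz SR content does not decline as strongly as release does
  (diastolic Ca²⁺ accumulation keeps uptake engaged), so the post-8 Hz
  force decline is carried mainly by release refractoriness and trigger
  availability.
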