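"""Model configuration: schema-validated parameter blocks and reference fixtures.

Conventions
-----------
* time in ms inside the engine; rate constants in the config are given in the
  units they are usually published in (s^-1, uM^-1 s^-1) and converted when the
  kernel parameter vector is packed,
* Ca2+ concentrations in uM, Na+ in mM, voltages in mV, lengths in um,
  diffusion coefficients in um^2/ms,
* fluxes are expressed per myoplasmic volume (uM/ms) unless stated otherwise,
* volumes of other compartments are fractions of the myoplasmic volume.

Two shipped fixtures: ``full`` mirrors the production numerics (20x20 dyad
grid, 1 us step, 150 pacing cycles) and ``fast_test`` is a coarse desk-scale
configuration (10x10 grid, 10 us step, convergence-stopped pacing capped at
50 cycles) used by the test-suite and the acceptance analyses.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["ModelConfig", "load_config", "reference_fixtures", "full_config", "fast_test_config"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class CompartmentSignaling(_Block):
    """CaM / CaMKII / CaN parameters for one compartment (dyad or myoplasm)."""

    cam_total: float = Field(gt=0, description="total CaM (uM)")
    # two-step cooperative Ca2+ binding (2 Ca per step: C-lobe then N-lobe)
    kon_c: float = Field(gt=0, description="C-lobe on rate (uM^-2 s^-1)")
    koff_c: float = Field(gt=0, description="C-lobe off rate (s^-1)")
    kon_n: float = Field(gt=0, description="N-lobe on rate (uM^-2 s^-1)")
    koff_n: float = Field(gt=0, description="N-lobe off rate (s^-1)")
    # generic CaM buffer, pseudo-first-order (buffer sites in excess)
    kon_buf: float = Field(ge=0, description="apoCaM -> buffered rate (s^-1)")
    koff_buf: float = Field(gt=0, description="buffered -> apoCaM rate (s^-1)")
    # CaMKII subunit switching (deterministic expected-fraction ODE)
    camkii_total: float = Field(gt=0, description="total CaMKII (compartment units)")
    kon_kii: float = Field(gt=0, description="activation rate per Ca4CaM fraction (s^-1)")
    koff_kii: float = Field(gt=0, description="deactivation rate (s^-1)")
    # CaN activation by CaM species; Ca4CaM-CaN dissociation is slow (<< 1 s^-1)
    can_total: float = Field(gt=0, description="total CaN (compartment units)")
    kon_can: float = Field(gt=0, description="activation rate per CaM-species drive (s^-1)")
    koff_can: float = Field(gt=0, le=1.0, description="deactivation rate (s^-1), slow")
    w_ca2: float = Field(ge=0, description="weight of Ca2CaM in the CaN drive")
    w_ca4: float = Field(ge=0, description="weight of Ca4CaM in the CaN drive")


class SignalingParams(_Block):
    dyad: CompartmentSignaling
    myo: CompartmentSignaling


class NeuroParams(_Block):
    beta_state: Literal["basal", "maximal"] = "basal"
    camp_override: float | None = Field(default=None, ge=0, description="pin cAMP (uM)")
    cgmp: float = Field(default=2.0, ge=0, description="constant cGMP (uM)")
    camp_interpolation: Literal["linear", "step"] = "linear"


class DyadParams(_Block):
    nr: int = Field(ge=4, le=64)
    nz: int = Field(ge=4, le=64)
    dr_nm: float = Field(gt=0, description="radial step (nm)")
    dz_nm: float = Field(gt=0, description="axial step (nm)")
    d_eff: float = Field(gt=0, description="barrier-reduced effective Ca diffusion (um^2/ms)")
    buf_total: float = Field(ge=0, description="stationary cleft buffer (uM)")
    buf_kon: float = Field(ge=0, description="buffer on rate (uM^-1 s^-1)")
    buf_koff: float = Field(gt=0, description="buffer off rate (s^-1)")
    v_frac: float = Field(gt=0, lt=0.05, description="total dyadic volume / myoplasmic volume")
    lambda_nm: float = Field(gt=0, description="buffered point-source length constant (nm)")
    mouth_radius_nm: float = Field(gt=0, description="channel mouth radius for the source kernel (nm)")
    lcc_ryr_gap_nm: float = Field(gt=0, description="axial LCC-to-RyR mouth distance (nm)")
    ryr_spacing_nm: float = Field(gt=0, description="nearest-neighbour RyR spacing (nm)")
    n_dcu: int = Field(gt=0, description="dyadic coupling units per cell")
    n_lcc: int = Field(gt=0, description="LCC channels per DCU")
    n_ryr: int = Field(gt=0, description="RyR channels per DCU")
    v_myo_pL: float = Field(gt=0, description="myoplasmic volume (pL)")


class LCCParams(_Block):
    """6-state Markov L-type channel: C0-C1-O activation chain, fast/slow
    voltage-dependent inactivated states If/Is and a deep refractory state R."""

    g_cal: float = Field(gt=0, description="whole-cell flux scale (uM/ms per uM driving)")
    # voltage-dependent activation C0->C1->O
    a01: float = Field(gt=0, description="C0->C1 at 0 mV (ms^-1)")
    sa01: float = Field(gt=0, description="slope (mV) for a01")
    b10: float = Field(gt=0)
    sb10: float = Field(gt=0)
    a12: float = Field(gt=0)
    sa12: float = Field(gt=0)
    b21: float = Field(gt=0)
    sb21: float = Field(gt=0)
    # inactivation / recovery
    kof: float = Field(gt=0, description="O->If (ms^-1)")
    kfo: float = Field(gt=0, description="If->O (ms^-1)")
    kfc: float = Field(gt=0, description="If->C1 recovery at hold (ms^-1, gated)")
    kfs: float = Field(gt=0, description="If->Is (ms^-1)")
    ksf: float = Field(gt=0, description="Is->If at V_hold (ms^-1)")
    ksr: float = Field(gt=0, description="Is->R (ms^-1)")
    krc: float = Field(gt=0, description="R->C0 recovery at V_hold (ms^-1)")
    v_inact_gate: float = Field(description="midpoint (mV) gating recovery-path rates")
    s_inact_gate: float = Field(gt=0, description="slope (mV) of the recovery gate")
    # Ca-dependent inactivation (separate 2-state gate)
    cdi_khalf: float = Field(gt=0, description="CDI half-inactivation local Ca (uM)")
    cdi_hill: float = Field(gt=0)
    cdi_tau_ms: float = Field(gt=0)
    cdi_floor: float = Field(ge=0, lt=1, description="residual conduction at saturating Ca")
    # CaMKII/CaN-dependent facilitation via xi
    xi_form: Literal["new", "linear"] = "new"
    xi_coupling: float = Field(ge=0, description="sensitivity of the scaled rates to xi/xi_ref - 1")


class RyRParams(_Block):
    """4-state ring: C -> O -> I -> Rf -> C with Ca-activated opening,
    CaMKII scaling and luminal-sensor coupled inactivation/recovery."""

    perm: float = Field(ge=0, description="release permeability (ms^-1, myo-volume units); 0 disables CICR")
    ko_max: float = Field(gt=0, description="max C->O rate (ms^-1)")
    ka_um: float = Field(gt=0, description="half-activation local Ca (uM)")
    hill: float = Field(gt=0)
    koc: float = Field(gt=0, description="O->C (ms^-1)")
    koi: float = Field(gt=0, description="O->I base (ms^-1)")
    koi_lum: float = Field(ge=0, description="luminal-inhibition multiplier on O->I")
    kir: float = Field(gt=0, description="I->Rf (ms^-1)")
    krc: float = Field(gt=0, description="Rf->C base recovery (ms^-1)")
    krc_lum: float = Field(ge=0, lt=1, description="fractional recovery block at full inhibition")
    eps_kii: float = Field(ge=0, description="CaMKII scaling of the opening rate")
    w_gate: float = Field(gt=0, lt=1, description="luminal-inhibition level that shuts the activation pathway (steep gate)")
    krec_ca_um: float = Field(gt=0, description="local Ca (uM) above which recovery from refractoriness is blocked")
    # luminal sensor
    lum_thr: float = Field(gt=0, description="jSR Ca threshold (uM)")
    lum_alpha: float = Field(gt=0, description="inhibition build-up rate (ms^-1)")
    lum_beta0: float = Field(gt=0, description="inhibition decay rate at threshold (ms^-1)")
    lum_m: float = Field(gt=0, description="refill sensitivity exponent of the decay")


class NCXParams(_Block):
    vmax: float = Field(gt=0, description="uM/ms")
    km_na: float = Field(gt=0, description="mM")
    km_ca: float = Field(gt=0, description="uM")
    eta: float = Field(gt=0, lt=1)
    ksat: float = Field(ge=0)
    na_o: float = Field(gt=0, description="mM")
    ca_o: float = Field(gt=0, description="uM")


class PMCAParams(_Block):
    vmax: float = Field(gt=0, description="uM/ms")
    k_half: float = Field(gt=0, description="uM")
    hill: float = Field(gt=0)


class NaParams(_Block):
    """Lumped myoplasmic Na+ balance: NCX stoichiometric influx, a constant
    background influx and a saturable pump-type efflux."""

    na_rest: float = Field(gt=0, description="mM, resting concentration")
    vol_factor: float = Field(default=1.0, gt=0, description="inverse effective distribution volume of the lumped Na+ pool (scales its kinetics, not its equilibria)")
    v_pump: float = Field(gt=0, description="mM/ms maximal efflux")
    km_pump: float = Field(gt=0, description="mM")
    hill_pump: float = Field(gt=0)


class SRParams(_Block):
    v_lsr: float = Field(gt=0, description="LSR volume fraction of myoplasm")
    v_jsr: float = Field(gt=0, description="jSR volume fraction of myoplasm")
    vmax_base: float = Field(gt=0, description="SERCA base max rate (uM/ms)")
    alpha_plb: float = Field(ge=0, description="vmax gain per phosphorylated-PLB fraction")
    alpha_kii: float = Field(ge=0, description="vmax gain per unit (CaMKII_myo x 1e5)")
    alpha_camp: float = Field(ge=0, description="direct PKA-arm vmax gain per unit F_cAMP,SERCA excess")
    ec50_f: float = Field(gt=0, description="forward half-activation (uM)")
    ec50_f_kii: float = Field(ge=0, lt=1, description="fractional EC50f decrease per unit CaMKII drive")
    ec50_b: float = Field(gt=0, description="backward half-activation (uM, LSR side)")
    ec50_b_kii: float = Field(ge=0, description="fractional EC50b increase per unit CaMKII drive")
    hill: float = Field(gt=0)
    backrate: float = Field(ge=0, description="relative weight of the backward flux")
    tau_tr_ms: float = Field(gt=0, description="LSR->jSR transfer time constant (ms)")
    csq_total: float = Field(gt=0, description="calsequestrin sites in jSR (uM of jSR volume)")
    csq_kd: float = Field(gt=0, description="uM")
    csq_kon: float = Field(gt=0, description="uM^-1 s^-1")
    # PLB two-state phosphorylation (printed constants)
    k12_plb: float = Field(gt=0, description="s^-1, dephosphorylation base rate")
    k21_plb: float = Field(gt=0, description="s^-1, phosphorylation base rate")


class MechanicsParams(_Block):
    # regulatory Ca binding to troponin (printed constants)
    kon_t: float = Field(gt=0, description="uM^-1 s^-1")
    koff_ht: float = Field(gt=0, description="s^-1, high-affinity site")
    koff_lt: float = Field(gt=0, description="s^-1, low-affinity site")
    trop_h_total: float = Field(gt=0, description="uM, high-affinity site density")
    trop_l_total: float = Field(gt=0, description="uM, low-affinity site density")
    # PKA-TnI two-state model (printed constants)
    kon_ti: float = Field(gt=0, description="s^-1")
    koff_ti: float = Field(gt=0, description="s^-1")
    # regulatory-unit switching (printed 500/50 s^-1) and cooperativity
    k_np: float = Field(gt=0, description="s^-1 non-permissive -> permissive base")
    k_pn: float = Field(gt=0, description="s^-1 permissive -> non-permissive base")
    coop_eta: float = Field(gt=0, description="nearest-neighbour cooperativity exponent")
    s50: float = Field(gt=0, lt=1, description="regulatory occupancy at half switching drive")
    sigma_cap: float = Field(gt=1, description="upper bound on the cooperative drive")
    # crossbridge cycle (base rates, s^-1)
    fapp: float = Field(gt=0)
    gapp: float = Field(gt=0)
    hf: float = Field(gt=0)
    hb: float = Field(gt=0)
    gxb: float = Field(gt=0)
    w_pre: float = Field(ge=0, le=1, description="force weight of pre-powerstroke bridges")
    force_ref: float = Field(gt=0, description="normalisation for force output")
    q10: float = Field(gt=0, le=6.5, description="Q10 of fappT/hfT/hbT/gxbT")
    t_ref_c: float = Field(ge=15, le=40, description="reference temperature (C)")
    temperature_c: float = Field(ge=15, le=40)
    sl_rest: float = Field(gt=0, description="resting sarcomere length (um)")
    dsl_max: float = Field(gt=0, description="max internal shortening (um) at unit force")


class ProtocolParams(_Block):
    v_hold: float = Field(default=-40.0, description="holding potential (mV)")
    v_step: float = Field(default=10.0, description="step potential (mV)")
    pulse_ms: float = Field(default=50.0, gt=0)


class EngineParams(_Block):
    dt_us: float = Field(gt=0, le=100, description="global time step (us)")
    n_cycles: int = Field(gt=0, le=1000)
    convergence_tol: float = Field(ge=0, description="relative beat-to-beat change for early stop")
    output_dt_ms: float = Field(gt=0, description="trace sampling interval (ms)")
    scheme: Literal["merson", "rk4"] = "merson"
    seed: int = Field(default=0, description="reserved; the model is fully deterministic")
    ca_rest: float = Field(gt=0, description="resting myoplasmic Ca (uM)")
    ca_sr_rest: float = Field(gt=0, description="resting SR free Ca (uM)")
    buf_myo_total: float = Field(gt=0, description="generic myoplasmic Ca buffer (uM)")
    buf_myo_kon: float = Field(gt=0, description="uM^-1 s^-1")
    buf_myo_koff: float = Field(gt=0, description="s^-1")


class Metadata(_Block):
    name: str = "reference"
    version: str = "1"
    description: str = "rat ventricular myocyte, voltage clamp"


class ModelConfig(_Block):
    metadata: Metadata = Metadata()
    signaling: SignalingParams
    neuro: NeuroParams = NeuroParams()
    dyad: DyadParams
    lcc: LCCParams
    ryr: RyRParams
    ncx: NCXParams
    pmca: PMCAParams
    na: NaParams
    sr: SRParams
    mechanics: MechanicsParams
    protocol: ProtocolParams = ProtocolParams()
    engine: EngineParams

    @model_validator(mode="after")
    def _check_grid_stability_inputs(self) -> "ModelConfig":
        # the explicit-FD stability bound itself is enforced where the grid is
        # built (sub-step count is derived there); here we only reject absurd
        # aspect ratios that would make the bound meaningless
        if self.dyad.dz_nm > self.dyad.dr_nm * 10:
            raise ValueError("dyadic grid: dz larger than 10x dr is not supported")
        return self

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return self.model_dump(mode="json")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def replace(self, **overrides) -> "ModelConfig":
        """Return a copy with nested overrides, e.g. ``replace(engine={'dt_us': 5})``."""
        data = self.model_dump()
        for key, value in overrides.items():
            if isinstance(value, dict) and isinstance(data.get(key), dict):
                data[key].update(value)
            else:
                data[key] = value
        return ModelConfig(**data)


def _deep_update(base: dict, overlay: dict) -> dict:
    for key, value in overlay.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path: str | Path | None = None, base: str = "full") -> ModelConfig:
    """Load a configuration: the named reference fixture, optionally overlaid
    with a YAML file containing a (possibly partial) parameter tree."""
    cfg = reference_fixtures()[base]
    if path is None:
        return cfg
    overlay = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(overlay, dict):
        raise ValueError(f"config overlay {path} must be a mapping")
    data = _deep_update(cfg.model_dump(), overlay)
    return ModelConfig(**data)


# ---------------------------------------------------------------------------
# Reference parameter set.  Printed constants (PLB, troponin, TnI, Q10,
# regulatory switching) are carried verbatim; unprinted internals are the
# package's calibrated reference values (see docs/methods.md).
# ---------------------------------------------------------------------------

_REFERENCE = dict(
    signaling=dict(
        dyad=dict(
            cam_total=400.0,
            kon_c=8.5, koff_c=60.0,
            kon_n=0.22, koff_n=1.6,
            kon_buf=12.0, koff_buf=30.0,
            camkii_total=120.0,
            kon_kii=5.2, koff_kii=1.1,
            can_total=40.0,
            kon_can=3.2, koff_can=0.10,
            w_ca2=0.35, w_ca4=1.0,
        ),
        myo=dict(
            cam_total=6.0,
            kon_c=8.5, koff_c=60.0,
            kon_n=0.22, koff_n=1.6,
            kon_buf=220.0, koff_buf=12.0,
            camkii_total=5.5e-5,
            kon_kii=1.6e4, koff_kii=1.1,
            can_total=7.0e3,
            kon_can=900.0, koff_can=0.10,
            w_ca2=0.35, w_ca4=1.0,
        ),
    ),
    neuro=dict(beta_state="basal"),
    dyad=dict(
        nr=20, nz=20, dr_nm=10.0, dz_nm=0.76,
        d_eff=0.10,
        buf_total=1000.0, buf_kon=30.0, buf_koff=300.0,
        v_frac=1.0e-3,
        lambda_nm=22.0, mouth_radius_nm=7.0,
        lcc_ryr_gap_nm=15.2, ryr_spacing_nm=30.0,
        n_dcu=20000, n_lcc=8, n_ryr=36,
        v_myo_pL=25.85,
    ),
    lcc=dict(
        g_cal=1.15e-3,
        a01=0.9, sa01=8.0, b10=0.3, sb10=12.0,
        a12=0.5, sa12=8.0, b21=0.12, sb21=14.0,
        kof=0.055, kfo=0.002, kfc=0.08, kfs=0.05, ksf=0.06,
        ksr=0.08, krc=0.008,
        v_inact_gate=-25.0, s_inact_gate=6.0,
        cdi_khalf=8.0, cdi_hill=2.0, cdi_tau_ms=8.0, cdi_floor=0.25,
        xi_form="new", xi_coupling=2.0,
    ),
    ryr=dict(
        perm=0.028,
        ko_max=2.5, ka_um=28.0, hill=4.0,
        koc=0.5,
        koi=0.12, koi_lum=8.0,
        kir=0.12, krc=0.025, krc_lum=0.98,
        eps_kii=0.06, w_gate=0.45, krec_ca_um=3.5,
        lum_thr=500.0, lum_alpha=0.8, lum_beta0=0.016, lum_m=6.0,
    ),
    ncx=dict(
        vmax=1800.0, km_na=87.5, km_ca=1380.0, eta=0.35, ksat=0.1,
        na_o=140.0, ca_o=1800.0,
    ),
    pmca=dict(vmax=0.006, k_half=0.5, hill=2.0),
    na=dict(na_rest=10.0, v_pump=8.0e-5, km_pump=13.0, hill_pump=1.5, vol_factor=4.0),
    sr=dict(
        v_lsr=0.06, v_jsr=0.02,
        vmax_base=2.8, alpha_plb=4.0, alpha_kii=0.15, alpha_camp=25.0,
        ec50_f=1.0, ec50_f_kii=0.10, ec50_b=4000.0, ec50_b_kii=0.10,
        hill=3.6, backrate=0.01, tau_tr_ms=110.0,
        csq_total=14000.0, csq_kd=630.0, csq_kon=1.0,
        k12_plb=6800.0, k21_plb=1000.0,
    ),
    mechanics=dict(
        kon_t=22.22, koff_ht=17.36, koff_lt=173.61,
        trop_h_total=70.0, trop_l_total=70.0,
        kon_ti=698.69, koff_ti=80.0,
        k_np=500.0, k_pn=50.0,
        coop_eta=5.0, s50=0.13, sigma_cap=20.0,
        fapp=120.0, gapp=30.0, hf=180.0, hb=40.0, gxb=40.0,
        w_pre=0.4, force_ref=0.62,
        q10=2.25, t_ref_c=25.0, temperature_c=25.0,
        sl_rest=1.95, dsl_max=0.14,
    ),
    protocol=dict(v_hold=-40.0, v_step=10.0, pulse_ms=50.0),
    engine=dict(
        dt_us=1.0, n_cycles=150, convergence_tol=1.0e-4, output_dt_ms=0.1,
        scheme="merson", ca_rest=0.143, ca_sr_rest=900.0,
        buf_myo_total=300.0, buf_myo_kon=100.0, buf_myo_koff=220.0,
    ),
)

_FAST_TEST_OVERLAY = dict(
    metadata=dict(name="fast_test", description="coarse desk-scale configuration"),
    dyad=dict(nr=10, nz=10, dr_nm=20.0, dz_nm=1.52),
    engine=dict(dt_us=10.0, n_cycles=50, convergence_tol=5.0e-4),
)


def full_config() -> ModelConfig:
    """The production reference cell (20x20 grid, 1 us step, 150 cycles)."""
    import copy

    return ModelConfig(**copy.deepcopy(_REFERENCE))


def fast_test_config() -> ModelConfig:
    """Coarse configuration for tests and desk-scale sweeps."""
    import copy

    data = _deep_update(copy.deepcopy(_REFERENCE), copy.deepcopy(_FAST_TEST_OVERLAY))
    return ModelConfig(**data)


def reference_fixtures() -> dict[str, ModelConfig]:
    return {"full": full_config(), "fast_test": fast_test_config()}
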