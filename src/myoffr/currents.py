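"""Sarcolemmal and jSR-membrane Ca2+ transport.

* **L-type (DHP-sensitive) channel** -- 6-state Markov chain
  C0 = C1 = O -> If = Is -> R -> C0 with voltage-dependent activation, fast and
  slow voltage-dependent inactivation and a deep refractory state whose slow
  recovery at the holding potential limits availability at pacing rates above
  8 Hz.  Ca2+-dependent inactivation (CDI) is a separate fast 2-state gate
  driven by the local Ca2+ at the channel mouth.  Ca2+-dependent facilitation
  (CDF) enters through the modulation term xi(CaMKII, CaN): three rates
  (activation, open-state inactivation, deep recovery) are scaled by
  xi/xi_ref, so rising dyadic CaMKII/CaN speeds activation and recovery and
  slows inactivation over several beats.  cAMP scales the conductance.
* **RyR channel** -- 4-state ring C -> O -> I -> Rf -> C.  Opening is steeply
  Ca2+-dependent (local cleft Ca2+ at the RyR mouth) and scaled by dyadic
  CaMKII; inactivation and recovery are coupled to a luminal-sensor gating
  variable driven by jSR Ca2+ depletion (post-release refractoriness).
* **NCX** -- electrogenic 3:1 Na+/Ca2+ exchanger (saturable, voltage and
  gradient dependent; no cAMP dependence).
* **PMCA** -- Hill-type saturating plasma-membrane Ca2+ pump.

Rate matrices follow the generator convention: off-diagonal entry (i, j) is
the j -> i rate and every column sums to zero, so d(occupancy)/dt = G @ p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .config import LCCParams, NCXParams, PMCAParams, RyRParams
from .neuro import f_camp_ical

__all__ = [
    "LCCState", "RyRState",
    "xi_modulation", "lcc_generator", "cdi_update", "cdi_steady", "i_cal",
    "ghk_driving", "ryr_generator", "ryr_flux", "luminal_sensor_rhs",
    "ncx_current", "pmca_current", "markov_steady_state",
]

RTF = 25.693  # RT/F at 25 C, mV

# state indices
LCC_C0, LCC_C1, LCC_O, LCC_IF, LCC_IS, LCC_R = range(6)
RYR_C, RYR_O, RYR_I, RYR_RF = range(4)


# ---------------------------------------------------------------------------
# CaMKII/CaN facilitation term xi
# ---------------------------------------------------------------------------


@njit(cache=True)
def _xi_new(camkii, can):
    """550 + CaMKII*(1.348 + CaMKII^3.22/(3.135e6 - 0.755*CaMKII^3.22)) + CaN,
    with the denominator clamped at a small positive floor."""
    p = camkii ** 3.22
    den = 3.135e6 - 0.755 * p
    if den < 1.0e3:
        den = 1.0e3
    return 550.0 + camkii * (1.348 + p / den) + can


@njit(cache=True)
def _xi_linear(camkii, can):
    return 550.0 + 6.0 * camkii + can


def xi_modulation(camkii: float, can: float, form: str = "new") -> float:
    """Facilitation term xi; both forms reduce to 550 at zero signalling."""
    if camkii < 0 or can < 0:
        raise ValueError("signalling inputs to xi must be non-negative")
    return float(_xi_new(camkii, can) if form == "new" else _xi_linear(camkii, can))


XI_REF = 550.0


# ---------------------------------------------------------------------------
# L-type channel
# ---------------------------------------------------------------------------


@dataclass
class LCCState:
    occupancy: np.ndarray = field(default_factory=lambda: _init_occ(6, LCC_C0))
    cdi_gate: float = 1.0
    conductance: float = 1.0e-3
    xi: float = XI_REF

    def validate(self):
        _check_simplex(self.occupancy)
        if not (0.0 <= self.cdi_gate <= 1.0):
            raise ValueError("cdi_gate outside [0,1]")
        if self.xi <= 0:
            raise ValueError("xi must be positive")


def _init_occ(n, idx):
    occ = np.zeros(n)
    occ[idx] = 1.0
    return occ


def _check_simplex(occ, tol=1e-9):
    if abs(occ.sum() - 1.0) > tol or occ.min() < -1e-12:
        raise ValueError(f"occupancy not on the simplex: {occ}")


@njit(cache=True)
def lcc_rates(v, xi_ratio, a01, sa01, b10, sb10, a12, sa12, b21, sb21,
              kof, kfo, kfc, kfs, ksf, ksr, krc, v_gate, s_gate):
    """The ten transition rates (ms^-1) of the 6-state chain at voltage v.

    CDF scales the activation rates (C0->C1, C1->O) up and open-state
    inactivation (O->If) down by the ratio xi/xi_ref; deep recovery is not
    facilitated, so incomplete recovery still limits availability at short
    diastolic intervals.
    """
    rec = 1.0 / (1.0 + np.exp((v - v_gate) / s_gate))  # ~1 at hold, ~0 at step
    r_a01 = a01 * np.exp(v / sa01) * xi_ratio
    r_b10 = b10 * np.exp(-v / sb10)
    r_a12 = a12 * np.exp(v / sa12) * xi_ratio
    r_b21 = b21 * np.exp(-v / sb21)
    r_of = kof / xi_ratio
    r_fo = kfo
    r_fc = kfc * rec
    r_fs = kfs
    r_sf = ksf * rec
    r_sr = ksr
    r_rc = krc * rec
    return r_a01, r_b10, r_a12, r_b21, r_of, r_fo, r_fc, r_fs, r_sf, r_sr, r_rc


def lcc_generator(v: float, camkii_dyad: float, can_dyad: float,
                  params: LCCParams) -> np.ndarray:
    """6x6 rate matrix of the L-type channel at voltage ``v`` (mV) under the
    current dyadic CaMKII/CaN levels (column sums are zero)."""
    xi = xi_modulation(camkii_dyad, can_dyad, params.xi_form)
    ratio = 1.0 + params.xi_coupling * (xi / XI_REF - 1.0)
    r = lcc_rates(v, ratio, params.a01, params.sa01, params.b10, params.sb10,
                  params.a12, params.sa12, params.b21, params.sb21,
                  params.kof, params.kfo, params.kfc, params.kfs, params.ksf,
                  params.ksr, params.krc, params.v_inact_gate, params.s_inact_gate)
    a01, b10, a12, b21, kof, kfo, kfc, kfs, ksf, ksr, krc = r
    G = np.zeros((6, 6))
    pairs = [
        (LCC_C1, LCC_C0, a01), (LCC_C0, LCC_C1, b10),
        (LCC_O, LCC_C1, a12), (LCC_C1, LCC_O, b21),
        (LCC_IF, LCC_O, kof), (LCC_O, LCC_IF, kfo),
        (LCC_C1, LCC_IF, kfc),
        (LCC_IS, LCC_IF, kfs), (LCC_IF, LCC_IS, ksf),
        (LCC_R, LCC_IS, ksr), (LCC_C0, LCC_R, krc),
    ]
    for dst, src, rate in pairs:
        G[dst, src] += rate
        G[src, src] -= rate
    return G


@njit(cache=True)
def _cdi_inf(ca, khalf, hill, floor):
    x = (ca / khalf) ** hill
    return floor + (1.0 - floor) / (1.0 + x)


def cdi_steady(ca_dyad: float, params: LCCParams) -> float:
    """Steady-state value of the CDI gate at local Ca (1 = no inactivation)."""
    return float(_cdi_inf(ca_dyad, params.cdi_khalf, params.cdi_hill, params.cdi_floor))


def cdi_update(cdi_gate: float, ca_dyad: float, dt: float, params: LCCParams) -> float:
    """First-order relaxation of the CDI gate toward its Ca-dependent target."""
    inf = cdi_steady(ca_dyad, params)
    return inf + (cdi_gate - inf) * np.exp(-dt / params.cdi_tau_ms)


@njit(cache=True)
def ghk_driving(v, ca_i, ca_o):
    """Constant-field driving term (uM, positive = inward) for a divalent."""
    u = 2.0 * v / RTF
    if abs(u) < 1.0e-6:
        return ca_o - ca_i
    e = np.exp(u)
    return -u * (ca_i * e - ca_o) / (e - 1.0)


def i_cal(v: float, lcc: LCCState, camp: float, ca_dyad: float, ca_o: float) -> float:
    """Whole-cell L-type current in flux units (uM/ms, myoplasmic volume);
    inward (Ca2+ entry) is negative by convention."""
    lcc.validate()
    drive = ghk_driving(v, ca_dyad, ca_o)
    return float(-lcc.conductance * lcc.occupancy[LCC_O] * lcc.cdi_gate
                 * f_camp_ical(camp) * drive)


# ---------------------------------------------------------------------------
# RyR channel and luminal sensor
# ---------------------------------------------------------------------------


@dataclass
class RyRState:
    occupancy: np.ndarray = field(default_factory=lambda: _init_occ(4, RYR_C))
    luminal_inhibition: float = 0.0
    camkii_scale: float = 1.0

    def validate(self):
        _check_simplex(self.occupancy)
        if not (0.0 <= self.luminal_inhibition <= 1.0):
            raise ValueError("luminal_inhibition outside [0,1]")


@njit(cache=True)
def ryr_rates(ca_mouth, kii_scale, w, w_gate, krec_ca, ko_max, ka, hill, koc,
              koi, koi_lum, kir, krc, krc_lum):
    x = (ca_mouth / ka) ** hill
    # the depletion-driven luminal sensor shuts the activation pathway with a
    # steep (near all-or-none) gate: release is regenerative while the store
    # is replete and terminates completely once it has depleted past the gate
    gate = 1.0 / (1.0 + (w / w_gate) ** 8)
    r_co = ko_max * x / (1.0 + x) * kii_scale * gate
    r_oc = koc
    r_oi = koi * (1.0 + koi_lum * w)
    r_ir = kir
    # recovery from refractoriness requires both a disengaged luminal sensor
    # (switch-like in w) and a cleared cytosolic face: while any release is
    # ongoing the refractory state is absorbing, so release terminates
    # completely instead of settling into a partially-refractory leak
    g = 1.0 - krc_lum * w
    r_rc = krc * g ** 6 / (1.0 + (ca_mouth / krec_ca) ** 4)
    return r_co, r_oc, r_oi, r_ir, r_rc


def ryr_generator(ca_ryr_mouth: float, camkii_dyad: float,
                  luminal_inhibition: float, params: RyRParams,
                  camkii_ref: float = 60.0) -> np.ndarray:
    """4x4 rate matrix of the RyR ring (column sums zero).

    Opening is Ca-activated (CICR trigger) and scaled up by dyadic CaMKII
    relative to ``camkii_ref``; inactivation and recovery are gated by the
    luminal-sensor variable.
    """
    if min(ca_ryr_mouth, camkii_dyad, luminal_inhibition) < 0:
        raise ValueError("ryr_generator inputs must be non-negative")
    scale = 1.0 + params.eps_kii * (camkii_dyad - camkii_ref) / camkii_ref
    r = ryr_rates(ca_ryr_mouth, max(scale, 0.0), luminal_inhibition,
                  params.w_gate, params.krec_ca_um, params.ko_max,
                  params.ka_um, params.hill, params.koc, params.koi,
                  params.koi_lum, params.kir, params.krc, params.krc_lum)
    r_co, r_oc, r_oi, r_ir, r_rc = r
    G = np.zeros((4, 4))
    pairs = [
        (RYR_O, RYR_C, r_co), (RYR_C, RYR_O, r_oc),
        (RYR_I, RYR_O, r_oi), (RYR_RF, RYR_I, r_ir),
        (RYR_C, RYR_RF, r_rc),
    ]
    for dst, src, rate in pairs:
        G[dst, src] += rate
        G[src, src] -= rate
    return G


def ryr_flux(open_prob: float, ca_jsr: float, ca_dyad_face: float,
             params: RyRParams) -> float:
    """Release flux into the dyad (uM/ms, myoplasmic volume units):
    permeability x open probability x concentration gradient."""
    if ca_jsr < 0 or ca_dyad_face < 0:
        raise ValueError("concentrations must be non-negative")
    return params.perm * open_prob * (ca_jsr - ca_dyad_face)


@njit(cache=True)
def _lum_rhs(w, ca_jsr, thr, alpha, beta0, m):
    depletion = (thr - ca_jsr) / thr
    if depletion < 0.0:
        depletion = 0.0
    # decay accelerates with refilling but saturates at beta0: once the store
    # is replete, recovery proceeds at a fixed rate, which sets the
    # inter-beat refractory period of release
    refill = (ca_jsr / thr) ** m
    if refill > 1.0:
        refill = 1.0
    return alpha * depletion * (1.0 - w) - beta0 * refill * w


def luminal_sensor_rhs(luminal_inhibition: float, ca_jsr: float,
                       params: RyRParams) -> float:
    """d(inhibition)/dt: builds as jSR Ca falls below threshold during
    release, decays as the jSR refills (faster at higher jSR Ca)."""
    return float(_lum_rhs(luminal_inhibition, ca_jsr, params.lum_thr,
                          params.lum_alpha, params.lum_beta0, params.lum_m))


# ---------------------------------------------------------------------------
# NCX and PMCA
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ncx(v, na_i, ca_i, na_o, ca_o, vmax, km_na, km_ca, eta, ksat):
    vfrt = v / RTF
    ef = np.exp(eta * vfrt)
    er = np.exp((eta - 1.0) * vfrt)
    num = er * na_o ** 3 * ca_i - ef * na_i ** 3 * ca_o
    den = (km_na ** 3 + na_o ** 3) * (km_ca + ca_o) * (1.0 + ksat * er)
    return vmax * num / den


def ncx_current(v: float, na_myo: float, ca_myo: float, params: NCXParams) -> float:
    """Na+/Ca2+ exchanger Ca flux (uM/ms); positive = Ca2+ extrusion
    (forward mode, 3 Na+ in : 1 Ca2+ out).  Zero at V = 3 E_Na - 2 E_Ca."""
    if min(na_myo, ca_myo) <= 0:
        raise ValueError("NCX requires positive ion concentrations")
    return float(_ncx(v, na_myo, ca_myo, params.na_o, params.ca_o,
                      params.vmax, params.km_na, params.km_ca,
                      params.eta, params.ksat))


@njit(cache=True)
def _pmca(ca, vmax, khalf, hill):
    x = (ca / khalf) ** hill
    return vmax * x / (1.0 + x)


def pmca_current(ca_myo: float, params: PMCAParams) -> float:
    """Plasma-membrane Ca2+ ATPase extrusion flux (uM/ms), Hill saturating;
    half of maximal rate exactly at ``k_half``."""
    if ca_myo < 0:
        raise ValueError("ca_myo must be non-negative")
    return float(_pmca(ca_myo, params.vmax, params.k_half, params.hill))


# ---------------------------------------------------------------------------
# shared linear-algebra helper
# ---------------------------------------------------------------------------


def markov_steady_state(G: np.ndarray) -> np.ndarray:
    """Stationary occupancy of a frozen generator: the normalised null-space
    vector of G (unique for an irreducible chain)."""
    n = G.shape[0]
    A = np.vstack([G, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    occ, *_ = np.linalg.lstsq(A, b, rcond=None)
    occ = np.clip(occ, 0.0, None)
    return occ / occ.sum()
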