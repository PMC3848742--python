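"""Sarcoplasmic-reticulum Ca2+ handling.

The SR is split into a longitudinal compartment (LSR, where the SERCA pumps
sit) and a junctional compartment (jSR, facing the dyad through the RyR
cluster and buffered by calsequestrin).  SERCA uptake is a bidirectional
saturable flux whose maximal rate and half-activation constants are modulated
by myoplasmic CaMKII directly and by phospholamban (PLB) phosphorylation:

* dephosphorylated PLB inhibits the pump; its two-state phosphorylation
  balance follows the first-order law with base rates k12PLB = 6800 s^-1 and
  k21PLB = 1000 s^-1, the dephosphorylation arm amplified by activated CaN
  (scaled x1e-4) and the phosphorylation arm by activated myoplasmic CaMKII
  (scaled x1e5) and the cAMP/PKA term F_cAMP,SERCA, all squared and applied
  multiplicatively;
* rising CaMKII lowers the forward half-activation constant (more Ca2+
  sensitivity of uptake) and raises the backward one (less back-flow).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .config import SRParams
from .neuro import f_camp_serca

__all__ = [
    "SRState", "plb_rhs", "plb_fixed_point", "serca_flux",
    "serca_vmax", "serca_ec50", "lsr_jsr_transfer", "csq_buffering",
]

MS = 1.0e-3

# published scaling of the activated-protein levels in the PLB law
CAN_SCALE = 1.0e-4
KII_SCALE = 1.0e5


@njit(cache=True)
def _plb_rate(plb_dp, can_term, kii_term, f_serca, k12, k21):
    plb_p = 1.0 - plb_dp
    fwd = k12 * (1.0 + can_term * can_term) * plb_p
    bwd = k21 * (1.0 + kii_term * kii_term + f_serca * f_serca) * plb_dp
    return fwd - bwd


def plb_rhs(plb_dp: float, can_myo: float, camkii_myo: float, camp: float,
            params: SRParams) -> float:
    """d(PLB_dp)/dt (1/ms): CaN drives dephosphorylation, CaMKII and cAMP/PKA
    drive phosphorylation; PLB_p = 1 - PLB_dp holds identically."""
    if not (0.0 <= plb_dp <= 1.0):
        raise ValueError(f"plb_dp outside [0,1]: {plb_dp}")
    return float(_plb_rate(plb_dp, can_myo * CAN_SCALE, camkii_myo * KII_SCALE,
                           f_camp_serca(camp), params.k12_plb * MS,
                           params.k21_plb * MS))


def plb_fixed_point(can_myo: float, camkii_myo: float, camp: float,
                    params: SRParams) -> float:
    """Algebraic steady state of the PLB two-state law."""
    k12 = params.k12_plb * (1.0 + (can_myo * CAN_SCALE) ** 2)
    f = f_camp_serca(camp)
    k21 = params.k21_plb * (1.0 + (camkii_myo * KII_SCALE) ** 2 + f * f)
    return k12 / (k12 + k21)


@dataclass
class SRState:
    """Dynamic SR state plus the current derived pump parameters."""

    ca_jsr: float
    ca_lsr: float
    csq_bound: float
    plb_dp: float

    @property
    def plb_p(self) -> float:
        return 1.0 - self.plb_dp


@njit(cache=True)
def _serca(ca_myo, ca_lsr, vmax, ec50f, ec50b, hill, backrate):
    fwd = (ca_myo / ec50f) ** hill
    bwd = (ca_lsr / ec50b) ** hill
    return vmax * (fwd - backrate * bwd) / (1.0 + fwd + bwd)


def serca_vmax(plb_p: float, camkii_myo: float, camp: float, params: SRParams) -> float:
    """Maximal pump rate (uM/ms): relieved by PLB phosphorylation, enhanced by
    direct CaMKII phosphorylation, with a small optional PKA arm."""
    kii = camkii_myo * KII_SCALE
    vmax = params.vmax_base * (1.0 + params.alpha_plb * plb_p) * (1.0 + params.alpha_kii * kii)
    if params.alpha_camp > 0:
        vmax *= 1.0 + params.alpha_camp * (f_camp_serca(camp) - f_camp_serca(2.67))
    return vmax


def serca_ec50(camkii_myo: float, params: SRParams) -> tuple[float, float]:
    """(forward, backward) half-activation constants (uM); the forward one
    decreases and the backward one increases monotonically with CaMKII."""
    kii = camkii_myo * KII_SCALE
    sat = kii / (1.0 + kii)
    return (params.ec50_f * (1.0 - params.ec50_f_kii * sat),
            params.ec50_b * (1.0 + params.ec50_b_kii * sat))


def serca_flux(ca_myo: float, ca_lsr: float, sr: SRState, camkii_myo: float,
               camp: float, params: SRParams) -> float:
    """Net SERCA uptake (uM/ms, myoplasm -> LSR, myoplasmic volume units)."""
    if ca_myo < 0 or ca_lsr < 0:
        raise ValueError("concentrations must be non-negative")
    ec50f, ec50b = serca_ec50(camkii_myo, params)
    vmax = serca_vmax(sr.plb_p, camkii_myo, camp, params)
    return float(_serca(ca_myo, ca_lsr, vmax, ec50f, ec50b, params.hill,
                        params.backrate))


def lsr_jsr_transfer(ca_lsr: float, ca_jsr: float, params: SRParams) -> float:
    """First-order LSR -> jSR transfer flux (uM/ms, myoplasmic volume units);
    its time constant sets the post-release jSR refilling delay."""
    if ca_lsr < 0 or ca_jsr < 0:
        raise ValueError("concentrations must be non-negative")
    return params.v_jsr * (ca_lsr - ca_jsr) / params.tau_tr_ms


def csq_buffering(ca_jsr: float, csq_bound: float, params: SRParams) -> tuple[float, float]:
    """Kinetic calsequestrin binding in the jSR.

    Returns ``(d ca_jsr/dt, d csq_bound/dt)`` contributions (uM/ms in jSR
    volume units); they are equal and opposite, conserving total jSR Ca.
    """
    if ca_jsr < 0 or csq_bound < 0 or csq_bound > params.csq_total:
        raise ValueError("invalid jSR buffering state")
    kon = params.csq_kon * MS
    koff = kon * params.csq_kd
    react = kon * ca_jsr * (params.csq_total - csq_bound) - koff * csq_bound
    return -react, react


def csq_equilibrium(ca_jsr: float, params: SRParams) -> float:
    """Isotherm occupancy of calsequestrin at a given free jSR Ca (uM)."""
    return params.csq_total * ca_jsr / (ca_jsr + params.csq_kd)
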