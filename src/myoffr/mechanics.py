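"""Isometric myofilament force generation (reduced cooperative/crossbridge model).

Regulatory Ca2+ binding to troponin uses two sites with a shared on-rate
konT = 22.22 uM^-1 s^-1 scaled by the unphosphorylated troponin-I fraction
(the PKA desensitisation mechanism) and off-rates koffHT = 17.36 s^-1
(high affinity) and koffLT = 173.61 s^-1 (low affinity, the regulatory
signal).  TnI phosphorylation is a two-state balance driven by the cAMP/PKA
term delta_PKA with konTI = 698.69 s^-1 and koffTI = 80 s^-1.

Thin-filament activation switches regulatory units between a crossbridge
non-permitting and a permitting state with base rates 500 s^-1 and 50 s^-1;
nearest-neighbour cooperativity enters as a power of the regulatory-site
occupancy, which makes the steady-state force-Ca2+ relation sigmoidal.
Permissive units cycle through a 3-state crossbridge scheme (unattached ->
pre-powerstroke -> post-powerstroke); the rates fapp, hf, hb and gxb carry a
cAMP factor F_cAMP,Force and a Q10 of 2.25, the regulatory switching rates do
not.  Normalised force is the weighted strongly-bound occupancy; the
sarcomere shortens internally against a series elastance in proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .config import MechanicsParams
from .neuro import delta_pka, f_camp_force

__all__ = [
    "MechState", "troponin_rhs", "troponin_fixed_point", "tni_rhs",
    "tni_fixed_point", "xb_rate_scaling", "crossbridge_rhs",
    "force_of_state", "force_ca_curve", "sarcomere_length",
]

MS = 1.0e-3


@dataclass
class MechState:
    ca_trop_h: float = 0.0     # high-affinity regulatory occupancy (fraction)
    ca_trop_l: float = 0.0     # low-affinity regulatory occupancy (fraction)
    tni_p: float = 0.0         # phosphorylated TnI fraction
    perm: float = 0.0          # crossbridge-permissive regulatory-unit fraction
    xb_pre: float = 0.0        # pre-powerstroke fraction (of all units)
    xb_post: float = 0.0       # post-powerstroke fraction (of all units)

    @property
    def tni_u(self) -> float:
        return 1.0 - self.tni_p

    def validate(self):
        vals = (self.ca_trop_h, self.ca_trop_l, self.tni_p, self.perm,
                self.xb_pre, self.xb_post)
        if any(v < -1e-12 or v > 1 + 1e-12 for v in vals):
            raise ValueError(f"myofilament fractions outside [0,1]: {vals}")
        if self.xb_pre + self.xb_post > self.perm + 1e-9:
            raise ValueError("crossbridge states exceed the permissive fraction")


# ---------------------------------------------------------------------------
# regulatory Ca2+ binding and TnI phosphorylation
# ---------------------------------------------------------------------------


@njit(cache=True)
def _trop_rates(ca, trop_h, trop_l, tni_u, kon_t, koff_ht, koff_lt):
    on = kon_t * tni_u * ca
    return on * (1.0 - trop_h) - koff_ht * trop_h, on * (1.0 - trop_l) - koff_lt * trop_l


def troponin_rhs(ca_myo: float, ca_trop_h: float, ca_trop_l: float,
                 tni_u: float, params: MechanicsParams) -> tuple[float, float]:
    """Derivatives (1/ms) of the high/low-affinity regulatory occupancies;
    the on-rate is scaled by the unphosphorylated TnI fraction."""
    if ca_myo < 0:
        raise ValueError("ca_myo must be non-negative")
    return _trop_rates(ca_myo, ca_trop_h, ca_trop_l, tni_u,
                       params.kon_t * MS, params.koff_ht * MS, params.koff_lt * MS)


def troponin_fixed_point(ca_myo: float, tni_u: float,
                         params: MechanicsParams) -> tuple[float, float]:
    on = params.kon_t * tni_u * ca_myo
    return on / (on + params.koff_ht), on / (on + params.koff_lt)


def tni_rhs(tni_p: float, camp: float, params: MechanicsParams) -> float:
    """d(TnI_p)/dt (1/ms) of the PKA-mediated TnI phosphorylation balance."""
    if not (0.0 <= tni_p <= 1.0):
        raise ValueError(f"tni_p outside [0,1]: {tni_p}")
    dp = delta_pka(camp)
    return params.kon_ti * MS * dp * (1.0 - tni_p) - params.koff_ti * MS * tni_p


def tni_fixed_point(camp: float, params: MechanicsParams) -> float:
    a = params.kon_ti * delta_pka(camp)
    return a / (a + params.koff_ti)


# ---------------------------------------------------------------------------
# crossbridge cycling
# ---------------------------------------------------------------------------


def xb_rate_scaling(camp: float, temperature: float,
                    params: MechanicsParams) -> dict[str, float]:
    """Scaled crossbridge rates (s^-1): base x F_cAMP,Force x Q10 factor.

    Only fapp, hf, hb and gxb are scaled (Q10 = 2.25 by default); the
    regulatory-unit switching rates (500/50 s^-1) and gapp are not.
    """
    if not (15.0 <= temperature <= 40.0):
        raise ValueError(f"temperature {temperature} C outside the valid 15-40 C range")
    scale = f_camp_force(camp) * params.q10 ** ((temperature - params.t_ref_c) / 10.0)
    return {
        "fapp": params.fapp * scale,
        "gapp": params.gapp,
        "hf": params.hf * scale,
        "hb": params.hb * scale,
        "gxb": params.gxb * scale,
    }


@njit(cache=True)
def _xb_rates(perm, pre, post, sig, k_np, k_pn, fapp, gapp, hf, hb, gxb):
    unbound = perm - pre - post
    if unbound < 0.0:
        unbound = 0.0
    dperm = k_np * sig * (1.0 - perm) - k_pn * unbound
    dpre = fapp * unbound - (gapp + hf) * pre + hb * post
    dpost = hf * pre - (hb + gxb) * post
    return dperm, dpre, dpost


@njit(cache=True)
def _coop_drive(s, s50, eta, cap):
    sig = (s / s50) ** eta
    if sig > cap:
        sig = cap
    return sig


def crossbridge_rhs(mech: MechState, scaled: dict[str, float],
                    params: MechanicsParams) -> dict[str, float]:
    """Derivatives (1/ms) of the permissive fraction and crossbridge states.

    The cooperative switching drive is a capped power of the low-affinity
    regulatory occupancy; crossbridge states never exceed the permissive
    fraction (units detach before switching off).
    """
    mech.validate()
    sig = _coop_drive(mech.ca_trop_l, params.s50, params.coop_eta, params.sigma_cap)
    dperm, dpre, dpost = _xb_rates(
        mech.perm, mech.xb_pre, mech.xb_post, sig,
        params.k_np * MS, params.k_pn * MS,
        scaled["fapp"] * MS, scaled["gapp"] * MS, scaled["hf"] * MS,
        scaled["hb"] * MS, scaled["gxb"] * MS,
    )
    return {"perm": dperm, "xb_pre": dpre, "xb_post": dpost}


def force_of_state(mech: MechState, params: MechanicsParams) -> float:
    """Normalised isometric force: weighted strongly-bound occupancy."""
    return (mech.xb_post + params.w_pre * mech.xb_pre) / params.force_ref


def sarcomere_length(force_norm: float, params: MechanicsParams) -> float:
    """Isometric sarcomere length (um): internal shortening against the
    series elastance, proportional to developed force."""
    return params.sl_rest - params.dsl_max * force_norm


# ---------------------------------------------------------------------------
# steady-state force-Ca relation (algebraic; used for CRCP extraction and as
# an independent oracle for the integrated steady state)
# ---------------------------------------------------------------------------


def force_ca_curve(ca: np.ndarray | float, camp: float = 2.67,
                   temperature: float | None = None,
                   params: MechanicsParams | None = None) -> np.ndarray:
    """Steady-state normalised force at fixed myoplasmic Ca (uM).

    Solves the regulatory and crossbridge balances algebraically: TnI at its
    cAMP fixed point, regulatory occupancy at its binding isotherm, then the
    linear 3-state crossbridge steady state within the permissive pool.
    """
    if params is None:
        raise ValueError("params required")
    temperature = params.temperature_c if temperature is None else temperature
    ca = np.atleast_1d(np.asarray(ca, dtype=float))
    tni_u = 1.0 - tni_fixed_point(camp, params)
    scaled = xb_rate_scaling(camp, temperature, params)
    fapp, gapp, hf, hb, gxb = (scaled[k] for k in ("fapp", "gapp", "hf", "hb", "gxb"))
    r2 = hf / (hb + gxb)
    d1 = gapp + hf - hb * r2
    r1 = fapp / d1
    occupancy = 1.0 + r1 + r1 * r2
    out = np.empty_like(ca)
    for i, c in enumerate(ca):
        on = params.kon_t * tni_u * c
        s_l = on / (on + params.koff_lt)
        sig = _coop_drive(s_l, params.s50, params.coop_eta, params.sigma_cap)
        a = params.k_np * sig
        perm = a / (a + params.k_pn / occupancy)
        unbound = perm / occupancy
        pre = r1 * unbound
        post = r2 * pre
        out[i] = (post + params.w_pre * pre) / params.force_ref
    return out if out.size > 1 else out
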