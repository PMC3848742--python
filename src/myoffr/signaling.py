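"""CaM-Ca2+ cooperative binding, CaM buffering, CaMKII and CaN activation.

Two compartments (dyadic cleft, bulk myoplasm) each carry a pool of total CaM
partitioned into apo-CaM, Ca2CaM (two Ca2+ on the C-terminal lobe), Ca4CaM
(two further Ca2+ on the N-terminal lobe) and buffer-bound CaM, plus activated
fractions of CaMKII and calcineurin (CaN):

* Ca2+ binds CaM cooperatively in two sequential 2-ion steps (C-lobe first),
  each step mass-action in [Ca2+]^2.
* A generic CaM buffer sequesters apo-CaM with compartment-specific rates; the
  dyadic buffer is much weaker, which leaves more CaM available there ("CaM
  enrichment") and is what lets dyadic CaMKII activity exceed myoplasmic
  activity by orders of magnitude.
* CaMKII subunit switching is modelled as a deterministic ODE on the expected
  active fraction, driven by Ca4CaM availability; deactivation is first order.
* CaN activation is driven by a weighted combination of Ca2CaM and Ca4CaM;
  the dissociation of the Ca4CaM-CaN complex is slow (rate << 1 s^-1), which
  makes dyadic CaN nearly constitutively active above a few Hz.

Activated CaMKII and CaN are carried in compartment-scoped concentration
units chosen so that the published scaling constants (x1e5, x1e-4 and the
coefficients of the facilitation term xi) produce order-one modulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from numba import njit
from scipy import optimize

from .config import CompartmentSignaling

__all__ = [
    "Compartment",
    "SignalingPool",
    "cam_rhs",
    "camkii_rhs",
    "can_rhs",
    "active_levels",
    "cam_equilibrium",
    "camkii_fixed_point",
    "can_fixed_point",
]

MS = 1.0e-3  # s^-1 -> ms^-1


class Compartment(str, Enum):
    dyad = "dyad"
    myoplasm = "myoplasm"


@dataclass
class SignalingPool:
    """State of one compartment's signalling pool.

    ``ca2cam``, ``ca4cam`` and ``cam_buffer_bound`` are fractions of total CaM
    (apo-CaM is the conserved remainder); ``camkii_active`` and ``can_active``
    are activated levels in compartment-scoped concentration units.
    """

    compartment_id: Compartment
    params: CompartmentSignaling
    ca2cam: float = 0.0
    ca4cam: float = 0.0
    cam_buffer_bound: float = 0.0
    camkii_active: float = 0.0
    can_active: float = 0.0

    @property
    def apo(self) -> float:
        return 1.0 - self.ca2cam - self.ca4cam - self.cam_buffer_bound

    def validate(self) -> None:
        fracs = (self.ca2cam, self.ca4cam, self.cam_buffer_bound, self.apo)
        if any(f < -1e-12 or f > 1.0 + 1e-12 for f in fracs):
            raise ValueError(f"CaM species fractions out of [0,1]: {fracs}")
        if not (0.0 <= self.camkii_active <= self.params.camkii_total * (1 + 1e-12)):
            raise ValueError("camkii_active outside [0, total]")
        if not (0.0 <= self.can_active <= self.params.can_total * (1 + 1e-12)):
            raise ValueError("can_active outside [0, total]")


# ---------------------------------------------------------------------------
# jitted scalar cores (shared with the simulation kernel); rates in ms^-1
# ---------------------------------------------------------------------------


@njit(cache=True)
def _cam_rates(ca, ca2, ca4, camb, kon_c, koff_c, kon_n, koff_n, kon_buf, koff_buf):
    """Time-derivatives (1/ms) of the CaM species fractions."""
    apo = 1.0 - ca2 - ca4 - camb
    ca_sq = ca * ca
    j_c = kon_c * ca_sq * apo - koff_c * ca2
    j_n = kon_n * ca_sq * ca2 - koff_n * ca4
    j_b = kon_buf * apo - koff_buf * camb
    dca2 = j_c - j_n
    dca4 = j_n
    dcamb = j_b
    return dca2, dca4, dcamb


@njit(cache=True)
def _camkii_rate(ca4, kii, kii_total, kon_kii, koff_kii):
    return kon_kii * ca4 * (kii_total - kii) - koff_kii * kii


@njit(cache=True)
def _can_rate(ca2, ca4, can, can_total, kon_can, koff_can, w2, w4):
    drive = w2 * ca2 + w4 * ca4
    return kon_can * drive * (can_total - can) - koff_can * can


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def cam_rhs(pool: SignalingPool, ca_local: float) -> dict[str, float]:
    """Derivatives (1/ms) of the CaM species fractions at local free Ca (uM).

    Mass conservation: the apo-CaM derivative is minus the sum of the returned
    derivatives, so total CaM is conserved exactly.
    """
    if ca_local < 0:
        raise ValueError(f"negative Ca2+ concentration: {ca_local}")
    pool.validate()
    p = pool.params
    dca2, dca4, dcamb = _cam_rates(
        ca_local, pool.ca2cam, pool.ca4cam, pool.cam_buffer_bound,
        p.kon_c * MS, p.koff_c * MS, p.kon_n * MS, p.koff_n * MS,
        p.kon_buf * MS, p.koff_buf * MS,
    )
    return {"ca2cam": dca2, "ca4cam": dca4, "cam_buffer_bound": dcamb,
            "apo": -(dca2 + dca4 + dcamb)}


def camkii_rhs(pool: SignalingPool) -> float:
    """Derivative (units/ms) of activated CaMKII, driven by Ca4CaM."""
    pool.validate()
    p = pool.params
    return _camkii_rate(pool.ca4cam, pool.camkii_active, p.camkii_total,
                        p.kon_kii * MS, p.koff_kii * MS)


def can_rhs(pool: SignalingPool) -> float:
    """Derivative (units/ms) of activated CaN, driven by Ca2CaM and Ca4CaM."""
    pool.validate()
    p = pool.params
    return _can_rate(pool.ca2cam, pool.ca4cam, pool.can_active, p.can_total,
                     p.kon_can * MS, p.koff_can * MS, p.w_ca2, p.w_ca4)


def active_levels(time_ms: np.ndarray, signal: np.ndarray, period_ms: float) -> float:
    """Cycle-average of a signal over exactly the final full pacing cycle.

    Raises if the trace does not cover one full cycle at its sampling grid.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if time_ms.shape != signal.shape or time_ms.ndim != 1:
        raise ValueError("time and signal must be 1-D arrays of equal length")
    t_end = time_ms[-1]
    t_start = t_end - period_ms
    if t_start < time_ms[0] - 1e-9:
        raise ValueError("trace shorter than one pacing cycle")
    mask = time_ms >= t_start - 1e-9
    t, s = time_ms[mask], signal[mask]
    return float(np.trapezoid(s, t) / (t[-1] - t[0]))


# ---------------------------------------------------------------------------
# independent equilibrium / fixed-point solvers (used by tests and rest-state
# construction; root-finding on the mass-action equations, not integration)
# ---------------------------------------------------------------------------


def cam_equilibrium(params: CompartmentSignaling, ca: float) -> dict[str, float]:
    """Algebraic equilibrium of the two-step CaM scheme with buffering."""
    ca_sq = ca * ca
    r_c = params.kon_c * ca_sq / params.koff_c          # ca2/apo
    r_n = params.kon_n * ca_sq / params.koff_n          # ca4/ca2
    r_b = params.kon_buf / params.koff_buf              # camb/apo
    apo = 1.0 / (1.0 + r_c + r_c * r_n + r_b)
    return {
        "apo": apo,
        "ca2cam": apo * r_c,
        "ca4cam": apo * r_c * r_n,
        "cam_buffer_bound": apo * r_b,
    }


def camkii_fixed_point(params: CompartmentSignaling, ca4: float) -> float:
    """Steady activated CaMKII under constant Ca4CaM, found by bisection."""

    def rhs(kii):
        return _camkii_rate(ca4, kii, params.camkii_total,
                            params.kon_kii * MS, params.koff_kii * MS)

    if ca4 <= 0:
        return 0.0
    return float(optimize.brentq(rhs, 0.0, params.camkii_total))


def can_fixed_point(params: CompartmentSignaling, ca2: float, ca4: float) -> float:
    """Steady activated CaN under constant CaM species, found by bisection."""

    def rhs(can):
        return _can_rate(ca2, ca4, can, params.can_total,
                         params.kon_can * MS, params.koff_can * MS,
                         params.w_ca2, params.w_ca4)

    if params.w_ca2 * ca2 + params.w_ca4 * ca4 <= 0:
        return 0.0
    return float(optimize.brentq(rhs, 0.0, params.can_total))
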