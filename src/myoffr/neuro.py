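"""beta-adrenergic neuromodulation: cAMP level and its closed-form target factors.

The model treats sympathetic (isoproterenol / norepinephrine) stimulation as a
frequency-dependent intracellular cAMP concentration.  Under basal conditions
cAMP sits at 2.67 uM at every pacing rate; under maximal beta-adrenergic
stimulation it follows an empirical table of anchor points rising from
2.67 uM below ~1.67 Hz to 29.17 uM at 12 Hz.  cAMP then scales four targets
through saturating exponentials / Michaelis forms:

* ``f_camp_ical``  -- conductance scaling of the L-type Ca2+ current,
* ``f_camp_serca`` -- PKA arm of phospholamban phosphorylation (SERCA uptake),
* ``delta_pka``    -- PKA drive for troponin-I phosphorylation
  (myofilament Ca2+ desensitisation),
* ``f_camp_force`` -- crossbridge-kinetics scaling.

cGMP is carried as a constant with no downstream coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "BetaState",
    "NeuroState",
    "CAMP_BASAL",
    "CAMP_TABLE_FREQ",
    "CAMP_TABLE_CONC",
    "camp_level",
    "f_camp_ical",
    "f_camp_serca",
    "delta_pka",
    "f_camp_force",
]

#: basal intracellular cAMP concentration (uM), frequency independent
CAMP_BASAL = 2.67

#: anchor points for maximal beta-adrenergic stimulation: (frequency Hz, cAMP uM).
#: Below 1.67 Hz the level is a plateau at the basal 2.67 uM.
CAMP_TABLE_FREQ = np.array(
    [0.50, 1.67, 2.50, 2.86, 3.33, 4.00, 5.00, 5.71, 6.67, 8.00, 10.00, 12.00]
)
CAMP_TABLE_CONC = np.array(
    [2.67, 2.67, 3.00, 3.19, 3.45, 3.85, 4.67, 5.58, 18.06, 24.58, 27.03, 29.17]
)

FREQ_MIN = 0.5
FREQ_MAX = 12.0


class BetaState(str, Enum):
    """Sympathetic tone of the simulated cell."""

    basal = "basal"
    maximal = "maximal"


def camp_level(
    frequency: float,
    beta_state: BetaState | str = BetaState.basal,
    *,
    interpolation: str = "linear",
) -> float:
    """Intracellular cAMP concentration (uM) at a given pacing frequency.

    Parameters
    ----------
    frequency
        Pacing frequency in Hz; must lie in [0.5, 12].
    beta_state
        ``basal`` (2.67 uM at all rates) or ``maximal`` (table lookup).
    interpolation
        ``"linear"`` (default) interpolates between table anchors;
        ``"step"`` holds the value of the nearest anchor at or below the
        requested frequency.
    """
    if not (FREQ_MIN <= frequency <= FREQ_MAX):
        raise ValueError(
            f"pacing frequency {frequency} Hz outside supported range "
            f"[{FREQ_MIN}, {FREQ_MAX}] Hz"
        )
    beta_state = BetaState(beta_state)
    if beta_state is BetaState.basal or frequency <= CAMP_TABLE_FREQ[1]:
        return CAMP_BASAL
    if interpolation == "linear":
        return float(np.interp(frequency, CAMP_TABLE_FREQ, CAMP_TABLE_CONC))
    if interpolation == "step":
        idx = int(np.searchsorted(CAMP_TABLE_FREQ, frequency, side="right") - 1)
        return float(CAMP_TABLE_CONC[idx])
    raise ValueError(f"unknown interpolation mode {interpolation!r}")


def f_camp_ical(camp: float) -> float:
    """Conductance scaling factor for the L-type Ca2+ current.

    ``1.094 - 0.163*exp(-0.219*[cAMP])``; strictly increasing in cAMP with
    range (0.931, 1.094).
    """
    _check_camp(camp)
    return 1.094 - 0.163 * np.exp(-0.219 * camp)


def f_camp_serca(camp: float) -> float:
    """PKA/cAMP term entering phospholamban phosphorylation.

    ``0.1094 - 0.0163*exp(-0.219*[cAMP])``, range (0.0931, 0.1094).
    """
    _check_camp(camp)
    return 0.1094 - 0.0163 * np.exp(-0.219 * camp)


def delta_pka(camp: float) -> float:
    """Fraction of PKA drive for troponin-I phosphorylation.

    Saturating Michaelis form ``0.3*[cAMP]/([cAMP]+12.1)``; range [0, 0.3).
    """
    _check_camp(camp)
    return 0.3 * camp / (camp + 12.1)


def f_camp_force(camp: float) -> float:
    """Crossbridge-kinetics scaling factor.

    ``1.873 - 1.4*exp(-0.192*[cAMP])``, range (0.473, 1.873).
    """
    _check_camp(camp)
    return 1.873 - 1.4 * np.exp(-0.192 * camp)


def _check_camp(camp: float) -> None:
    if camp < 0:
        raise ValueError(f"cAMP concentration must be non-negative, got {camp}")


@dataclass
class NeuroState:
    """Resolved neuromodulatory state for one simulation run.

    ``camp`` may be pinned explicitly (dose-response experiments); otherwise it
    is derived from ``beta_state`` and the pacing frequency.
    """

    beta_state: BetaState = BetaState.basal
    camp: float = CAMP_BASAL
    cgmp: float = 2.0  # uM, constant; no downstream coupling in this model
    factors: dict = field(default_factory=dict)

    @classmethod
    def for_frequency(
        cls,
        frequency: float,
        beta_state: BetaState | str = BetaState.basal,
        camp_override: float | None = None,
    ) -> "NeuroState":
        beta_state = BetaState(beta_state)
        camp = camp_override if camp_override is not None else camp_level(
            frequency, beta_state
        )
        state = cls(beta_state=beta_state, camp=camp)
        state.factors = {
            "f_ical": f_camp_ical(camp),
            "f_serca": f_camp_serca(camp),
            "f_force": f_camp_force(camp),
            "delta_pka": delta_pka(camp),
        }
        return state
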