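"""Post-processing of pacing runs.

Per-cycle transient and force metrics (extrema and maximal rates by centred
differences on the saved sampling grid), force-frequency tables, EC-coupling
gain (paired runs with release enabled/disabled), force-Ca2+ phase loops with
the contraction-relaxation coupling point (CRCP), and the relative share of
SERCA vs NCX + PMCA in removing the systolic Ca2+ rise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .config import ModelConfig
from .engine import RunResult, frequency_sweep, run_to_steady_state
from .mechanics import force_ca_curve

__all__ = [
    "CycleMetrics", "cycle_metrics", "ffr_curve", "ec_gain",
    "phase_loop", "serca_share",
]


@dataclass
class CycleMetrics:
    peak_ca: float          # uM
    min_ca: float           # uM
    r_rise: float           # uM/s, max d[Ca]/dt
    r_decay: float          # uM/s, max -d[Ca]/dt
    peak_force: float       # normalised
    min_force: float        # normalised
    r_act: float            # 1/s, max dF/dt
    r_relax: float          # 1/s, max -dF/dt
    min_sl: float           # um
    peak_ical: float        # |flux| units
    peak_iryr: float        # flux units
    pre_release_jsr: float  # uM
    post_release_jsr: float  # uM

    def validate(self):
        pairs = [(self.peak_ca, self.min_ca), (self.peak_force, self.min_force),
                 (self.pre_release_jsr, self.post_release_jsr)]
        if any(hi < lo - 1e-12 for hi, lo in pairs):
            raise ValueError("cycle metrics: peak below minimum")
        if min(self.r_rise, self.r_decay, self.r_act, self.r_relax) < 0:
            raise ValueError("cycle metrics: negative rate")


def _max_slope(t_ms: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """(max rise, max fall) of dx/dt in 1/s by centred differences."""
    d = np.gradient(x, t_ms) * 1000.0
    return float(d.max()), float(-d.min())


def cycle_metrics(traces: pd.DataFrame, period_ms: float | None = None) -> CycleMetrics:
    """Metrics of one steady cycle.  ``traces`` must cover exactly one cycle
    (pass ``RunResult.final_cycle``) or ``period_ms`` is used to crop it."""
    df = traces
    if period_ms is not None:
        t_end = df["time_ms"].iloc[-1]
        df = df[df["time_ms"] > t_end - period_ms + 1e-9]
    t = df["time_ms"].to_numpy()
    ca = df["ca_myo"].to_numpy()
    force = df["force"].to_numpy()
    r_rise, r_decay = _max_slope(t, ca)
    r_act, r_relax = _max_slope(t, force)
    m = CycleMetrics(
        peak_ca=float(ca.max()), min_ca=float(ca.min()),
        r_rise=max(r_rise, 0.0), r_decay=max(r_decay, 0.0),
        peak_force=float(force.max()), min_force=float(force.min()),
        r_act=max(r_act, 0.0), r_relax=max(r_relax, 0.0),
        min_sl=float(df["sl"].min()),
        peak_ical=float(np.abs(df["i_cal"]).max()),
        peak_iryr=float(df["j_ryr"].max()),
        pre_release_jsr=float(df["ca_jsr"].max()),
        post_release_jsr=float(df["ca_jsr"].min()),
    )
    m.validate()
    return m


def ffr_curve(cfg: ModelConfig, frequencies, beta_state: str = "basal", *,
              continuation: bool = True,
              results: dict[float, RunResult] | None = None) -> pd.DataFrame:
    """Steady-state force-frequency table: one row per frequency with the
    cycle metrics of the final cycle.  Pass precomputed ``results`` to avoid
    re-running the sweep."""
    frequencies = sorted(frequencies)
    if len(frequencies) < 1:
        raise ValueError("at least one frequency required")
    if results is None:
        results = frequency_sweep(cfg, frequencies, beta_state,
                                  continuation=continuation)
    rows = []
    for f in frequencies:
        res = results[f]
        m = cycle_metrics(res.final_cycle)
        row = {"frequency": f, "beta_state": beta_state, **asdict(m)}
        row["converged"] = res.converged
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("frequency").reset_index(drop=True)
    df.attrs["argmax_force_hz"] = float(df.loc[df["peak_force"].idxmax(), "frequency"])
    return df


def ec_gain(cfg: ModelConfig, frequency: float, beta_state: str = "basal", *,
            init=None, init_no_cicr=None) -> float:
    """EC-coupling gain: peak myoplasmic Ca2+ transient with CICR divided by
    the transient from the trigger Ca2+ alone (RyR release disabled)."""
    with_ryr = run_to_steady_state(cfg, frequency, beta_state, init=init)
    cfg_off = cfg.replace(ryr={"perm": 0.0})
    without = run_to_steady_state(cfg_off, frequency, beta_state, init=init_no_cicr)
    peak_on = cycle_metrics(with_ryr.final_cycle).peak_ca
    peak_off = cycle_metrics(without.final_cycle).peak_ca
    if peak_off <= 0:
        raise ZeroDivisionError("trigger-only transient vanished")
    return peak_on / peak_off


def phase_loop(result: RunResult) -> dict:
    """Force vs Ca2+ phase loop of the final cycle and its CRCP.

    The CRCP is the point where the relaxation limb of the loop crosses the
    steady-state force-Ca2+ relation; loop area is computed by the shoelace
    formula (positive for the physiological counter-clockwise orientation).
    """
    df = result.final_cycle
    ca = df["ca_myo"].to_numpy()
    force = df["force"].to_numpy()
    ss = force_ca_curve(ca, camp=result.camp, params=result.config.mechanics)
    i_pk = int(np.argmax(force))
    resid = force[i_pk:] - ss[i_pk:]
    crcp_ca = crcp_force = np.nan
    for k in range(1, len(resid)):
        if resid[k - 1] > 0 >= resid[k]:
            w = resid[k - 1] / (resid[k - 1] - resid[k])
            crcp_ca = ca[i_pk + k - 1] + w * (ca[i_pk + k] - ca[i_pk + k - 1])
            crcp_force = force[i_pk + k - 1] + w * (force[i_pk + k] - force[i_pk + k - 1])
            break
    area = 0.5 * float(np.sum(ca * np.roll(force, -1) - np.roll(ca, -1) * force))
    return {"ca": ca, "force": force, "crcp_ca": float(crcp_ca),
            "crcp_force": float(crcp_force), "area": abs(area)}


def serca_share(result: RunResult) -> float:
    """Fraction of systolic Ca2+ removal carried by SERCA (vs NCX + PMCA)
    over the decay phase, from the cycle's Ca2+ peak to the next stimulus."""
    df = result.final_cycle
    t = df["time_ms"].to_numpy()
    i_pk = int(np.argmax(df["ca_myo"].to_numpy()))
    sl = slice(i_pk, None)
    tt = t[sl]
    j_up = np.clip(df["j_serca"].to_numpy()[sl], 0.0, None)
    j_ncx = np.clip(df["j_ncx"].to_numpy()[sl], 0.0, None)
    j_pmca = np.clip(df["j_pmca"].to_numpy()[sl], 0.0, None)
    up = np.trapezoid(j_up, tt)
    out = np.trapezoid(j_ncx, tt) + np.trapezoid(j_pmca, tt)
    if up + out <= 0:
        raise ValueError("no removal flux in the decay phase")
    return float(up / (up + out))
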