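"""Time integration of the coupled cell model under voltage-clamp pacing.

The voltage command is a square pulse train (default: 50 ms steps to +10 mV
from a -40 mV holding potential).  The dyadic reaction-diffusion grid is
advanced by operator splitting with explicit sub-steps inside each global
step; all other state advances with a fixed-step 5-stage Merson Runge-Kutta
scheme (classic RK4 selectable).  Pacing runs continue either for a fixed
cycle count or until the per-cycle peak myoplasmic Ca2+ and peak force both
change by less than a relative tolerance between consecutive cycles.

A strict whole-cell Ca2+ balance is maintained: every internal flux moves
mass between tracked pools exactly, so the change of total cell Ca2+ over any
window equals the integral of the sarcolemmal pathways (L-type influx plus
background leak minus NCX and PMCA extrusion).  ``ca_balance_audit`` checks
this from the recorded traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel as K
from .config import ModelConfig
from .currents import markov_steady_state, lcc_generator, ryr_generator, cdi_steady
from .dyad import radial_weights, radial_stability_dt
from .mechanics import tni_fixed_point, troponin_fixed_point, force_ca_curve
from .neuro import BetaState, NeuroState
from .signaling import cam_equilibrium, camkii_fixed_point, can_fixed_point
from .sr import csq_equilibrium, plb_fixed_point

__all__ = [
    "PacingProtocol", "RunResult", "NumericalError", "build_protocol",
    "resting_state", "integrate", "run_to_steady_state", "frequency_sweep",
    "ca_balance_audit", "total_cell_ca", "merson_integrate",
]

FREQ_MIN, FREQ_MAX = 0.5, 12.0


class NumericalError(RuntimeError):
    """Raised when integration produces NaN or a negative concentration."""


@dataclass(frozen=True)
class PacingProtocol:
    frequency: float
    v_hold: float = -40.0
    v_step: float = 10.0
    pulse_ms: float = 50.0
    n_cycles: int = 150
    convergence_tol: float = 1.0e-4

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.frequency

    def __post_init__(self):
        if not (FREQ_MIN <= self.frequency <= FREQ_MAX):
            raise ValueError(f"frequency {self.frequency} Hz outside [{FREQ_MIN}, {FREQ_MAX}]")
        if self.pulse_ms >= self.period_ms:
            raise ValueError(
                f"pulse duration {self.pulse_ms} ms must be shorter than the "
                f"cycle period {self.period_ms} ms")


def build_protocol(frequency: float, cfg: ModelConfig | None = None,
                   **overrides) -> PacingProtocol:
    """Square-pulse voltage-clamp protocol at the given pacing frequency."""
    kw = {}
    if cfg is not None:
        kw.update(v_hold=cfg.protocol.v_hold, v_step=cfg.protocol.v_step,
                  pulse_ms=cfg.protocol.pulse_ms,
                  n_cycles=cfg.engine.n_cycles,
                  convergence_tol=cfg.engine.convergence_tol)
    kw.update(overrides)
    return PacingProtocol(frequency=frequency, **kw)


@dataclass
class RunResult:
    """Outcome of a pacing run: final-cycle traces, per-cycle summaries and
    the complete final state (reusable as a warm start)."""

    traces: pd.DataFrame
    cycle_metrics: pd.DataFrame
    config: ModelConfig
    protocol: PacingProtocol
    camp: float
    state: tuple[np.ndarray, np.ndarray, np.ndarray]
    params: np.ndarray
    converged: bool
    stop_reason: str
    n_cycles_run: int
    balance: dict = field(default_factory=dict)

    @property
    def final_cycle(self) -> pd.DataFrame:
        t_end = self.traces["time_ms"].iloc[-1]
        period = self.protocol.period_ms
        return self.traces[self.traces["time_ms"] > t_end - period + 1e-9]


# ---------------------------------------------------------------------------
# initial state
# ---------------------------------------------------------------------------


def resting_state(cfg: ModelConfig, camp: float = 2.67):
    """Quiescent-cell state: every pool at its algebraic fixed point for the
    resting concentrations, the cleft grid uniform at resting Ca2+."""
    e, sig = cfg.engine, cfg.signaling
    ca0, sr0 = e.ca_rest, e.ca_sr_rest
    y = np.zeros(K.NY)
    y[K.Y_CAMYO] = ca0
    y[K.Y_NA] = cfg.na.na_rest
    y[K.Y_CALSR] = sr0
    y[K.Y_CAJSR] = sr0
    y[K.Y_CSQ] = csq_equilibrium(sr0, cfg.sr)
    kd_b = e.buf_myo_koff / e.buf_myo_kon
    y[K.Y_BUFM] = e.buf_myo_total * ca0 / (ca0 + kd_b)

    # signalling pools at the resting-Ca fixed points
    for prefix, comp in (("D", sig.dyad), ("M", sig.myo)):
        eq = cam_equilibrium(comp, ca0)
        kii = camkii_fixed_point(comp, eq["ca4cam"])
        can = can_fixed_point(comp, eq["ca2cam"], eq["ca4cam"])
        base = K.Y_DCA2 if prefix == "D" else K.Y_MCA2
        y[base + 0] = eq["ca2cam"]
        y[base + 1] = eq["ca4cam"]
        y[base + 2] = eq["cam_buffer_bound"]
        y[base + 3] = kii
        y[base + 4] = can

    # channels at the holding potential
    G = lcc_generator(cfg.protocol.v_hold, y[K.Y_DKII], y[K.Y_DCAN], cfg.lcc)
    y[K.Y_LCC0:K.Y_LCC0 + 6] = markov_steady_state(G)
    y[K.Y_CDI] = cdi_steady(ca0, cfg.lcc)
    Gr = ryr_generator(ca0, y[K.Y_DKII], 0.0, cfg.ryr, K.RYR_KII_REF)
    y[K.Y_RYRC:K.Y_RYRC + 4] = markov_steady_state(Gr)
    y[K.Y_WLUM] = 0.0

    y[K.Y_PLBDP] = plb_fixed_point(y[K.Y_MCAN], y[K.Y_MKII], camp, cfg.sr)
    y[K.Y_TNIP] = tni_fixed_point(camp, cfg.mechanics)
    th, tl = troponin_fixed_point(ca0, 1.0 - y[K.Y_TNIP], cfg.mechanics)
    y[K.Y_TROPH], y[K.Y_TROPL] = th, tl
    # crossbridges at the algebraic steady state for resting Ca
    m = cfg.mechanics
    sig_d = min((tl / m.s50) ** m.coop_eta, m.sigma_cap)
    r2 = m.hf / (m.hb + m.gxb)
    d1 = m.gapp + m.hf - m.hb * r2
    r1 = m.fapp / d1
    occ = 1.0 + r1 + r1 * r2
    a = m.k_np * sig_d
    perm = a / (a + m.k_pn / occ)
    y[K.Y_PERM] = perm
    y[K.Y_XBPRE] = r1 * perm / occ
    y[K.Y_XBPOST] = r2 * r1 * perm / occ

    gca = np.full((cfg.dyad.nr, cfg.dyad.nz), ca0)
    kd_g = cfg.dyad.buf_koff / max(cfg.dyad.buf_kon, 1e-30)
    gbuf = np.full((cfg.dyad.nr, cfg.dyad.nz),
                   cfg.dyad.buf_total * ca0 / (ca0 + kd_g))
    return y, gca, gbuf


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def _resolve_camp(cfg: ModelConfig, frequency: float,
                  beta_state: str | BetaState | None) -> float:
    beta = beta_state if beta_state is not None else cfg.neuro.beta_state
    ns = NeuroState.for_frequency(frequency, beta,
                                  camp_override=cfg.neuro.camp_override)
    return ns.camp


def _grid_substeps(cfg: ModelConfig) -> int:
    # axial diffusion is implicit in the kernel's ADI sub-step, so only the
    # radial explicit bound restricts the sub-step length
    dt_ms = cfg.engine.dt_us * 1e-3
    bound = 0.8 * radial_stability_dt(cfg.dyad)
    return max(1, int(np.ceil(dt_ms / bound)))


def integrate(cfg: ModelConfig, protocol: PacingProtocol, *,
              beta_state: str | None = None, init=None,
              camp: float | None = None) -> RunResult:
    """Pace the cell for up to ``protocol.n_cycles`` cycles, stopping early
    once the per-cycle peaks of myoplasmic Ca2+ and force both converge."""
    if camp is None:
        camp = _resolve_camp(cfg, protocol.frequency, beta_state)
    n_sub = _grid_substeps(cfg)
    P = K.pack_params(cfg, camp, n_sub)
    P[K.P_VHOLD], P[K.P_VSTEP] = protocol.v_hold, protocol.v_step
    if init is None:
        y, gca, gbuf = resting_state(cfg, camp)
    else:
        y, gca, gbuf = (np.array(a, dtype=np.float64, copy=True) for a in init)
    w_r = radial_weights(cfg.dyad.nr)

    dt = cfg.engine.dt_us * 1e-3
    period = protocol.period_ms
    n_steps = int(np.rint(period / dt))
    if abs(n_steps * dt - period) > 1e-9 * period:
        dt = period / n_steps  # commensurate step (exact cycle length)
    out_stride = max(1, int(np.rint(cfg.engine.output_dt_ms / dt)))
    n_samp = (n_steps + out_stride - 1) // out_stride

    scheme = 0 if cfg.engine.scheme == "merson" else 1
    tol = protocol.convergence_tol
    prev_traces: list[np.ndarray] = []
    metrics = []
    peak_ca_prev = peak_f_prev = None
    converged = False
    stop_reason = "n_cycles"
    t0 = 0.0
    total_before = total_cell_ca(y, gca, gbuf, P)
    n_run = 0
    for cyc in range(protocol.n_cycles):
        total_start = total_cell_ca(y, gca, gbuf, P)
        trace = np.zeros((n_samp, K.NSIG))
        n_out = K.run_cycle(y, gca, gbuf, P, w_r, period, protocol.pulse_ms,
                            dt, out_stride, scheme, trace, t0)
        if n_out < 0:
            raise NumericalError(
                f"integration failed in cycle {cyc}: non-finite or negative "
                f"value in state slice index {-n_out - 1}")
        _clean_simplexes(y)
        t0 += period
        n_run = cyc + 1
        trace = trace[:n_out]
        prev_traces.append(trace)
        if len(prev_traces) > 2:
            prev_traces.pop(0)
        peak_ca = trace[:, K.SIG_CA_MYO].max()
        peak_f = trace[:, K.SIG_FORCE].max()
        metrics.append({
            "cycle": cyc, "peak_ca": peak_ca,
            "min_ca": trace[:, K.SIG_CA_MYO].min(),
            "peak_force": peak_f, "min_force": trace[:, K.SIG_FORCE].min(),
            "peak_ical": np.abs(trace[:, K.SIG_I_CAL]).max(),
            "po_ryr_max": trace[:, K.SIG_PO_RYR].max(),
            "jsr_max": trace[:, K.SIG_CA_JSR].max(),
            "jsr_min": trace[:, K.SIG_CA_JSR].min(),
            "total_ca_start": total_start,
        })
        if peak_ca_prev is not None and tol > 0:
            dca = abs(peak_ca - peak_ca_prev) / max(peak_ca_prev, 1e-12)
            dfo = abs(peak_f - peak_f_prev) / max(peak_f_prev, 1e-12)
            if dca < tol and dfo < tol:
                converged = True
                stop_reason = "convergence"
                break
        peak_ca_prev, peak_f_prev = peak_ca, peak_f

    total_after = total_cell_ca(y, gca, gbuf, P)
    df = pd.DataFrame(np.vstack(prev_traces), columns=K.SIG_NAMES)
    m = cfg.mechanics
    df["sl"] = m.sl_rest - m.dsl_max * df["force"]
    result = RunResult(
        traces=df, cycle_metrics=pd.DataFrame(metrics), config=cfg,
        protocol=protocol, camp=camp, state=(y, gca, gbuf), params=P,
        converged=converged, stop_reason=stop_reason, n_cycles_run=n_run,
    )
    delta_final = total_after - metrics[-1]["total_ca_start"]
    result.balance = ca_balance_audit(result, delta_total=delta_final)
    result.balance["total_run_delta"] = total_after - total_before
    return result


def _clean_simplexes(y: np.ndarray) -> None:
    """Clip round-off negatives (< 1e-12) and renormalise Markov occupancies."""
    for base, n in ((K.Y_LCC0, 6), (K.Y_RYRC, 4)):
        occ = y[base:base + n]
        occ[occ < 0.0] = 0.0
        s = occ.sum()
        if abs(s - 1.0) > 1e-9:
            occ /= s
        y[base:base + n] = occ


def run_to_steady_state(cfg: ModelConfig, frequency: float,
                        beta_state: str | None = None, *,
                        init=None) -> RunResult:
    """Pace at ``frequency`` until steady state (convergence-stop, capped at
    the configured cycle count)."""
    protocol = build_protocol(frequency, cfg)
    return integrate(cfg, protocol, beta_state=beta_state, init=init)


def frequency_sweep(cfg: ModelConfig, frequencies, beta_state: str | None = None,
                    *, continuation: bool = True) -> dict[float, RunResult]:
    """Steady-state runs over a set of pacing frequencies.

    With ``continuation`` (default) the frequencies are run in increasing
    order and each run is warm-started from the previous frequency's final
    state, mirroring an experimental ramp protocol; slow states (Na+, CaN,
    accumulated Ca4CaM) then settle well within the per-frequency cycle cap.
    """
    results: dict[float, RunResult] = {}
    init = None
    for f in sorted(frequencies):
        res = run_to_steady_state(cfg, f, beta_state, init=init if continuation else None)
        results[f] = res
        if continuation:
            init = res.state
    return results


# ---------------------------------------------------------------------------
# Ca balance audit
# ---------------------------------------------------------------------------


def total_cell_ca(y: np.ndarray, gca: np.ndarray, gbuf: np.ndarray,
                  P: np.ndarray) -> float:
    """Total cell Ca2+ (uM, myoplasmic volume units): free + all buffers +
    SR + dyad, the conserved quantity of the sealed cell."""
    w = radial_weights(gca.shape[0])
    gmean_free = float(np.sum(w[:, None] * gca) / gca.shape[1])
    gmean_buf = float(np.sum(w[:, None] * gbuf) / gbuf.shape[1])
    cam_d = P[K.P_DCAMT] * (2.0 * y[K.Y_DCA2] + 4.0 * y[K.Y_DCA4])
    cam_m = P[K.P_MCAMT] * (2.0 * y[K.Y_MCA2] + 4.0 * y[K.Y_MCA4])
    return (
        y[K.Y_CAMYO] + y[K.Y_BUFM] + cam_m
        + P[K.P_TROPHT] * y[K.Y_TROPH] + P[K.P_TROPLT] * y[K.Y_TROPL]
        + P[K.P_VLSR] * y[K.Y_CALSR]
        + P[K.P_VJSR] * (y[K.Y_CAJSR] + y[K.Y_CSQ])
        + P[K.P_VFRAC] * (gmean_free + gmean_buf + cam_d)
    )


def ca_balance_audit(result: RunResult, delta_total: float | None = None,
                     tolerance: float = 0.005) -> dict:
    """Check that the change in total cell Ca2+ over the final cycle equals
    the integrated sarcolemmal fluxes (trigger influx + background leak -
    NCX - PMCA) within ``tolerance`` of the gross influx."""
    df = result.final_cycle
    t = df["time_ms"].to_numpy()
    influx = -df["i_cal"].to_numpy() + result.params[K.P_CABLEAK]
    efflux = df["j_ncx"].to_numpy() + df["j_pmca"].to_numpy()
    gross_in = float(np.trapezoid(influx, t))
    gross_out = float(np.trapezoid(efflux, t))
    net = gross_in - gross_out
    if delta_total is None:
        delta_total = result.balance.get("delta_total_ca", np.nan) if result.balance else np.nan
    scale = max(abs(gross_in), abs(gross_out), 1e-12)
    residual = (delta_total - net) / scale if np.isfinite(delta_total) else np.nan
    return {
        "influx_integral": gross_in,
        "efflux_integral": gross_out,
        "net_sarcolemmal": net,
        "delta_total_ca": delta_total,
        "relative_residual": residual,
        "within_tolerance": bool(np.isfinite(residual) and abs(residual) <= tolerance),
    }


# ---------------------------------------------------------------------------
# reference Merson integrator (same coefficients as the kernel) for smooth
# test problems; used to verify integration order against matrix exponentials
# ---------------------------------------------------------------------------


def merson_step(f, y: np.ndarray, t: float, h: float) -> np.ndarray:
    k1 = f(t, y)
    k2 = f(t + h / 3, y + h / 3 * k1)
    k3 = f(t + h / 3, y + h / 6 * (k1 + k2))
    k4 = f(t + h / 2, y + h * (0.125 * k1 + 0.375 * k3))
    k5 = f(t + h, y + h * (0.5 * k1 - 1.5 * k3 + 2.0 * k4))
    return y + h / 6 * (k1 + 4 * k4 + k5)


def merson_integrate(f, y0: np.ndarray, t_span: tuple[float, float],
                     dt: float) -> np.ndarray:
    t, t_end = t_span
    y = np.array(y0, dtype=float)
    while t < t_end - 1e-12:
        h = min(dt, t_end - t)
        y = merson_step(f, y, t, h)
        t += h
    return y
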