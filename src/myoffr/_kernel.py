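"""Fixed-step integration kernel (numba).

One global step advances, in order:

1. the whole-cell trigger and release fluxes are evaluated from the current
   state and *frozen* for the step, so the dyadic grid and the compartment
   ODEs see bit-identical fluxes (exact Ca2+ bookkeeping);
2. the dyadic CaM chain is advanced by one backward-Euler step (its binding
   rates at cleft Ca2+ levels are far too stiff for an explicit scheme) and
   its net Ca2+ uptake is turned into a uniform grid sink;
3. the cleft grid takes the required number of explicit diffusion/buffering
   sub-steps (the count is set by the stability bound);
4. the remaining ODE state advances by one Merson 5-stage Runge-Kutta step
   (classic RK4 selectable).

Runge-Kutta steps preserve linear invariants, so every internal Ca2+ transfer
between compartments cancels exactly in the whole-cell balance; the only
sources/sinks are the sarcolemmal pathways, which is what the balance audit
checks.

The layout of the state vector, parameter vector and trace columns is defined
by the ``Y_*``, ``P_*`` and ``SIG_*`` constants; ``pack_params`` fills the
parameter vector from a validated configuration.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import neuro as _neuro
from . import dyad as _dyad
from .config import ModelConfig
from .dyad import grid_substep_adi

MS = 1.0e-3

# ---------------------------------------------------------------------------
# state vector layout
# ---------------------------------------------------------------------------
(Y_CAMYO, Y_NA, Y_CALSR, Y_CAJSR, Y_CSQ, Y_BUFM,
 Y_LCC0, Y_LCC1, Y_LCCO, Y_LCCIF, Y_LCCIS, Y_LCCR,
 Y_CDI,
 Y_RYRC, Y_RYRO, Y_RYRI, Y_RYRR,
 Y_WLUM,
 Y_DCA2, Y_DCA4, Y_DCAMB, Y_DKII, Y_DCAN,
 Y_MCA2, Y_MCA4, Y_MCAMB, Y_MKII, Y_MCAN,
 Y_PLBDP, Y_TNIP, Y_TROPH, Y_TROPL,
 Y_PERM, Y_XBPRE, Y_XBPOST) = range(35)
NY = 35

# ---------------------------------------------------------------------------
# parameter vector layout
# ---------------------------------------------------------------------------
_P_NAMES = [
    # dyad geometry / grid
    "NR", "NZ", "DR", "DZ", "DEFF", "GBKON", "GBKOFF", "GBTOT", "VFRAC",
    "K_LR", "K_RR", "K_RL", "K_SELF", "NSUB",
    # LCC
    "GCAL", "A01", "SA01", "B10", "SB10", "A12", "SA12", "B21", "SB21",
    "KOF", "KFO", "KFC", "KFS", "KSF", "KSR", "KRC", "VGATE", "SGATE",
    "CDIK", "CDIH", "CDITAU", "CDIFLOOR", "XIFORM", "XICOUP", "FICAL",
    # RyR
    "RPERM", "KOMAX", "KA", "RHILL", "KOC", "KOI", "KOILUM", "KIR",
    "KRCR", "KRCLUM", "EPSKII", "WGATE", "KRECCA", "KIIREF", "LUMTHR", "LUMA", "LUMB", "LUMM",
    # NCX / PMCA / Na
    "NCXV", "KMNA", "KMCA", "ETA", "KSAT", "NAO", "CAO",
    "PMCAV", "PMCAK", "PMCAH", "NAVP", "NAKM", "NAHILL", "NABG", "NAVOL", "CABLEAK",
    # SR
    "VLSR", "VJSR", "VMAXB", "APLB", "AKII", "VCAMPF", "EC50F", "EC50FK",
    "EC50B", "EC50BK", "SRHILL", "BACKR", "TAUTR", "CSQT", "CSQKON",
    "CSQKOFF", "K12PLB", "K21PLB", "FSERCA", "LEAKC",
    # signalling dyad
    "DCAMT", "DKONC", "DKOFFC", "DKONN", "DKOFFN", "DKONB", "DKOFFB",
    "DKIIT", "DKONKII", "DKOFFKII", "DCANT", "DKONCAN", "DKOFFCAN",
    "DW2", "DW4",
    # signalling myo
    "MCAMT", "MKONC", "MKOFFC", "MKONN", "MKOFFN", "MKONB", "MKOFFB",
    "MKIIT", "MKONKII", "MKOFFKII", "MCANT", "MKONCAN", "MKOFFCAN",
    "MW2", "MW4",
    # mechanics
    "KONT", "KOFFHT", "KOFFLT", "TROPHT", "TROPLT", "KONTI", "KOFFTI",
    "DPKA", "KNP", "KPN", "ETACOOP", "S50", "SIGCAP",
    "FAPP", "GAPP", "HF", "HB", "GXB", "WPRE", "FREF",
    # myoplasmic buffer / protocol
    "BMT", "BMKON", "BMKOFF", "VHOLD", "VSTEP",
]
for _i, _n in enumerate(_P_NAMES):
    globals()["P_" + _n] = _i
NP = len(_P_NAMES)

# ---------------------------------------------------------------------------
# trace column layout
# ---------------------------------------------------------------------------
SIG_NAMES = [
    "time_ms", "v", "ca_myo", "na_myo", "ca_lsr", "ca_jsr", "ca_dyad",
    "ca_ryr", "ca_lcc", "i_cal", "j_ryr", "j_serca", "j_ncx", "j_pmca",
    "j_rim", "j_leak", "po_lcc", "cdi", "po_ryr", "w_lum",
    "kii_dyad", "can_dyad", "kii_myo", "can_myo", "ca2_dyad", "ca4_dyad",
    "plb_dp", "tni_p", "trop_h", "trop_l", "perm", "xb_pre", "xb_post",
    "force", "sl",
]
for _i, _n in enumerate(SIG_NAMES):
    globals()["SIG_" + _n.upper()] = _i
NSIG = len(SIG_NAMES)

XI_REF = 550.0
RTF = 25.693
RYR_KII_REF = 60.0


def pack_params(cfg: ModelConfig, camp: float, n_sub: int) -> np.ndarray:
    """Flatten a validated configuration into the kernel parameter vector.

    All rates are converted to ms^-1; cAMP-derived factors and the derived
    rest-balance leaks are precomputed here (cAMP is constant within a run).
    """
    from .currents import (_ncx, _pmca, markov_steady_state, ryr_generator,
                           ghk_driving, lcc_generator, cdi_steady)
    from .mechanics import xb_rate_scaling
    from .signaling import cam_equilibrium, camkii_fixed_point, can_fixed_point

    P = np.zeros(NP)
    d, l, r, x, pm, na, s, m, e = (cfg.dyad, cfg.lcc, cfg.ryr, cfg.ncx,
                                   cfg.pmca, cfg.na, cfg.sr, cfg.mechanics,
                                   cfg.engine)
    kern = _dyad.source_kernel_coeffs(d)
    P[P_NR], P[P_NZ] = d.nr, d.nz
    P[P_DR], P[P_DZ] = d.dr_nm * 1e-3, d.dz_nm * 1e-3
    P[P_DEFF] = d.d_eff
    P[P_GBKON], P[P_GBKOFF], P[P_GBTOT] = d.buf_kon * MS, d.buf_koff * MS, d.buf_total
    P[P_VFRAC] = d.v_frac
    P[P_K_LR], P[P_K_RR] = kern["lcc_to_ryr"], kern["ryr_to_ryr"]
    P[P_K_RL], P[P_K_SELF] = kern["ryr_to_lcc"], kern["lcc_self"]
    P[P_NSUB] = n_sub

    P[P_GCAL] = l.g_cal
    P[P_A01], P[P_SA01], P[P_B10], P[P_SB10] = l.a01, l.sa01, l.b10, l.sb10
    P[P_A12], P[P_SA12], P[P_B21], P[P_SB21] = l.a12, l.sa12, l.b21, l.sb21
    P[P_KOF], P[P_KFO], P[P_KFC] = l.kof, l.kfo, l.kfc
    P[P_KFS], P[P_KSF] = l.kfs, l.ksf
    P[P_KSR], P[P_KRC] = l.ksr, l.krc
    P[P_VGATE], P[P_SGATE] = l.v_inact_gate, l.s_inact_gate
    P[P_CDIK], P[P_CDIH], P[P_CDITAU], P[P_CDIFLOOR] = (
        l.cdi_khalf, l.cdi_hill, l.cdi_tau_ms, l.cdi_floor)
    P[P_XIFORM] = 1.0 if l.xi_form == "new" else 0.0
    P[P_XICOUP] = l.xi_coupling
    P[P_FICAL] = _neuro.f_camp_ical(camp)

    P[P_RPERM] = r.perm
    P[P_KOMAX], P[P_KA], P[P_RHILL], P[P_KOC] = r.ko_max, r.ka_um, r.hill, r.koc
    P[P_KOI], P[P_KOILUM], P[P_KIR] = r.koi, r.koi_lum, r.kir
    P[P_KRCR], P[P_KRCLUM], P[P_EPSKII] = r.krc, r.krc_lum, r.eps_kii
    P[P_WGATE] = r.w_gate
    P[P_KRECCA] = r.krec_ca_um
    P[P_KIIREF] = RYR_KII_REF
    P[P_LUMTHR], P[P_LUMA], P[P_LUMB], P[P_LUMM] = (
        r.lum_thr, r.lum_alpha, r.lum_beta0, r.lum_m)

    P[P_NCXV], P[P_KMNA], P[P_KMCA] = x.vmax, x.km_na, x.km_ca
    P[P_ETA], P[P_KSAT], P[P_NAO], P[P_CAO] = x.eta, x.ksat, x.na_o, x.ca_o
    P[P_PMCAV], P[P_PMCAK], P[P_PMCAH] = pm.vmax, pm.k_half, pm.hill
    P[P_NAVP], P[P_NAKM], P[P_NAHILL] = na.v_pump, na.km_pump, na.hill_pump
    P[P_NAVOL] = na.vol_factor

    P[P_VLSR], P[P_VJSR] = s.v_lsr, s.v_jsr
    P[P_VMAXB], P[P_APLB], P[P_AKII] = s.vmax_base, s.alpha_plb, s.alpha_kii
    P[P_VCAMPF] = 1.0 + s.alpha_camp * (
        _neuro.f_camp_serca(camp) - _neuro.f_camp_serca(_neuro.CAMP_BASAL))
    P[P_EC50F], P[P_EC50FK] = s.ec50_f, s.ec50_f_kii
    P[P_EC50B], P[P_EC50BK] = s.ec50_b, s.ec50_b_kii
    P[P_SRHILL], P[P_BACKR], P[P_TAUTR] = s.hill, s.backrate, s.tau_tr_ms
    P[P_CSQT], P[P_CSQKON] = s.csq_total, s.csq_kon * MS
    P[P_CSQKOFF] = s.csq_kon * MS * s.csq_kd
    P[P_K12PLB], P[P_K21PLB] = s.k12_plb * MS, s.k21_plb * MS
    P[P_FSERCA] = _neuro.f_camp_serca(camp)

    sig = cfg.signaling
    for prefix, c in (("D", sig.dyad), ("M", sig.myo)):
        g = globals()
        P[g[f"P_{prefix}CAMT"]] = c.cam_total
        P[g[f"P_{prefix}KONC"]] = c.kon_c * MS
        P[g[f"P_{prefix}KOFFC"]] = c.koff_c * MS
        P[g[f"P_{prefix}KONN"]] = c.kon_n * MS
        P[g[f"P_{prefix}KOFFN"]] = c.koff_n * MS
        P[g[f"P_{prefix}KONB"]] = c.kon_buf * MS
        P[g[f"P_{prefix}KOFFB"]] = c.koff_buf * MS
        P[g[f"P_{prefix}KIIT"]] = c.camkii_total
        P[g[f"P_{prefix}KONKII"]] = c.kon_kii * MS
        P[g[f"P_{prefix}KOFFKII"]] = c.koff_kii * MS
        P[g[f"P_{prefix}CANT"]] = c.can_total
        P[g[f"P_{prefix}KONCAN"]] = c.kon_can * MS
        P[g[f"P_{prefix}KOFFCAN"]] = c.koff_can * MS
        P[g[f"P_{prefix}W2"]] = c.w_ca2
        P[g[f"P_{prefix}W4"]] = c.w_ca4

    P[P_KONT], P[P_KOFFHT], P[P_KOFFLT] = (
        m.kon_t * MS, m.koff_ht * MS, m.koff_lt * MS)
    P[P_TROPHT], P[P_TROPLT] = m.trop_h_total, m.trop_l_total
    P[P_KONTI], P[P_KOFFTI] = m.kon_ti * MS, m.koff_ti * MS
    P[P_DPKA] = _neuro.delta_pka(camp)
    P[P_KNP], P[P_KPN] = m.k_np * MS, m.k_pn * MS
    P[P_ETACOOP], P[P_S50], P[P_SIGCAP] = m.coop_eta, m.s50, m.sigma_cap
    scaled = xb_rate_scaling(camp, m.temperature_c, m)
    P[P_FAPP], P[P_GAPP], P[P_HF] = scaled["fapp"] * MS, scaled["gapp"] * MS, scaled["hf"] * MS
    P[P_HB], P[P_GXB] = scaled["hb"] * MS, scaled["gxb"] * MS
    P[P_WPRE], P[P_FREF] = m.w_pre, m.force_ref

    P[P_BMT], P[P_BMKON], P[P_BMKOFF] = (
        e.buf_myo_total, e.buf_myo_kon * MS, e.buf_myo_koff * MS)
    P[P_VHOLD], P[P_VSTEP] = cfg.protocol.v_hold, cfg.protocol.v_step

    # ---- derived rest-balance leaks (quiescent cell is flux-balanced) -----
    ca0, sr0, na0 = e.ca_rest, e.ca_sr_rest, na.na_rest
    j_ncx0 = _ncx(cfg.protocol.v_hold, na0, ca0, x.na_o, x.ca_o,
                  x.vmax, x.km_na, x.km_ca, x.eta, x.ksat)
    j_pmca0 = _pmca(ca0, pm.vmax, pm.k_half, pm.hill)
    # resting trigger leak through the small open L-type occupancy at hold
    eq_d = cam_equilibrium(sig.dyad, ca0)
    kii_d0 = camkii_fixed_point(sig.dyad, eq_d["ca4cam"])
    can_d0 = can_fixed_point(sig.dyad, eq_d["ca2cam"], eq_d["ca4cam"])
    Gl = lcc_generator(cfg.protocol.v_hold, kii_d0, can_d0, l)
    o_rest = markov_steady_state(Gl)[2]
    j_cal0 = (l.g_cal * o_rest * cdi_steady(ca0, l)
              * _neuro.f_camp_ical(camp) * ghk_driving(cfg.protocol.v_hold, ca0, x.ca_o))
    if j_cal0 < 0.0:
        j_cal0 = 0.0
    P[P_CABLEAK] = j_ncx0 + j_pmca0 - j_cal0
    pump0 = na.v_pump * na0 ** na.hill_pump / (na0 ** na.hill_pump + na.km_pump ** na.hill_pump)
    P[P_NABG] = pump0 - 3.0e-3 * j_ncx0
    # SERCA at rest vs SR leak + resting RyR flux
    plb0 = s.k12_plb / (s.k12_plb + s.k21_plb * (1.0 + _neuro.f_camp_serca(camp) ** 2))
    vmax0 = s.vmax_base * (1.0 + s.alpha_plb * (1.0 - plb0))
    fwd = (ca0 / s.ec50_f) ** s.hill
    bwd = (sr0 / s.ec50_b) ** s.hill
    j_serca0 = vmax0 * (fwd - s.backrate * bwd) / (1.0 + fwd + bwd)
    G0 = ryr_generator(ca0, RYR_KII_REF, 0.0, r, RYR_KII_REF)
    po0 = markov_steady_state(G0)[1]
    j_ryr0 = r.perm * po0 * (sr0 - ca0)
    leak = (j_serca0 - j_ryr0) / max(sr0 - ca0, 1.0)
    P[P_LEAKC] = max(leak, 0.0)
    return P


# ---------------------------------------------------------------------------
# jitted pieces
# ---------------------------------------------------------------------------


@njit(cache=True)
def _xi(kii, can, form):
    if form > 0.5:
        p = kii ** 3.22
        den = 3.135e6 - 0.755 * p
        if den < 1.0e3:
            den = 1.0e3
        return 550.0 + kii * (1.348 + p / den) + can
    return 550.0 + 6.0 * kii + can


@njit(cache=True)
def _ghk(v, ca_i, ca_o):
    u = 2.0 * v / RTF
    if abs(u) < 1.0e-6:
        return ca_o - ca_i
    e = np.exp(u)
    return -u * (ca_i * e - ca_o) / (e - 1.0)


@njit(cache=True)
def _fluxes(y, v, gca00, gca0n, P):
    """Whole-cell trigger influx (>=0) and RyR release flux at the current
    state (uM/ms, myoplasmic volume units)."""
    xi = _xi(y[Y_DKII], y[Y_DCAN], P[P_XIFORM])
    drive = _ghk(v, gca00, P[P_CAO])
    j_cal = P[P_GCAL] * y[Y_LCCO] * y[Y_CDI] * P[P_FICAL] * drive
    if j_cal < 0.0:
        j_cal = 0.0
    j_ryr = P[P_RPERM] * y[Y_RYRO] * (y[Y_CAJSR] - gca0n)
    return j_cal, j_ryr, xi


@njit(cache=True)
def _ode_rhs(y, dy, v, gca00, gca0n, gmean, j_cal, j_ryr, j_rim, P):
    for k in range(NY):
        dy[k] = 0.0

    # local channel-mouth concentrations (frozen fluxes)
    j_rel_pos = j_ryr if j_ryr > 0.0 else 0.0
    ca_ryr = gca0n + P[P_K_LR] * j_cal + P[P_K_RR] * j_rel_pos
    ca_lcc = gca00 + P[P_K_SELF] * j_cal + P[P_K_RL] * j_rel_pos

    # ---- LCC 6-state -----------------------------------------------------
    ratio = 1.0 + P[P_XICOUP] * (_xi(y[Y_DKII], y[Y_DCAN], P[P_XIFORM]) / XI_REF - 1.0)
    rec = 1.0 / (1.0 + np.exp((v - P[P_VGATE]) / P[P_SGATE]))
    a01 = P[P_A01] * np.exp(v / P[P_SA01]) * ratio
    b10 = P[P_B10] * np.exp(-v / P[P_SB10])
    a12 = P[P_A12] * np.exp(v / P[P_SA12]) * ratio
    b21 = P[P_B21] * np.exp(-v / P[P_SB21])
    kof = P[P_KOF] / ratio
    kfc = P[P_KFC] * rec
    ksf = P[P_KSF] * rec
    krc = P[P_KRC] * rec
    c0, c1, o = y[Y_LCC0], y[Y_LCC1], y[Y_LCCO]
    fi, si, rr = y[Y_LCCIF], y[Y_LCCIS], y[Y_LCCR]
    f01 = a01 * c0 - b10 * c1
    f12 = a12 * c1 - b21 * o
    f_of = kof * o - P[P_KFO] * fi
    f_fc = kfc * fi
    f_fs = P[P_KFS] * fi - ksf * si
    f_sr = P[P_KSR] * si
    f_rc = krc * rr
    dy[Y_LCC0] = -f01 + f_rc
    dy[Y_LCC1] = f01 - f12 + f_fc
    dy[Y_LCCO] = f12 - f_of
    dy[Y_LCCIF] = f_of - f_fc - f_fs
    dy[Y_LCCIS] = f_fs - f_sr
    dy[Y_LCCR] = f_sr - f_rc

    # CDI gate
    xcdi = (ca_lcc / P[P_CDIK]) ** P[P_CDIH]
    cdi_inf = P[P_CDIFLOOR] + (1.0 - P[P_CDIFLOOR]) / (1.0 + xcdi)
    dy[Y_CDI] = (cdi_inf - y[Y_CDI]) / P[P_CDITAU]

    # ---- RyR 4-state -----------------------------------------------------
    kii_scale = 1.0 + P[P_EPSKII] * (y[Y_DKII] - P[P_KIIREF]) / P[P_KIIREF]
    if kii_scale < 0.0:
        kii_scale = 0.0
    w = y[Y_WLUM]
    xr = (ca_ryr / P[P_KA]) ** P[P_RHILL]
    gate = 1.0 / (1.0 + (w / P[P_WGATE]) ** 8)
    r_co = P[P_KOMAX] * xr / (1.0 + xr) * kii_scale * gate
    r_oi = P[P_KOI] * (1.0 + P[P_KOILUM] * w)
    r_rc = P[P_KRCR] * (1.0 - P[P_KRCLUM] * w) ** 6 \
        / (1.0 + (ca_ryr / P[P_KRECCA]) ** 4)
    rc_, ro_, ri_, rf_ = y[Y_RYRC], y[Y_RYRO], y[Y_RYRI], y[Y_RYRR]
    g_co = r_co * rc_ - P[P_KOC] * ro_
    g_oi = r_oi * ro_
    g_ir = P[P_KIR] * ri_
    g_rc = r_rc * rf_
    dy[Y_RYRC] = -g_co + g_rc
    dy[Y_RYRO] = g_co - g_oi
    dy[Y_RYRI] = g_oi - g_ir
    dy[Y_RYRR] = g_ir - g_rc

    # luminal sensor
    depl = (P[P_LUMTHR] - y[Y_CAJSR]) / P[P_LUMTHR]
    if depl < 0.0:
        depl = 0.0
    refill = (y[Y_CAJSR] / P[P_LUMTHR]) ** P[P_LUMM]
    if refill > 1.0:
        refill = 1.0
    dy[Y_WLUM] = P[P_LUMA] * depl * (1.0 - w) - P[P_LUMB] * refill * w

    # ---- signalling: dyadic CaMKII/CaN (CaM species frozen, split step) ---
    dy[Y_DKII] = P[P_DKONKII] * y[Y_DCA4] * (P[P_DKIIT] - y[Y_DKII]) \
        - P[P_DKOFFKII] * y[Y_DKII]
    drive_d = P[P_DW2] * y[Y_DCA2] + P[P_DW4] * y[Y_DCA4]
    dy[Y_DCAN] = P[P_DKONCAN] * drive_d * (P[P_DCANT] - y[Y_DCAN]) \
        - P[P_DKOFFCAN] * y[Y_DCAN]

    # ---- signalling: myoplasmic pool --------------------------------------
    ca = y[Y_CAMYO]
    q = ca * ca
    apo_m = 1.0 - y[Y_MCA2] - y[Y_MCA4] - y[Y_MCAMB]
    jc = P[P_MKONC] * q * apo_m - P[P_MKOFFC] * y[Y_MCA2]
    jn = P[P_MKONN] * q * y[Y_MCA2] - P[P_MKOFFN] * y[Y_MCA4]
    jb = P[P_MKONB] * apo_m - P[P_MKOFFB] * y[Y_MCAMB]
    dy[Y_MCA2] = jc - jn
    dy[Y_MCA4] = jn
    dy[Y_MCAMB] = jb
    dy[Y_MKII] = P[P_MKONKII] * y[Y_MCA4] * (P[P_MKIIT] - y[Y_MKII]) \
        - P[P_MKOFFKII] * y[Y_MKII]
    drive_m = P[P_MW2] * y[Y_MCA2] + P[P_MW4] * y[Y_MCA4]
    dy[Y_MCAN] = P[P_MKONCAN] * drive_m * (P[P_MCANT] - y[Y_MCAN]) \
        - P[P_MKOFFCAN] * y[Y_MCAN]
    j_cam_myo = P[P_MCAMT] * (2.0 * jc + 4.0 * jn)  # Ca into myoplasmic CaM

    # ---- SR: PLB, SERCA, transfer, leak, CSQ ------------------------------
    kii_m = y[Y_MKII] * 1.0e5
    can_m = y[Y_MCAN] * 1.0e-4
    plb_dp = y[Y_PLBDP]
    dy[Y_PLBDP] = P[P_K12PLB] * (1.0 + can_m * can_m) * (1.0 - plb_dp) \
        - P[P_K21PLB] * (1.0 + kii_m * kii_m + P[P_FSERCA] * P[P_FSERCA]) * plb_dp

    sat = kii_m / (1.0 + kii_m)
    ec50f = P[P_EC50F] * (1.0 - P[P_EC50FK] * sat)
    ec50b = P[P_EC50B] * (1.0 + P[P_EC50BK] * sat)
    vmax = P[P_VMAXB] * (1.0 + P[P_APLB] * (1.0 - plb_dp)) * (1.0 + P[P_AKII] * kii_m) \
        * P[P_VCAMPF]
    fwd = (ca / ec50f) ** P[P_SRHILL]
    bwd = (y[Y_CALSR] / ec50b) ** P[P_SRHILL]
    j_serca = vmax * (fwd - P[P_BACKR] * bwd) / (1.0 + fwd + bwd)
    j_tr = P[P_VJSR] * (y[Y_CALSR] - y[Y_CAJSR]) / P[P_TAUTR]
    j_leak = P[P_LEAKC] * (y[Y_CALSR] - ca)
    csq_react = P[P_CSQKON] * y[Y_CAJSR] * (P[P_CSQT] - y[Y_CSQ]) \
        - P[P_CSQKOFF] * y[Y_CSQ]
    dy[Y_CALSR] = (j_serca - j_leak - j_tr) / P[P_VLSR]
    dy[Y_CAJSR] = (j_tr - j_ryr) / P[P_VJSR] - csq_react
    dy[Y_CSQ] = csq_react

    # ---- sarcolemmal extrusion and Na balance -----------------------------
    na = y[Y_NA]
    vfrt = v / RTF
    ef = np.exp(P[P_ETA] * vfrt)
    er = np.exp((P[P_ETA] - 1.0) * vfrt)
    j_ncx = P[P_NCXV] * (er * P[P_NAO] ** 3 * ca - ef * na ** 3 * P[P_CAO]) / (
        (P[P_KMNA] ** 3 + P[P_NAO] ** 3) * (P[P_KMCA] + P[P_CAO]) * (1.0 + P[P_KSAT] * er))
    xp = (ca / P[P_PMCAK]) ** P[P_PMCAH]
    j_pmca = P[P_PMCAV] * xp / (1.0 + xp)
    nah = na ** P[P_NAHILL]
    j_napump = P[P_NAVP] * nah / (nah + P[P_NAKM] ** P[P_NAHILL])
    dy[Y_NA] = P[P_NAVOL] * (3.0e-3 * j_ncx - j_napump + P[P_NABG])

    # ---- myoplasmic buffers and troponin ----------------------------------
    react_b = P[P_BMKON] * ca * (P[P_BMT] - y[Y_BUFM]) - P[P_BMKOFF] * y[Y_BUFM]
    dy[Y_BUFM] = react_b
    tni_u = 1.0 - y[Y_TNIP]
    on = P[P_KONT] * tni_u * ca
    dth = on * (1.0 - y[Y_TROPH]) - P[P_KOFFHT] * y[Y_TROPH]
    dtl = on * (1.0 - y[Y_TROPL]) - P[P_KOFFLT] * y[Y_TROPL]
    dy[Y_TROPH] = dth
    dy[Y_TROPL] = dtl
    dy[Y_TNIP] = P[P_KONTI] * P[P_DPKA] * tni_u - P[P_KOFFTI] * y[Y_TNIP]

    # ---- crossbridges ------------------------------------------------------
    sig = (y[Y_TROPL] / P[P_S50]) ** P[P_ETACOOP]
    if sig > P[P_SIGCAP]:
        sig = P[P_SIGCAP]
    unbound = y[Y_PERM] - y[Y_XBPRE] - y[Y_XBPOST]
    if unbound < 0.0:
        unbound = 0.0
    dy[Y_PERM] = P[P_KNP] * sig * (1.0 - y[Y_PERM]) - P[P_KPN] * unbound
    dy[Y_XBPRE] = P[P_FAPP] * unbound - (P[P_GAPP] + P[P_HF]) * y[Y_XBPRE] \
        + P[P_HB] * y[Y_XBPOST]
    dy[Y_XBPOST] = P[P_HF] * y[Y_XBPRE] - (P[P_HB] + P[P_GXB]) * y[Y_XBPOST]

    # ---- myoplasmic Ca ----------------------------------------------------
    dy[Y_CAMYO] = j_rim + j_leak + P[P_CABLEAK] - j_serca - j_ncx - j_pmca \
        - react_b - P[P_TROPHT] * dth - P[P_TROPLT] * dtl - j_cam_myo


@njit(cache=True)
def _dyad_cam_be(y, gmean, dt, max_uptake, P):
    """Backward-Euler step of the dyadic CaM chain at the current mean cleft
    Ca2+.  Returns the Ca2+ mass (uM, dyad volume units) newly bound to CaM;
    net uptake is limited to ``max_uptake`` (availability guard)."""
    q = gmean * gmean
    konc, koffc = P[P_DKONC] * q, P[P_DKOFFC]
    konn, koffn = P[P_DKONN] * q, P[P_DKOFFN]
    konb, koffb = P[P_DKONB], P[P_DKOFFB]
    ca2, ca4, camb = y[Y_DCA2], y[Y_DCA4], y[Y_DCAMB]
    # linear system x' = A x + b with x = (ca2, ca4, camb)
    a11 = -(konc + koffc + konn)
    a12 = -konc + koffn
    a13 = -konc
    a21, a22 = konn, -koffn
    a31 = -konb
    a32 = -konb
    a33 = -(konb + koffb)
    b1, b3 = konc, konb
    # (I - dt A) x_new = x + dt b
    m11, m12, m13 = 1.0 - dt * a11, -dt * a12, -dt * a13
    m21, m22, m23 = -dt * a21, 1.0 - dt * a22, 0.0
    m31, m32, m33 = -dt * a31, -dt * a32, 1.0 - dt * a33
    r1, r2, r3 = ca2 + dt * b1, ca4, camb + dt * b3
    det = (m11 * (m22 * m33 - m23 * m32) - m12 * (m21 * m33 - m23 * m31)
           + m13 * (m21 * m32 - m22 * m31))
    n_ca2 = (r1 * (m22 * m33 - m23 * m32) - m12 * (r2 * m33 - m23 * r3)
             + m13 * (r2 * m32 - m22 * r3)) / det
    n_ca4 = (m11 * (r2 * m33 - m23 * r3) - r1 * (m21 * m33 - m23 * m31)
             + m13 * (m21 * r3 - r2 * m31)) / det
    n_camb = (m11 * (m22 * r3 - r2 * m32) - m12 * (m21 * r3 - r2 * m31)
              + r1 * (m21 * m32 - m22 * m31)) / det
    # bound Ca = 2*ca2 + 4*ca4 (per unit CaM fraction, times total CaM)
    dbound = P[P_DCAMT] * (2.0 * (n_ca2 - ca2) + 4.0 * (n_ca4 - ca4))
    scale = 1.0
    if dbound > max_uptake:
        scale = max_uptake / dbound
        dbound = max_uptake
    y[Y_DCA2] = ca2 + scale * (n_ca2 - ca2)
    y[Y_DCA4] = ca4 + scale * (n_ca4 - ca4)
    y[Y_DCAMB] = camb + scale * (n_camb - camb)
    return dbound


@njit(cache=True)
def run_cycle(y, gca, gbuf, P, w_r, period_ms, pulse_ms, dt, out_stride, scheme,
              trace, t0):
    """Advance one pacing cycle in place; fill `trace` every `out_stride`
    steps.  Returns the number of samples written."""
    n_steps = int(np.rint(period_ms / dt))
    nr = int(P[P_NR])
    nz = int(P[P_NZ])
    n_sub = int(P[P_NSUB])
    dt_sub = dt / n_sub
    src = np.zeros((nr, nz))
    cl = np.zeros(nz)
    cd = np.zeros(nz)
    cu = np.zeros(nz)
    rhs = np.zeros(nz)
    dy = np.zeros(NY)
    k1 = np.zeros(NY)
    k2 = np.zeros(NY)
    k3 = np.zeros(NY)
    k4 = np.zeros(NY)
    k5 = np.zeros(NY)
    yt = np.zeros(NY)
    n_out = 0
    j_rim_prev = 0.0
    for step in range(n_steps):
        t_in = step * dt
        v = P[P_VSTEP] if t_in < pulse_ms else P[P_VHOLD]
        gca00 = gca[0, 0]
        gca0n = gca[0, nz - 1]
        # mean free cleft Ca
        gmean = 0.0
        for i in range(nr):
            acc = 0.0
            for j in range(nz):
                acc += gca[i, j]
            gmean += w_r[i] * acc / nz
        # frozen whole-cell fluxes for this step
        j_cal, j_ryr, _ = _fluxes(y, v, gca00, gca0n, P)

        # -- output sample (state before the step) --------------------------
        if step % out_stride == 0:
            _sample(trace, n_out, t0 + t_in, v, y, gmean, gca00, gca0n,
                    j_cal, j_ryr, j_rim_prev, P)
            n_out += 1

        # -- grid sub-steps with co-evolving dyadic CaM uptake ---------------
        # channel clusters span the cleft faces: trigger influx enters
        # uniformly over the sarcolemmal face, release over the jSR face
        # (sub-grid localisation is carried by the point-source kernel)
        rho_cal = j_cal * nz / P[P_VFRAC]
        rho_ryr = j_ryr * nz / P[P_VFRAC]
        for i in range(nr):
            src[i, 0] = rho_cal
            src[i, nz - 1] = rho_ryr
        rim_acc = 0.0
        for _ in range(n_sub):
            gm_sub = 0.0
            for i in range(nr):
                acc = 0.0
                for j in range(nz):
                    acc += gca[i, j]
                gm_sub += w_r[i] * acc / nz
            dbound = _dyad_cam_be(y, gm_sub, dt_sub, 0.5 * gm_sub, P)
            sink_rel = dbound / (gm_sub * dt_sub) if gm_sub > 1e-12 else 0.0
            rim_acc += grid_substep_adi(
                gca, gbuf, dt_sub, P[P_DR], P[P_DZ], P[P_DEFF],
                P[P_GBKON], P[P_GBKOFF], P[P_GBTOT],
                1, y[Y_CAMYO], src, sink_rel, cl, cd, cu, rhs)
        j_rim = -P[P_VFRAC] * rim_acc / n_sub  # uM/ms into the myoplasm
        j_rim_prev = j_rim

        # -- ODE step --------------------------------------------------------
        if scheme == 0:  # Merson 5-stage
            _ode_rhs(y, k1, v, gca00, gca0n, gmean, j_cal, j_ryr, j_rim, P)
            for k in range(NY):
                yt[k] = y[k] + dt / 3.0 * k1[k]
            _ode_rhs(yt, k2, v, gca00, gca0n, gmean, j_cal, j_ryr, j_rim, P)
            for k in range(NY):
                yt[k] = y[k] + dt / 6.0 * (k1[k] + k2[k])
            _ode_rhs(yt, k3, v, gca00, gca0n, gmean, j_cal, j_ryr, j_rim, P)
            for k in range(NY):
                yt[k] = y[k] + dt * (0.125 * k1[k] + 0.375 * k3[k])
            _ode_rhs(yt, k4, v, gca00, gca0n, gmean, j_cal, j_ryr, j_rim, P)
            for k in range(NY):
                yt[k] = y[k] + dt * (0.5 * k1[k] - 1.5 * k3[k] + 2.0 * k4[k])
            _ode_rhs(yt, k5, v, gca00, gca0n, gmean, j_cal, j_ryr, j_rim, P)
            for k in range(NY):
                y[k] += dt / 6.0 * (k1[k] + 4.0 * k4[k] + k5[k])
        else:  # classic RK4
            _ode_rhs(y, k1, v, gca00, gca0n, gmean, j_cal, j_ryr, j_rim, P)
            for k in range(NY):
                yt[k] = y[k] + 0.5 * dt * k1[k]
            _ode_rhs(yt, k2, v, gca00, gca0n, gmean, j_cal, j_ryr, j_rim, P)
            for k in range(NY):
                yt[k] = y[k] + 0.5 * dt * k2[k]
            _ode_rhs(yt, k3, v, gca00, gca0n, gmean, j_cal, j_ryr, j_rim, P)
            for k in range(NY):
                yt[k] = y[k] + dt * k3[k]
            _ode_rhs(yt, k4, v, gca00, gca0n, gmean, j_cal, j_ryr, j_rim, P)
            for k in range(NY):
                y[k] += dt / 6.0 * (k1[k] + 2.0 * k2[k] + 2.0 * k3[k] + k4[k])

        # guards
        for k in range(NY):
            if not np.isfinite(y[k]):
                return -(k + 1)  # diagnostic: offending slice
        if y[Y_CAMYO] < 0.0:
            return -(Y_CAMYO + 1)
    return n_out


@njit(cache=True)
def _sample(trace, n, t, v, y, gmean, gca00, gca0n, j_cal, j_ryr, j_rim, P):
    ca = y[Y_CAMYO]
    kii_m = y[Y_MKII] * 1.0e5
    plb_dp = y[Y_PLBDP]
    sat = kii_m / (1.0 + kii_m)
    ec50f = P[P_EC50F] * (1.0 - P[P_EC50FK] * sat)
    ec50b = P[P_EC50B] * (1.0 + P[P_EC50BK] * sat)
    vmax = P[P_VMAXB] * (1.0 + P[P_APLB] * (1.0 - plb_dp)) * (1.0 + P[P_AKII] * kii_m) \
        * P[P_VCAMPF]
    fwd = (ca / ec50f) ** P[P_SRHILL]
    bwd = (y[Y_CALSR] / ec50b) ** P[P_SRHILL]
    j_serca = vmax * (fwd - P[P_BACKR] * bwd) / (1.0 + fwd + bwd)
    vfrt = v / RTF
    ef = np.exp(P[P_ETA] * vfrt)
    er = np.exp((P[P_ETA] - 1.0) * vfrt)
    na = y[Y_NA]
    j_ncx = P[P_NCXV] * (er * P[P_NAO] ** 3 * ca - ef * na ** 3 * P[P_CAO]) / (
        (P[P_KMNA] ** 3 + P[P_NAO] ** 3) * (P[P_KMCA] + P[P_CAO]) * (1.0 + P[P_KSAT] * er))
    xp = (ca / P[P_PMCAK]) ** P[P_PMCAH]
    j_pmca = P[P_PMCAV] * xp / (1.0 + xp)
    j_leak = P[P_LEAKC] * (y[Y_CALSR] - ca)
    j_rel_pos = j_ryr if j_ryr > 0.0 else 0.0
    force = (y[Y_XBPOST] + P[P_WPRE] * y[Y_XBPRE]) / P[P_FREF]

    trace[n, 0] = t
    trace[n, 1] = v
    trace[n, 2] = ca
    trace[n, 3] = na
    trace[n, 4] = y[Y_CALSR]
    trace[n, 5] = y[Y_CAJSR]
    trace[n, 6] = gmean
    trace[n, 7] = gca0n + P[P_K_LR] * j_cal + P[P_K_RR] * j_rel_pos
    trace[n, 8] = gca00 + P[P_K_SELF] * j_cal + P[P_K_RL] * j_rel_pos
    trace[n, 9] = -j_cal  # inward current negative by convention
    trace[n, 10] = j_ryr
    trace[n, 11] = j_serca
    trace[n, 12] = j_ncx
    trace[n, 13] = j_pmca
    trace[n, 14] = j_rim  # rim exchange of the preceding step
    trace[n, 15] = j_leak
    trace[n, 16] = y[Y_LCCO]
    trace[n, 17] = y[Y_CDI]
    trace[n, 18] = y[Y_RYRO]
    trace[n, 19] = y[Y_WLUM]
    trace[n, 20] = y[Y_DKII]
    trace[n, 21] = y[Y_DCAN]
    trace[n, 22] = y[Y_MKII]
    trace[n, 23] = y[Y_MCAN]
    trace[n, 24] = y[Y_DCA2]
    trace[n, 25] = y[Y_DCA4]
    trace[n, 26] = y[Y_PLBDP]
    trace[n, 27] = y[Y_TNIP]
    trace[n, 28] = y[Y_TROPH]
    trace[n, 29] = y[Y_TROPL]
    trace[n, 30] = y[Y_PERM]
    trace[n, 31] = y[Y_XBPRE]
    trace[n, 32] = y[Y_XBPOST]
    trace[n, 33] = force
    trace[n, 34] = 0.0  # sl filled by the engine (simple map of force)
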