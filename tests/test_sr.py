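"""SERCA/PLB regulation, LSR-jSR transfer and calsequestrin buffering."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from myoffr import sr


def test_plb_fixed_point_without_signalling(cfg):
    """CaN = CaMKII = 0 and cAMP = 0 (F = 0.0931):
    PLB_dp = 6800 / (6800 + 1000 (1 + 0.0931^2)) = 0.8708."""
    fp = sr.plb_fixed_point(0.0, 0.0, 0.0, cfg.sr)
    assert fp == pytest.approx(0.8708, abs=2e-4)


def test_plb_fixed_point_with_camkii_and_camp(cfg):
    """CaMKII x 1e5 = 1, cAMP = 24.58 (F = 0.10933):
    PLB_dp = 6800 / (6800 + 1000 (2 + 0.011953)) = 0.7717."""
    fp = sr.plb_fixed_point(0.0, 1.0e-5, 24.58, cfg.sr)
    assert fp == pytest.approx(0.7717, abs=2e-4)


def test_plb_integration_reaches_algebraic_fixed_point(cfg):
    can, kii, camp = 3.0e3, 1.2e-5, 4.67
    fp = sr.plb_fixed_point(can, kii, camp, cfg.sr)
    sol = solve_ivp(lambda _, y: [sr.plb_rhs(y[0], can, kii, camp, cfg.sr)],
                    (0, 50.0), [0.5], rtol=1e-12, atol=1e-14)
    assert sol.y[0, -1] == pytest.approx(fp, abs=1e-6)


def test_plb_p_complements_plb_dp(cfg):
    state = sr.SRState(ca_jsr=700.0, ca_lsr=800.0, csq_bound=7000.0, plb_dp=0.83)
    assert state.plb_p + state.plb_dp == 1.0


def test_plb_rhs_rejects_out_of_range(cfg):
    with pytest.raises(ValueError):
        sr.plb_rhs(1.2, 0.0, 0.0, 2.67, cfg.sr)


def test_serca_flux_zero_without_calcium(cfg):
    state = sr.SRState(ca_jsr=0.0, ca_lsr=0.0, csq_bound=0.0, plb_dp=0.85)
    assert sr.serca_flux(0.0, 0.0, state, 0.0, 2.67, cfg.sr) == 0.0


def test_serca_flux_increases_with_plb_phosphorylation(cfg):
    """Relief of PLB inhibition: flux strictly increasing in PLB_p over a
    grid of concentrations."""
    for ca, lsr in [(0.2, 500.0), (0.8, 800.0), (2.0, 1200.0)]:
        fluxes = []
        for plb_dp in (0.9, 0.6, 0.3):
            state = sr.SRState(ca_jsr=lsr, ca_lsr=lsr, csq_bound=0.0,
                               plb_dp=plb_dp)
            fluxes.append(sr.serca_flux(ca, lsr, state, 1.0e-5, 2.67, cfg.sr))
        assert fluxes[0] < fluxes[1] < fluxes[2]


def test_serca_ec50_monotone_in_camkii(cfg):
    f0, b0 = sr.serca_ec50(0.0, cfg.sr)
    f1, b1 = sr.serca_ec50(2.0e-5, cfg.sr)
    assert f1 < f0      # more Ca sensitivity of uptake
    assert b1 > b0      # less back-flow


def test_lsr_jsr_transfer(cfg):
    assert sr.lsr_jsr_transfer(700.0, 700.0, cfg.sr) == 0.0
    # step gradient equilibrates exponentially at the configured rate
    p = cfg.sr

    def rhs(_, y):
        j = sr.lsr_jsr_transfer(800.0, y[0], p)
        return [j / p.v_jsr]

    sol = solve_ivp(rhs, (0, p.tau_tr_ms), [300.0], rtol=1e-10, atol=1e-10)
    expected = 800.0 + (300.0 - 800.0) * np.exp(-1.0)
    assert sol.y[0, -1] == pytest.approx(expected, rel=1e-6)


def test_csq_equilibrium_matches_isotherm(cfg):
    p = cfg.sr
    ca = 650.0
    bound = sr.csq_equilibrium(ca, p)
    d_free, d_bound = sr.csq_buffering(ca, bound, p)
    assert d_free == pytest.approx(0.0, abs=1e-9)
    assert d_bound == pytest.approx(0.0, abs=1e-9)
    assert bound == pytest.approx(p.csq_total * ca / (ca + p.csq_kd))


def test_csq_rates_conserve_and_vanish_when_empty(cfg):
    d_free, d_bound = sr.csq_buffering(0.0, 0.0, cfg.sr)
    assert d_free == 0.0 and d_bound == 0.0
    d_free, d_bound = sr.csq_buffering(500.0, 4000.0, cfg.sr)
    assert d_free + d_bound == pytest.approx(0.0, abs=1e-15)


def test_csq_buffering_slows_free_jsr_depletion(cfg):
    """With calsequestrin present, a fixed release flux depletes free jSR Ca
    more slowly than in an unbuffered compartment."""
    p = cfg.sr
    j_rel = 2.0  # uM/ms, myoplasm-volume units

    def rhs(_, y, buffered):
        ca, bound = y
        d_free = -j_rel / p.v_jsr
        if buffered:
            r_free, r_bound = sr.csq_buffering(ca, bound, p)
            return [d_free + r_free, r_bound]
        return [d_free, 0.0]

    y0 = [800.0, sr.csq_equilibrium(800.0, p)]
    t_span = (0.0, 20.0)
    buf = solve_ivp(rhs, t_span, y0, args=(True,), rtol=1e-8)
    unbuf = solve_ivp(rhs, t_span, y0, args=(False,), rtol=1e-8)
    assert buf.y[0, -1] > unbuf.y[0, -1]
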