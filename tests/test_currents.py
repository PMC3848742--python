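"""Markov channel generators, CDI, NCX and PMCA."""

import numpy as np
import pytest
from scipy.linalg import expm

from myoffr import currents as cur


# ---------------------------------------------------------------------------
# facilitation term
# ---------------------------------------------------------------------------


def test_xi_reduces_to_550_without_signalling():
    assert cur.xi_modulation(0.0, 0.0, "new") == 550.0
    assert cur.xi_modulation(0.0, 0.0, "linear") == 550.0


def test_xi_increases_with_signalling_and_rejects_negative():
    assert cur.xi_modulation(60.0, 35.0) > 550.0
    assert cur.xi_modulation(90.0, 35.0) > cur.xi_modulation(60.0, 35.0)
    with pytest.raises(ValueError):
        cur.xi_modulation(-1.0, 0.0)


def test_xi_denominator_clamped_at_extreme_camkii():
    assert np.isfinite(cur.xi_modulation(200.0, 0.0))


# ---------------------------------------------------------------------------
# generator structure and the null-space steady-state oracle
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("v", [-40.0, 10.0, -10.0])
@pytest.mark.parametrize("kii,can", [(0.0, 0.0), (60.0, 34.0), (95.0, 39.0)])
def test_lcc_generator_structure_and_steady_state(cfg, v, kii, can):
    G = cur.lcc_generator(v, kii, can, cfg.lcc)
    assert np.allclose(G.sum(axis=0), 0.0, atol=1e-12)  # generator columns
    off = G - np.diag(np.diag(G))
    assert (off >= 0).all()
    # long propagation of the frozen generator reaches the null-space vector
    p0 = np.zeros(6)
    p0[0] = 1.0
    p_inf = expm(G * 1.0e6) @ p0
    assert np.allclose(p_inf, cur.markov_steady_state(G), atol=1e-6)


@pytest.mark.parametrize("ca,kii,w", [(0.15, 60.0, 0.0), (80.0, 60.0, 0.1),
                                      (300.0, 90.0, 0.5)])
def test_ryr_generator_structure_and_steady_state(cfg, ca, kii, w):
    G = cur.ryr_generator(ca, kii, w, cfg.ryr)
    assert np.allclose(G.sum(axis=0), 0.0, atol=1e-12)
    p0 = np.array([1.0, 0.0, 0.0, 0.0])
    p_inf = expm(G * 1.0e6) @ p0
    assert np.allclose(p_inf, cur.markov_steady_state(G), atol=1e-6)


def test_ryr_rest_open_probability_is_tiny(cfg):
    G = cur.ryr_generator(0.143, 60.0, 0.0, cfg.ryr)
    p = cur.markov_steady_state(G)
    assert p[cur.RYR_O] < 1e-3


def test_ryr_opening_rate_increases_with_trigger_ca_and_camkii(cfg):
    rates = [cur.ryr_generator(ca, 60.0, 0.0, cfg.ryr)[cur.RYR_O, cur.RYR_C]
             for ca in (5.0, 30.0, 120.0)]
    assert rates[0] < rates[1] < rates[2]
    lo = cur.ryr_generator(100.0, 60.0, 0.0, cfg.ryr)[cur.RYR_O, cur.RYR_C]
    hi = cur.ryr_generator(100.0, 90.0, 0.0, cfg.ryr)[cur.RYR_O, cur.RYR_C]
    assert hi > lo


# ---------------------------------------------------------------------------
# CDI gate
# ---------------------------------------------------------------------------


def test_cdi_relaxes_to_one_without_calcium(cfg):
    gate = 0.3
    for _ in range(100):
        gate = cur.cdi_update(gate, 0.0, 5.0, cfg.lcc)
    assert gate == pytest.approx(cur.cdi_steady(0.0, cfg.lcc), abs=1e-9)
    assert cur.cdi_steady(0.0, cfg.lcc) == pytest.approx(1.0)


def test_cdi_step_response_is_monoexponential(cfg):
    """After a Ca step the gate approaches its target with the configured
    time constant (closed-form exponential oracle)."""
    ca = 30.0
    inf = cur.cdi_steady(ca, cfg.lcc)
    tau = cfg.lcc.cdi_tau_ms
    gate0, t = 1.0, 12.0
    expected = inf + (gate0 - inf) * np.exp(-t / tau)
    stepped = gate0
    for _ in range(12):  # 12 x 1 ms steps
        stepped = cur.cdi_update(stepped, ca, 1.0, cfg.lcc)
    assert stepped == pytest.approx(expected, rel=1e-9)


def test_more_local_ca_means_more_inactivation(cfg):
    assert cur.cdi_steady(50.0, cfg.lcc) < cur.cdi_steady(5.0, cfg.lcc)


# ---------------------------------------------------------------------------
# currents
# ---------------------------------------------------------------------------


def test_ical_zero_when_closed(cfg):
    lcc = cur.LCCState(conductance=cfg.lcc.g_cal)
    assert cur.i_cal(10.0, lcc, 2.67, 0.1, 1800.0) == 0.0


def test_ical_camp_ratio_matches_factor_ratio(cfg):
    lcc = cur.LCCState(conductance=cfg.lcc.g_cal)
    lcc.occupancy[:] = 0.0
    lcc.occupancy[cur.LCC_O] = 1.0
    i_lo = cur.i_cal(10.0, lcc, 2.67, 0.1, 1800.0)
    i_hi = cur.i_cal(10.0, lcc, 24.58, 0.1, 1800.0)
    assert i_hi / i_lo == pytest.approx(1.0933 / 1.0032, abs=1e-4)
    assert i_lo < 0  # inward current negative by convention


def test_ryr_flux_trivial_cases(cfg):
    assert cur.ryr_flux(0.0, 800.0, 0.1, cfg.ryr) == 0.0
    assert cur.ryr_flux(0.5, 300.0, 300.0, cfg.ryr) == 0.0
    one = cur.ryr_flux(0.5, 500.0, 100.0, cfg.ryr)
    two = cur.ryr_flux(0.5, 900.0, 100.0, cfg.ryr)
    assert two == pytest.approx(2.0 * one)  # linear in the gradient


def test_luminal_sensor_directionality(cfg):
    p = cfg.ryr
    # fully replete SR: inhibition decays
    assert cur.luminal_sensor_rhs(0.5, 2.0 * p.lum_thr, p) < 0
    # depleted SR: inhibition builds
    assert cur.luminal_sensor_rhs(0.1, 0.3 * p.lum_thr, p) > 0


def test_luminal_sensor_step_rise_rate(cfg):
    p = cfg.ryr
    ca_jsr = 0.5 * p.lum_thr
    d = cur.luminal_sensor_rhs(0.0, ca_jsr, p)
    assert d == pytest.approx(p.lum_alpha * 0.5, rel=1e-12)


def test_ncx_zero_at_reversal_potential(cfg):
    na, ca = 10.0, 0.3
    p = cfg.ncx
    rtf = cur.RTF
    v_rev = 3 * rtf * np.log(p.na_o / na) - 2 * (rtf / 2) * np.log(p.ca_o / ca)
    assert cur.ncx_current(v_rev, na, ca, p) == pytest.approx(0.0, abs=1e-12)
    assert cur.ncx_current(v_rev - 10, na, ca, p) > 0   # extrusion below V_rev
    assert cur.ncx_current(v_rev + 10, na, ca, p) < 0


def test_ncx_extrusion_impeded_by_higher_na(cfg):
    base = cur.ncx_current(-40.0, 10.0, 1.0, cfg.ncx)
    high = cur.ncx_current(-40.0, 13.0, 1.0, cfg.ncx)
    assert base > 0 and high < base


def test_ncx_matches_independent_formula_evaluation(cfg):
    """Cross-check against a separately written closed-form evaluation."""
    p = cfg.ncx
    rtf = cur.RTF
    for v in (-60.0, -40.0, 0.0, 10.0):
        for na in (8.0, 12.0):
            for ca in (0.1, 0.5, 2.0):
                ef, er = np.exp(p.eta * v / rtf), np.exp((p.eta - 1) * v / rtf)
                num = er * p.na_o**3 * ca - ef * na**3 * p.ca_o
                den = ((p.km_na**3 + p.na_o**3) * (p.km_ca + p.ca_o)
                       * (1 + p.ksat * er))
                assert cur.ncx_current(v, na, ca, p) == pytest.approx(
                    p.vmax * num / den, rel=1e-12)


def test_pmca_trivial_and_half_saturation(cfg):
    p = cfg.pmca
    assert cur.pmca_current(0.0, p) == 0.0
    assert cur.pmca_current(p.k_half, p) == pytest.approx(0.5 * p.vmax)
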