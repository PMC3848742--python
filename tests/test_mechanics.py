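"""Myofilament regulatory binding, TnI phosphorylation and crossbridges."""

import numpy as np
import pytest

from myoffr import mechanics as mech


def test_troponin_fixed_points_at_one_micromolar(cfg):
    """At 1 uM Ca and unphosphorylated TnI the occupancies are
    22.22/(22.22+17.36) = 0.5614 (high) and 22.22/(22.22+173.61) = 0.1135."""
    h, l = mech.troponin_fixed_point(1.0, 1.0, cfg.mechanics)
    assert h == pytest.approx(0.5614, abs=2e-4)
    assert l == pytest.approx(0.1135, abs=2e-4)


def test_troponin_decays_without_calcium(cfg):
    dh, dl = mech.troponin_rhs(0.0, 0.4, 0.2, 1.0, cfg.mechanics)
    assert dh < 0 and dl < 0


def test_tni_scaling_halves_effective_on_rate(cfg):
    """Halving TnI_u halves the on-rate: the fixed point shifts right."""
    h_full, _ = mech.troponin_fixed_point(1.0, 1.0, cfg.mechanics)
    h_half, _ = mech.troponin_fixed_point(1.0, 0.5, cfg.mechanics)
    on = cfg.mechanics.kon_t * 0.5
    assert h_half == pytest.approx(on / (on + cfg.mechanics.koff_ht))
    assert h_half < h_full


def test_tni_fixed_point_at_half_saturating_pka(cfg):
    """delta_PKA = 0.15 gives TnI_p = 104.80/(104.80+80.0) = 0.5671."""
    fp = mech.tni_fixed_point(12.1, cfg.mechanics)  # camp=12.1 -> dPKA=0.15
    assert fp == pytest.approx(0.5671, abs=2e-4)


def test_tni_decays_without_camp(cfg):
    assert mech.tni_rhs(0.3, 0.0, cfg.mechanics) < 0
    assert mech.tni_rhs(0.0, 0.0, cfg.mechanics) == 0.0


def test_xb_rate_scaling_identity_and_q10(cfg):
    p = cfg.mechanics
    base = {"fapp": p.fapp, "gapp": p.gapp, "hf": p.hf, "hb": p.hb, "gxb": p.gxb}
    # F_cAMP,Force = 1 at camp = ln(1.4/0.873)/0.192 = 2.4577...
    camp_unity = np.log(1.4 / 0.873) / 0.192
    scaled = mech.xb_rate_scaling(camp_unity, p.t_ref_c, p)
    for k in ("fapp", "hf", "hb", "gxb"):
        assert scaled[k] == pytest.approx(base[k], rel=1e-10)
    warm = mech.xb_rate_scaling(camp_unity, p.t_ref_c + 10.0, p)
    for k in ("fapp", "hf", "hb", "gxb"):
        assert warm[k] == pytest.approx(base[k] * 2.25, rel=1e-10)
    assert warm["gapp"] == base["gapp"]  # gapp carries no Q10/cAMP scaling


def test_xb_rate_scaling_camp_factor(cfg):
    p = cfg.mechanics
    scaled = mech.xb_rate_scaling(24.58, p.t_ref_c, p)
    assert scaled["fapp"] / p.fapp == pytest.approx(1.8605, abs=2e-4)


def test_xb_rate_scaling_temperature_range(cfg):
    with pytest.raises(ValueError):
        mech.xb_rate_scaling(2.67, 50.0, cfg.mechanics)


def test_crossbridge_conservation_and_bounds(cfg):
    p = cfg.mechanics
    state = mech.MechState(ca_trop_l=0.2, perm=0.4, xb_pre=0.15, xb_post=0.2)
    scaled = mech.xb_rate_scaling(2.67, p.temperature_c, p)
    d = mech.crossbridge_rhs(state, scaled, p)
    # crossbridge states cannot exceed the permissive pool: at the boundary
    # the unbound pool is empty and attachment stops
    state2 = mech.MechState(ca_trop_l=0.2, perm=0.3, xb_pre=0.1, xb_post=0.2)
    d2 = mech.crossbridge_rhs(state2, scaled, p)
    assert d2["xb_pre"] <= 0 or state2.xb_pre + state2.xb_post < state2.perm
    assert set(d) == {"perm", "xb_pre", "xb_post"}


def test_crossbridge_rejects_inconsistent_state(cfg):
    bad = mech.MechState(perm=0.1, xb_pre=0.2, xb_post=0.1)
    with pytest.raises(ValueError):
        bad.validate()


def test_force_ca_curve_is_sigmoidal(cfg):
    """Steady-state force-Ca relation: monotone, sigmoidal with apparent
    Hill coefficient > 1."""
    ca = np.logspace(-1.5, 1.2, 120)
    f = mech.force_ca_curve(ca, camp=2.67, params=cfg.mechanics)
    assert np.all(np.diff(f) >= -1e-12)
    # apparent Hill coefficient from the 20-80% span
    fmax = f[-1]
    lo = ca[np.searchsorted(f, 0.2 * fmax)]
    hi = ca[np.searchsorted(f, 0.8 * fmax)]
    n_h = np.log(0.8 / 0.2 * (1 - 0.2) / (1 - 0.8)) / np.log(hi / lo)
    assert n_h > 1.0


def test_tni_phosphorylation_desensitises_without_raising_max(cfg):
    ca = np.logspace(-1.5, 1.5, 100)
    basal = mech.force_ca_curve(ca, camp=2.67, params=cfg.mechanics)
    stim = mech.force_ca_curve(ca, camp=24.58, params=cfg.mechanics)
    # rightward shift: mid-range force is lower per unit Ca once the
    # crossbridge-rate scaling is divided out (compare half-activation Ca)
    ca50_basal = ca[np.searchsorted(basal, 0.5 * basal[-1])]
    ca50_stim = ca[np.searchsorted(stim, 0.5 * stim[-1])]
    assert ca50_stim > ca50_basal


def test_force_and_sarcomere_outputs(cfg):
    p = cfg.mechanics
    state = mech.MechState(xb_pre=0.1, xb_post=0.3, perm=0.5)
    f = mech.force_of_state(state, p)
    assert f == pytest.approx((0.3 + p.w_pre * 0.1) / p.force_ref)
    assert mech.sarcomere_length(f, p) == pytest.approx(p.sl_rest - p.dsl_max * f)
    assert mech.sarcomere_length(0.0, p) == p.sl_rest
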