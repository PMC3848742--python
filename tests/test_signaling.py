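"""CaM cooperative binding, CaMKII and CaN activation kinetics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from myoffr.signaling import (
    Compartment, SignalingPool, active_levels, cam_equilibrium, cam_rhs,
    camkii_fixed_point, camkii_rhs, can_fixed_point, can_rhs,
)


def make_pool(cfg, comp="dyad", **state):
    params = getattr(cfg.signaling, "dyad" if comp == "dyad" else "myo")
    cid = Compartment.dyad if comp == "dyad" else Compartment.myoplasm
    return SignalingPool(compartment_id=cid, params=params, **state)


def test_no_ligand_no_bound_species_gives_zero_derivatives(cfg):
    pool = make_pool(cfg, cam_buffer_bound=0.0)
    pool.params = pool.params.model_copy(update={"kon_buf": 0.0})
    d = cam_rhs(pool, 0.0)
    assert all(abs(v) < 1e-15 for v in d.values())
    assert camkii_rhs(pool) == 0.0
    assert can_rhs(pool) == 0.0


def test_cam_rhs_conserves_total(cfg):
    pool = make_pool(cfg, ca2cam=0.2, ca4cam=0.1, cam_buffer_bound=0.3)
    d = cam_rhs(pool, 5.0)
    total = d["ca2cam"] + d["ca4cam"] + d["cam_buffer_bound"] + d["apo"]
    assert abs(total) < 1e-15


def test_negative_ca_rejected(cfg):
    with pytest.raises(ValueError):
        cam_rhs(make_pool(cfg), -0.1)


@pytest.mark.parametrize("comp, ca", [("dyad", 2.0), ("dyad", 50.0), ("myo", 0.5)])
def test_integrated_cam_equilibrium_matches_root_finding(cfg, comp, ca):
    """Integrating the ODEs to steady state reproduces the algebraic
    mass-action equilibrium of the two-step scheme."""
    pool = make_pool(cfg, comp)
    p = pool.params

    def rhs(_, y):
        pool.ca2cam, pool.ca4cam, pool.cam_buffer_bound = y
        d = cam_rhs(pool, ca)
        return [d["ca2cam"], d["ca4cam"], d["cam_buffer_bound"]]

    sol = solve_ivp(rhs, (0.0, 5.0e4), [0.0, 0.0, 0.0], method="LSODA",
                    rtol=1e-10, atol=1e-12)
    eq = cam_equilibrium(p, ca)
    assert sol.y[0, -1] == pytest.approx(eq["ca2cam"], abs=1e-6)
    assert sol.y[1, -1] == pytest.approx(eq["ca4cam"], abs=1e-6)
    assert sol.y[2, -1] == pytest.approx(eq["cam_buffer_bound"], abs=1e-6)


def test_dyadic_buffer_leaves_more_free_ca4cam(cfg):
    """The weaker dyadic CaM buffer yields more free Ca4CaM than the
    myoplasmic pool at identical local Ca (CaM enrichment in the cleft)."""
    ca = 10.0
    dy = cam_equilibrium(cfg.signaling.dyad, ca)
    my = cam_equilibrium(cfg.signaling.myo, ca)
    assert dy["ca4cam"] > my["ca4cam"]


def test_camkii_steady_state_matches_bisection_fixed_point(cfg):
    p = cfg.signaling.dyad
    ca4 = 0.4
    fp = camkii_fixed_point(p, ca4)
    pool = make_pool(cfg, ca4cam=ca4)

    def rhs(_, y):
        pool.camkii_active = y[0]
        return [camkii_rhs(pool)]

    sol = solve_ivp(rhs, (0.0, 5.0e4), [0.0], method="LSODA", rtol=1e-12,
                    atol=1e-12)
    assert sol.y[0, -1] == pytest.approx(fp, rel=1e-6)
    # fixed point is interior and respects conservation
    assert 0.0 < fp < p.camkii_total


def test_can_fixed_point_and_slow_dissociation(cfg):
    p = cfg.signaling.dyad
    assert p.koff_can < 1.0, "Ca4CaM-CaN dissociation must be slow (<< 1 s^-1)"
    fp = can_fixed_point(p, ca2=0.2, ca4=0.3)
    pool = make_pool(cfg, ca2cam=0.2, ca4cam=0.3, can_active=fp)
    assert can_rhs(pool) == pytest.approx(0.0, abs=1e-12)


def test_active_levels_constant_and_square_wave():
    t = np.linspace(0.0, 1000.0, 10001)
    assert active_levels(t, np.full_like(t, 3.3), 500.0) == pytest.approx(3.3)
    duty = (t % 500.0) < 125.0  # 25% duty square wave
    avg = active_levels(t, np.where(duty, 2.0, 0.0), 500.0)
    assert avg == pytest.approx(0.5, abs=2e-3)


def test_active_levels_requires_full_cycle():
    t = np.linspace(0.0, 100.0, 101)
    with pytest.raises(ValueError):
        active_levels(t, t, 500.0)
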