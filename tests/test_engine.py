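"""Protocol construction, integrator accuracy and whole-cell invariants."""

import numpy as np
import pytest
from scipy.linalg import expm

from myoffr import engine
from myoffr._kernel import NY, Y_CAMYO, Y_CAJSR, Y_NA


def test_protocol_periods(cfg):
    p = engine.build_protocol(5.0, cfg)
    assert p.period_ms == 200.0
    assert p.pulse_ms == 50.0
    assert p.v_hold == -40.0 and p.v_step == 10.0
    assert engine.build_protocol(0.5, cfg).period_ms == 2000.0


def test_protocol_rejects_pulse_longer_than_period(cfg):
    with pytest.raises(ValueError):
        engine.build_protocol(12.0, cfg, pulse_ms=100.0)
    with pytest.raises(ValueError):
        engine.build_protocol(0.1, cfg)


def test_merson_order_at_least_four():
    """On a smooth linear system the observed convergence order of the
    Merson scheme is >= 4 (matrix-exponential oracle)."""
    rng = np.random.default_rng(3)
    A = rng.normal(size=(5, 5))
    A -= 2.0 * np.eye(5)  # keep it stable
    y0 = rng.normal(size=5)
    exact = expm(A * 1.0) @ y0

    def err(dt):
        y = engine.merson_integrate(lambda t, y: A @ y, y0, (0.0, 1.0), dt)
        return np.linalg.norm(y - exact)

    e1, e2 = err(0.02), err(0.01)
    order = np.log2(e1 / e2)
    assert order >= 3.9


def test_single_merson_step_matches_exponential_to_fifth_order():
    A = np.array([[0.0, 1.0], [-4.0, -0.4]])
    y0 = np.array([1.0, 0.0])
    for h in (0.05, 0.025):
        y1 = engine.merson_step(lambda t, y: A @ y, y0, 0.0, h)
        exact = expm(A * h) @ y0
        assert np.linalg.norm(y1 - exact) < 5.0 * h**5


def test_resting_state_is_valid(cfg):
    y, gca, gbuf = engine.resting_state(cfg)
    assert y.shape == (NY,)
    assert np.all(np.isfinite(y))
    assert abs(y[6:12].sum() - 1.0) < 1e-9   # LCC simplex
    assert abs(y[13:17].sum() - 1.0) < 1e-9  # RyR simplex
    assert np.all(gca > 0) and np.all(gbuf >= 0)


@pytest.fixture(scope="module")
def short_run(cfg):
    proto = engine.build_protocol(8.0, cfg, n_cycles=3, convergence_tol=0.0)
    return engine.integrate(cfg, proto)


def test_run_is_deterministic(cfg, short_run):
    proto = engine.build_protocol(8.0, cfg, n_cycles=3, convergence_tol=0.0)
    again = engine.integrate(cfg, proto)
    assert np.array_equal(short_run.traces.to_numpy(), again.traces.to_numpy())
    assert np.array_equal(short_run.state[0], again.state[0])


def test_markov_simplexes_preserved_under_integration(short_run):
    y = short_run.state[0]
    assert abs(y[6:12].sum() - 1.0) < 1e-9
    assert abs(y[13:17].sum() - 1.0) < 1e-9
    assert y[6:12].min() >= -1e-12 and y[13:17].min() >= -1e-12


def test_traces_are_finite_and_labelled(short_run):
    df = short_run.traces
    assert {"time_ms", "ca_myo", "force", "i_cal", "sl"} <= set(df.columns)
    assert np.isfinite(df.to_numpy()).all()


def test_convergence_stop(cfg):
    proto = engine.build_protocol(8.0, cfg, n_cycles=40, convergence_tol=0.05)
    res = engine.integrate(cfg, proto)
    assert res.stop_reason in ("convergence", "n_cycles")
    if res.converged:
        pk = res.cycle_metrics["peak_ca"].to_numpy()
        assert abs(pk[-1] - pk[-2]) / pk[-2] < 0.05


def test_zero_tolerance_runs_all_cycles(cfg):
    proto = engine.build_protocol(8.0, cfg, n_cycles=4, convergence_tol=0.0)
    res = engine.integrate(cfg, proto)
    assert res.n_cycles_run == 4 and not res.converged


def test_rest_stability_drift(cfg):
    """Quiescent cell (holding potential only, no pulses): the state drifts
    by < 0.1% over 10 s of simulated time."""
    proto = engine.build_protocol(0.5, cfg, v_step=cfg.protocol.v_hold,
                                  n_cycles=5, convergence_tol=0.0)
    res = engine.integrate(cfg, proto)
    y0, _, _ = engine.resting_state(cfg)
    y1 = res.state[0]
    for idx, scale in ((Y_CAMYO, y0[Y_CAMYO]), (Y_CAJSR, y0[Y_CAJSR]),
                       (Y_NA, y0[Y_NA])):
        assert abs(y1[idx] - y0[idx]) / scale < 1e-3


def test_sealed_cell_conserves_total_calcium(cfg):
    """All sarcolemmal pathways off: total cell Ca2+ is constant to 1e-8
    relative over a paced run (internal fluxes cancel exactly)."""
    sealed = cfg.replace(
        lcc={"g_cal": 1e-12}, ncx={"vmax": 1e-12}, pmca={"vmax": 1e-12})
    proto = engine.build_protocol(4.0, sealed, n_cycles=4, convergence_tol=0.0)
    res = engine.integrate(sealed, proto)
    cm = res.cycle_metrics["total_ca_start"].to_numpy()
    assert abs(res.balance["total_run_delta"]) / cm[0] < 1e-8


def test_balance_audit_within_tolerance_on_steady_cycle(cfg):
    res = engine.run_to_steady_state(cfg, 4.0)
    assert abs(res.balance["relative_residual"]) <= 0.005


def test_self_convergence_in_dt(cfg):
    """Halving the global step changes the final-cycle peak Ca by well under
    the integration-accuracy budget."""
    proto = engine.build_protocol(8.0, cfg, n_cycles=3, convergence_tol=0.0)
    coarse = engine.integrate(cfg, proto)
    fine_cfg = cfg.replace(engine={"dt_us": cfg.engine.dt_us / 2})
    fine = engine.integrate(fine_cfg, proto)
    pk_c = coarse.cycle_metrics["peak_ca"].iloc[-1]
    pk_f = fine.cycle_metrics["peak_ca"].iloc[-1]
    assert abs(pk_c - pk_f) / pk_f < 0.005


def test_numerical_failure_is_diagnosed(cfg):
    # a pathologically stiff gating rate overwhelms the fixed-step scheme;
    # the engine aborts with a diagnostic naming the offending state slice
    bad = cfg.replace(ryr={"koi": 1.0e7}, engine={"dt_us": 50.0})
    proto = engine.build_protocol(8.0, bad, n_cycles=2, convergence_tol=0.0)
    with pytest.raises(engine.NumericalError, match="slice"):
        engine.integrate(bad, proto)
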