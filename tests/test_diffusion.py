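"""Tracer diffusion: walker simulation, D estimation, mean-field closure."""

import math

import numpy as np
import pandas as pd
import pytest

import mitonet as mn
from mitonet.diffusion import (
    WalkerConfig,
    MSDCurve,
    estimate_D,
    simulate_walkers,
    ema_diffusion,
    diffusion_surface,
    kiss_and_run_range,
)

from oracles import exact_effective_diffusion


def _sim_D(p, tau, n_walkers=2000, t_max=300.0, seed=0, L=64):
    lat = mn.make_lattice(L, 2, p=p, tau=tau, boundary="periodic", seed=seed)
    cfg = WalkerConfig(n_walkers=n_walkers, t_max=t_max, seed=seed)
    return estimate_D(simulate_walkers(lat, cfg)).D_app


def test_free_lattice_diffusion():
    """All bonds on: the blind ant is a free walk with D = lambda/(2d)."""
    assert _sim_D(1.0, math.inf) == pytest.approx(0.25, rel=0.05)


def test_no_bonds_no_motion():
    lat = mn.make_lattice(16, 2, p=0.0, seed=1, boundary="periodic")
    cfg = WalkerConfig(n_walkers=50, t_max=50.0, seed=2)
    curve = simulate_walkers(lat, cfg)
    assert np.all(curve.msd == 0.0)


def test_fast_flicker_is_annealed():
    """tau << 1/lambda_dif: every attempt independently succeeds w.p. p."""
    assert _sim_D(0.5, 0.01) == pytest.approx(0.5 * 0.25, rel=0.10)


def test_open_boundary_rejected():
    lat = mn.make_lattice(8, 2, p=0.5, seed=0)
    with pytest.raises(ValueError, match="periodic"):
        simulate_walkers(lat, WalkerConfig(n_walkers=2, t_max=1.0))


def test_walker_config_validation():
    with pytest.raises(ValueError):
        WalkerConfig(lambda_dif=0.0)
    with pytest.raises(ValueError):
        WalkerConfig(n_walkers=0)
    with pytest.raises(ValueError):
        WalkerConfig(t_max=-1.0)
    with pytest.raises(ValueError):
        WalkerConfig(t_max=10.0, record_times=np.array([0.0, 20.0]))


def test_estimate_D_exact_line():
    t = np.linspace(0, 10, 21)
    curve = MSDCurve(times=t, msd=4.0 * t, stderr=np.zeros_like(t), n_walkers=1, d=2)
    est = estimate_D(curve, (0.0, 10.0))
    assert est.D_app == pytest.approx(1.0)
    assert est.r_squared == pytest.approx(1.0)


def test_estimate_D_plateau_is_confined():
    t = np.linspace(0, 100, 51)
    msd = 5.0 * (1.0 - np.exp(-t / 2.0))
    curve = MSDCurve(times=t, msd=msd, stderr=np.zeros_like(t), n_walkers=1, d=2)
    est = estimate_D(curve, (50.0, 100.0))
    assert est.D_app < 1e-2


def test_estimate_D_recovers_known_coefficient():
    """Parameter recovery: noisy synthetic MSD generated with D = 0.2."""
    rng = np.random.default_rng(4)
    t = np.linspace(0, 100, 41)
    true_D = 0.2
    msd = 2 * 2 * true_D * t + rng.normal(0, 0.5, t.size)
    curve = MSDCurve(times=t, msd=msd, stderr=np.full(t.size, 0.5), n_walkers=100, d=2)
    est = estimate_D(curve, (0.0, 100.0))
    assert est.D_app == pytest.approx(true_D, abs=0.02)


def test_estimate_D_window_validation():
    t = np.linspace(0, 10, 21)
    curve = MSDCurve(times=t, msd=t, stderr=np.zeros_like(t), n_walkers=1, d=2)
    with pytest.raises(ValueError):
        estimate_D(curve, (5.0, 5.0))
    with pytest.raises(ValueError):
        estimate_D(curve, (9.4, 10.0))  # fewer than 5 points


def test_negative_slope_clipped_with_warning():
    t = np.linspace(0, 10, 11)
    curve = MSDCurve(times=t, msd=10.0 - t, stderr=np.zeros_like(t), n_walkers=1, d=2)
    with pytest.warns(UserWarning):
        est = estimate_D(curve, (0.0, 10.0))
    assert est.D_app == 0.0


@pytest.mark.parametrize("d", [2, 3])
def test_ema_exact_limits(d):
    lam = 1.3
    free = lam / (2 * d)
    assert ema_diffusion(1.0, 7.0, lam, d) == pytest.approx(free)
    # tau -> 0 annealed limit within 1%
    assert ema_diffusion(0.37, 1e-9, lam, d) == pytest.approx(0.37 * free, rel=0.01)
    assert ema_diffusion(0.0, 1.0, lam, d) == 0.0


def test_static_ema_closed_form_square_lattice():
    """z = 4 static EMA: D/D_free = 2p - 1 above p = 1/2, zero below."""
    for p in (0.55, 0.75, 0.9):
        assert ema_diffusion(p, math.inf) == pytest.approx((2 * p - 1) * 0.25)
    for p in (0.1, 0.3, 0.5):
        assert ema_diffusion(p, math.inf) == 0.0


def test_static_ema_against_simulation_above_threshold():
    """Static EMA 2p - 1 is close to a long static-lattice simulation."""
    D = _sim_D(0.75, math.inf, n_walkers=2500, seed=21)
    assert D == pytest.approx(0.125, rel=0.15)


def test_ema_validation():
    with pytest.raises(ValueError):
        ema_diffusion(1.2, 1.0)
    with pytest.raises(ValueError):
        ema_diffusion(0.5, -1.0)
    with pytest.raises(ValueError):
        ema_diffusion(0.5, 1.0, d=4)


def test_ema_monotone_in_p_and_tau():
    ps = np.linspace(0.05, 0.95, 10)
    taus = [0.01, 0.1, 1.0, 10.0, 1e3]
    for tau in taus:
        vals = [ema_diffusion(p, tau) for p in ps]
        assert np.all(np.diff(vals) > -1e-12)
    for p in (0.2, 0.5, 0.8):
        vals = [ema_diffusion(p, tau) for tau in taus]
        assert np.all(np.diff(vals) < 1e-12)


def test_simulated_D_monotone_in_p_and_tau():
    """D_app non-decreasing in p at fixed tau; non-increasing in tau at p = 0.5."""
    Ds = [_sim_D(p, 1.0, n_walkers=1200, seed=31) for p in (0.2, 0.5, 0.8)]
    assert Ds[0] < Ds[1] < Ds[2]
    Dt = [_sim_D(0.5, tau, n_walkers=1200, seed=32) for tau in (0.1, 1.0, 10.0)]
    assert Dt[0] > Dt[1] > Dt[2]


def test_switch_like_nonlinearity_of_mean_field():
    """At tau = inf the steepest dD/dp sits at p_c; fast flicker is linear."""
    ps = np.linspace(0.3, 0.7, 21)
    static = np.array([ema_diffusion(p, math.inf) for p in ps])
    grad = np.diff(static)
    mids = (ps[1:] + ps[:-1]) / 2
    assert 0.45 <= mids[np.argmax(grad)] <= 0.55
    fast = np.array([ema_diffusion(p, 1e-4) for p in ps])
    # curvature of the fast-flicker curve vanishes
    assert np.abs(np.diff(fast, 2)).max() < 1e-4 * fast.max()


def test_simulation_matches_exact_master_equation_on_small_lattices():
    """Walker MSD slope vs exact corrector solve on static 4x4 configurations."""
    for k in range(3):
        lat = mn.make_lattice(4, 2, p=0.8, tau=math.inf, boundary="periodic", seed=100 + k)
        d_exact = exact_effective_diffusion(4, lat.bond_state)
        cfg = WalkerConfig(n_walkers=8000, t_max=300.0, seed=200 + k, fresh_lattice_per_walker=False)
        d_sim = estimate_D(simulate_walkers(lat, cfg), fit_window=(100.0, 300.0)).D_app
        assert d_sim == pytest.approx(d_exact, rel=0.05)


def test_diffusion_surface_table_shapes_and_regimes():
    ps = [0.05, 0.25, 0.45, 0.65, 0.85]
    taus = [0.1, 1.0, 10.0, math.inf]
    df = diffusion_surface(ps, taus, method="ema")
    assert len(df) == 20
    assert set(df.columns) == {"p", "tau", "method", "D", "stderr"}
    static = df[np.isinf(df["tau"])].sort_values("p")["D"].to_numpy()
    assert np.all(static[:2] == 0.0) and np.all(np.diff(static[2:]) > 0)
    # microfused with fast flicker still diffuses slower than a slow hyperfused net
    assert ema_diffusion(0.05, 0.01) < ema_diffusion(0.8, 100.0)


def test_diffusion_surface_sim_reproducible():
    cfg = WalkerConfig(n_walkers=60, t_max=30.0)
    a = diffusion_surface([0.5], [1.0], method="sim", walker_config=cfg, seed=5)
    b = diffusion_surface([0.5], [1.0], method="sim", walker_config=cfg, seed=5)
    pd.testing.assert_frame_equal(a, b)


def test_kiss_and_run_range():
    # GFP-like mobility over a mean 45 s transient fusion contact
    assert kiss_and_run_range(20.0, 45.0, 3) == pytest.approx(math.sqrt(5400), rel=1e-12)
    assert kiss_and_run_range(1.0, 0.5, 1) == pytest.approx(1.0)
    assert kiss_and_run_range(0.0, 1.0) == 0.0
    with pytest.raises(ValueError):
        kiss_and_run_range(1.0, 0.0)
    with pytest.raises(ValueError):
        kiss_and_run_range(-1.0, 1.0)
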