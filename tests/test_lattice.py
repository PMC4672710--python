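"""Fluctuating bond lattice: construction, exact flicker law, connectivity."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mitonet as mn
from mitonet.lattice import spanning_probability

from oracles import bfs_components


@pytest.mark.parametrize(
    "L,d,boundary,expected",
    [
        (4, 2, "open", 2 * 4 * 3),
        (5, 2, "open", 2 * 5 * 4),
        (3, 3, "open", 3 * 9 * 2),
        (4, 2, "periodic", 2 * 16),
        (3, 3, "periodic", 3 * 27),
    ],
)
def test_bond_count(L, d, boundary, expected):
    lat = mn.make_lattice(L, d, lambda_fus=1.0, lambda_fis=1.0, boundary=boundary)
    assert lat.n_bonds == expected


def test_p_tau_derived_from_rates():
    lat = mn.make_lattice(4, 2, lambda_fus=2.0, lambda_fis=2.0, seed=0)
    assert lat.p == pytest.approx(0.5)
    assert lat.tau == pytest.approx(0.25)
    # no fission at all forces p = 1: every bond on
    lat = mn.make_lattice(4, 2, lambda_fus=1.0, lambda_fis=0.0, seed=0)
    assert lat.p == 1.0
    assert lat.bond_state.all()


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(L=1, d=2, lambda_fus=1.0, lambda_fis=1.0),
        dict(L=4, d=4, lambda_fus=1.0, lambda_fis=1.0),
        dict(L=4, d=2, lambda_fus=-1.0, lambda_fis=1.0),
        dict(L=4, d=2, lambda_fus=0.0, lambda_fis=0.0),
        dict(L=4, d=2, p=1.5),
        dict(L=4, d=2, lambda_fus=1.0, lambda_fis=1.0, p=0.5),
        dict(L=4, d=2, lambda_fus=1.0),
        dict(L=4, d=2, lambda_fus=1.0, lambda_fis=1.0, boundary="twisted"),
    ],
)
def test_make_lattice_rejects_invalid(kwargs):
    with pytest.raises(ValueError):
        mn.make_lattice(**kwargs)


def test_seed_reproducibility():
    a = mn.make_lattice(16, 2, p=0.4, seed=123)
    b = mn.make_lattice(16, 2, p=0.4, seed=123)
    assert np.array_equal(a.bond_state, b.bond_state)


def test_stationary_on_fraction_converges_to_p():
    """Long-run time-averaged on-bond fraction sits at p (no drift)."""
    p = 0.3
    lat = mn.make_lattice(64, 2, lambda_fus=0.3, lambda_fis=0.7, seed=5)
    tau = lat.tau
    fracs = []
    for _ in range(120):
        mn.step_bonds(lat, 5 * tau)  # ~decorrelated snapshots
        fracs.append(lat.bond_state.mean())
    fracs = np.asarray(fracs)
    se = fracs.std(ddof=1) / math.sqrt(len(fracs))
    assert abs(fracs.mean() - p) < 3 * se
    # no drift: slope of fraction vs sample index consistent with zero
    idx = np.arange(len(fracs))
    slope = np.polyfit(idx, fracs, 1)[0]
    slope_se = se / idx.std() / math.sqrt(len(fracs) - 2) * math.sqrt(len(fracs))
    assert abs(slope) < 3 * slope_se


def test_step_bonds_exact_transition_probabilities():
    """Off->on probability over dt matches p (1 - e^(-dt/tau)) exactly in law."""
    p, tau, dt = 0.4, 2.0, 1.0
    lat = mn.make_lattice(100, 2, lambda_fus=p / tau, lambda_fis=(1 - p) / tau, seed=7)
    lat.bond_state[:] = False
    mn.step_bonds(lat, dt)
    n = lat.n_bonds
    expected = p * (1 - math.exp(-dt / tau))
    se = math.sqrt(expected * (1 - expected) / n)
    assert abs(lat.bond_state.mean() - expected) < 3 * se


def test_step_bonds_composition_has_same_law():
    """Two half-steps are distributionally identical to one full step."""
    p, tau, dt = 0.6, 1.5, 2.0
    kw = dict(lambda_fus=p / tau, lambda_fis=(1 - p) / tau)
    one = mn.make_lattice(100, 2, **kw, seed=11)
    two = mn.make_lattice(100, 2, **kw, seed=12)
    one.bond_state[:] = False
    two.bond_state[:] = False
    mn.step_bonds(one, dt)
    mn.step_bonds(two, dt / 2)
    mn.step_bonds(two, dt / 2)
    f1, f2 = one.bond_state.mean(), two.bond_state.mean()
    n = one.n_bonds
    pool = (f1 + f2) / 2
    z = (f1 - f2) / math.sqrt(2 * pool * (1 - pool) / n)
    assert abs(z) < 3


def test_bond_autocorrelation_decays_with_tau():
    """Stationary autocorrelation of a bond state decays as e^(-dt/tau)."""
    p, tau = 0.5, 2.0
    lat = mn.make_lattice(100, 2, lambda_fus=p / tau, lambda_fis=(1 - p) / tau, seed=3)
    dt = 1.0
    before = lat.bond_state.copy()
    mn.step_bonds(lat, dt)
    after = lat.bond_state
    rho = np.corrcoef(before, after)[0, 1]
    expected = math.exp(-dt / tau)
    assert rho == pytest.approx(expected, abs=3 / math.sqrt(lat.n_bonds))


def test_absorbing_when_no_fission():
    lat = mn.make_lattice(8, 2, lambda_fus=1.0, lambda_fis=0.0, seed=0)
    mn.step_bonds(lat, 100.0)
    assert lat.bond_state.all()
    with pytest.raises(ValueError):
        mn.step_bonds(lat, 0.0)


def test_cluster_stats_extremes():
    lat = mn.make_lattice(5, 2, p=0.0, seed=0)
    st = mn.connectivity_stats(lat)
    assert st.n_clusters == 25
    assert st.cluster_sizes.max() == 1
    assert not st.spanning
    assert st.largest_fraction == pytest.approx(1 / 25)

    lat = mn.make_lattice(5, 2, p=1.0, seed=0)
    st = mn.connectivity_stats(lat)
    assert st.n_clusters == 1
    assert st.spanning
    assert st.largest_fraction == 1.0


@given(
    L=st.sampled_from([4, 6, 8]),
    p=st.floats(0.1, 0.9),
    seed=st.integers(0, 10_000),
)
def test_cluster_sizes_sum_to_node_count(L, p, seed):
    lat = mn.make_lattice(L, 2, p=p, seed=seed)
    st_ = mn.connectivity_stats(lat)
    assert int(st_.cluster_sizes.sum()) == L * L


@pytest.mark.parametrize("L", [4, 8])
@pytest.mark.parametrize("p", [0.2, 0.5, 0.8])
def test_connectivity_matches_bfs_oracle(L, p):
    """Component multiset and spanning agree with a brute-force BFS."""
    for seed in range(5):
        lat = mn.make_lattice(L, 2, p=p, seed=seed)
        st_ = mn.connectivity_stats(lat)
        on = lat.bond_state
        comps = bfs_components(
            L * L, list(zip(lat.bond_u[on].tolist(), lat.bond_v[on].tolist()))
        )
        assert sorted(len(c) for c in comps) == sorted(st_.cluster_sizes.tolist())
        coords0 = lat.coords(np.arange(L * L))[:, 0]
        spanning_bfs = any(
            any(coords0[i] == 0 for i in comp) and any(coords0[i] == L - 1 for i in comp)
            for comp in comps
        )
        assert st_.spanning == spanning_bfs


def test_spanning_frequency_near_half_at_critical_p():
    """Square-lattice bond percolation is self-dual: ~half of p = 0.5
    snapshots span."""
    rng = np.random.default_rng(17)
    frac = spanning_probability(64, 2, 0.5, 500, rng)
    assert abs(frac - 0.5) < 1.96 * math.sqrt(0.25 / 500) + 0.02  # binomial CI + finite size


@pytest.mark.parametrize(
    "p,lambda_fis,expected",
    [
        (0.0, 0.5, "fragmented"),
        (0.03, 0.5, "microfused"),
        (0.3, 0.5, "mesofused"),
        (0.6, 0.5, "dynamic_hyperfused"),
        (0.99, 0.5, "static_hyperfused"),
        (0.99, 0.0, "static_hyperfused"),
        (0.6, 0.0, "static_hyperfused"),
    ],
)
def test_classify_morphology(p, lambda_fis, expected):
    assert mn.classify_morphology(p, lambda_fis).label == expected


def test_classify_morphology_validation():
    with pytest.raises(ValueError):
        mn.classify_morphology(1.2, 0.5)
    with pytest.raises(ValueError):
        mn.classify_morphology(0.5, 0.5, p_c=1.0)
    with pytest.raises(ValueError):
        mn.classify_morphology(0.5, 0.5, eps=0.6)


def test_percolation_threshold_estimate_small_lattice():
    est = mn.estimate_percolation_threshold(L=32, n_snapshots=100, seed=2, n_iter=8)
    assert abs(est.p_c - 0.5) < 0.06
    assert set(est.history.columns) == {"p", "spanning_fraction"}


def test_graphml_export_roundtrip(tmp_path):
    import networkx as nx

    lat = mn.make_lattice(6, 2, p=0.5, seed=4)
    path = tmp_path / "snap.graphml"
    from mitonet.lattice import export_graphml

    export_graphml(lat, path)
    g = nx.read_graphml(path)
    assert g.number_of_nodes() == 36
    assert g.number_of_edges() == int(lat.bond_state.sum())


def test_cluster_timeseries_roundtrip(tmp_path):
    import pandas as pd

    lat = mn.make_lattice(12, 2, lambda_fus=1.0, lambda_fis=1.0, seed=8)
    df = mn.lattice.cluster_timeseries(lat, dt=0.5, n_steps=5)
    assert list(df.columns) == [
        "time",
        "n_clusters",
        "largest_fraction",
        "spanning",
        "mean_fragment_size",
        "on_fraction",
    ]
    assert len(df) == 6
    path = tmp_path / "ts.csv"
    df.to_csv(path, index=False)
    back = pd.read_csv(path)
    assert np.allclose(back["largest_fraction"], df["largest_fraction"])
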