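"""Independent brute-force oracles used by the test suite only.

These deliberately avoid the library code paths they check: components
come from a hand-rolled breadth-first search, effective diffusion from a
direct linear solve of the master-equation corrector, and the
quality-control steady state from a closed form derived by hand.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_components(n_nodes: int, edges) -> list[set[int]]:
    """Connected components by breadth-first search over an edge list."""
    adj: dict[int, list[int]] = {i: [] for i in range(n_nodes)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    seen = set()
    comps = []
    for s in range(n_nodes):
        if s in seen:
            continue
        comp = {s}
        seen.add(s)
        q = deque([s])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    comp.add(v)
                    q.append(v)
        comps.append(comp)
    return comps


def exact_effective_diffusion(L: int, bond_on: np.ndarray, lambda_dif: float = 1.0) -> float:
    """Exact long-time D of a static periodic 2D lattice configuration.

    Solves the master-equation corrector (discrete homogenisation)
    problem for the continuous-time walk with per-direction rate
    w = lambda_dif / 4 across on-bonds: for each transport axis a, find
    chi with sum_j w_ij (chi_j - chi_i + dx_ij) = 0 for every node i,
    where dx_ij is the (+-1 or 0) step along axis a including the
    periodic wrap, then

        D_aa = (1 / 2N) * sum_{directed pairs} w_ij * (dx_ij + chi_j - chi_i)^2.

    Returns the isotropic average (D_00 + D_11)/2, which is what the
    MSD of a walker started from the uniform distribution measures.
    Bond order matches the walker kernel: bond id = axis * L^2 +
    ravel(lower endpoint).
    """
    n = L * L
    w = lambda_dif / 4.0
    # directed edges (i -> j, step vector)
    edges = []
    for axis in range(2):
        for x0 in range(L):
            for x1 in range(L):
                bid = axis * n + x0 * L + x1
                if not bond_on[bid]:
                    continue
                i = x0 * L + x1
                if axis == 0:
                    j = ((x0 + 1) % L) * L + x1
                    step = (1.0, 0.0)
                else:
                    j = x0 * L + (x1 + 1) % L
                    step = (0.0, 1.0)
                edges.append((i, j, step))
                edges.append((j, i, (-step[0], -step[1])))
    d_axes = []
    for a in range(2):
        A = np.zeros((n, n))
        b = np.zeros(n)
        for i, j, step in edges:
            A[i, i] -= w
            A[i, j] += w
            b[i] -= w * step[a]
        chi, *_ = np.linalg.lstsq(A, b, rcond=None)
        acc = 0.0
        for i, j, step in edges:
            acc += w * (step[a] + chi[j] - chi[i]) ** 2
        d_axes.append(acc / (2.0 * n))
    return float(np.mean(d_axes))


def qc_healthy_fraction_closed_form(lambda_fus, s, lambda_fis, mu, delta) -> float:
    """Steady-state healthy fraction of the default quality-control model.

    For fragmented-only damage, healthy-biogenesis replacement and
    lambda_fis, mu > 0, balancing damage against mitophagy by hand gives

        h* = (1 + x) / (1 + x + (delta/mu) * (1 + s x)),   x = lambda_fus/lambda_fis.
    """
    x = lambda_fus / lambda_fis
    return (1.0 + x) / (1.0 + x + (delta / mu) * (1.0 + s * x))


def two_state_occupancy(a: float, b: float, t: float) -> float:
    """P(down at t) for a two-state chain with down-rate a, up-rate b."""
    return a / (a + b) * (1.0 - np.exp(-(a + b) * t))
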