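"""Spin-coupled agents: collective resistance to catastrophic failure.

Each mitochondrion is a binary agent, functional (+1) or failed (-1),
and prefers to share the state of the mitochondria it is fused to.  The
ensemble carries an Ising-type energy

    E(s) = -J * sum_edges s_i s_j - h * sum_i s_i,

with ferromagnetic coupling J >= 0 across fusion contacts and a bias
h > 0 favouring the functional state.  States evolve by single-flip
Glauber dynamics at noise temperature ``beta_inv`` (heat-bath rates
1/(1 + exp(dE/beta_inv)) per agent, attempt rate 1; a Metropolis
variant shares the same Boltzmann stationary law).

A *catastrophic loss of function* is the event that every agent is in
the failed state.  Two bookkeeping conventions are supported:
``first_hit`` (the all-failed configuration is reached at or before the
horizon T; it is made absorbing) and ``at_horizon`` (all agents failed
at exactly time T).  For uncoupled agents (J = 0) the ``at_horizon``
probability factorises exactly into the closed-form two-state
occupancy per agent; coupling J > 0 makes the all-functional
configuration metastable, so groups fail catastrophically less often
than the same number of independent mitochondria.

Exact probabilities come from the master equation on the full 2^N state
space (N <= 12); larger ensembles use Gillespie sampling with a
reported standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import expm_multiply

__all__ = [
    "SpinEnsemble",
    "SpinFailureResult",
    "spin_failure_probability",
    "group_vs_individual",
    "single_agent_failure_probability",
    "build_generator",
    "boltzmann_distribution",
]

_TOPOLOGIES = ("complete", "chain", "edges")
_DYNAMICS = ("heat_bath", "metropolis")
_DEFINITIONS = ("first_hit", "at_horizon")
_EXACT_MAX_N = 12


@dataclass(frozen=True)
class SpinEnsemble:
    n_agents: int
    coupling: float = 1.0  # J
    bias: float = 1.0  # h
    beta_inv: float = 1.0  # noise temperature
    horizon: float = 10.0  # T
    topology: str = "complete"
    edges: tuple[tuple[int, int], ...] | None = None
    dynamics: str = "heat_bath"
    definition: str = "first_hit"
    seed: int | None = None

    def __post_init__(self):
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.coupling < 0:
            raise ValueError("coupling J must be >= 0")
        if self.beta_inv <= 0:
            raise ValueError("beta_inv must be positive")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.topology not in _TOPOLOGIES:
            raise ValueError(f"topology must be one of {_TOPOLOGIES}")
        if self.topology == "edges" and self.edges is None:
            raise ValueError("topology 'edges' requires an explicit edge list")
        if self.dynamics not in _DYNAMICS:
            raise ValueError(f"dynamics must be one of {_DYNAMICS}")
        if self.definition not in _DEFINITIONS:
            raise ValueError(f"definition must be one of {_DEFINITIONS}")

    def edge_list(self) -> list[tuple[int, int]]:
        n = self.n_agents
        if self.topology == "complete":
            return [(i, j) for i in range(n) for j in range(i + 1, n)]
        if self.topology == "chain":
            return [(i, i + 1) for i in range(n - 1)]
        edges = [tuple(sorted(e)) for e in self.edges]
        if any(not 0 <= i < j < n for i, j in edges):
            raise ValueError("edge endpoints must be distinct agents in range")
        return edges

    @classmethod
    def from_lattice_cluster(cls, lattice, **kwargs) -> "SpinEnsemble":
        """Couple the agents of the largest fused cluster of a lattice."""
        from .lattice import _component_labels

        _, labels = _component_labels(lattice)
        sizes = np.bincount(labels)
        big = int(np.argmax(sizes))
        nodes = np.flatnonzero(labels == big)
        index = {int(u): k for k, u in enumerate(nodes)}
        on = lattice.bond_state
        edges = []
        for u, v in zip(lattice.bond_u[on], lattice.bond_v[on]):
            if int(u) in index and int(v) in index:
                a, b = index[int(u)], index[int(v)]
                edges.append((min(a, b), max(a, b)))
        return cls(
            n_agents=len(nodes), topology="edges", edges=tuple(sorted(set(edges))), **kwargs
        )


@dataclass
class SpinFailureResult:
    p_catastrophe: float
    method: str
    stderr: float | None = None
    n_reps: int | None = None


def _neighbour_lists(ens: SpinEnsemble) -> list[list[int]]:
    nbrs: list[list[int]] = [[] for _ in range(ens.n_agents)]
    for i, j in ens.edge_list():
        nbrs[i].append(j)
        nbrs[j].append(i)
    return nbrs


def _flip_rate(dE: float, theta: float, dynamics: str) -> float:
    x = dE / theta
    if dynamics == "heat_bath":
        return 0.0 if x > 700.0 else 1.0 / (1.0 + math.exp(x))
    return 1.0 if x <= 0 else math.exp(-x)


def _spin(state: int, i: int) -> int:
    """+1 functional, -1 failed; bit set means failed."""
    return -1 if (state >> i) & 1 else 1


def build_generator(ens: SpinEnsemble, absorbing: bool) -> sparse.csr_matrix:
    """Rate matrix Q (Q[i, j] = rate i -> j) on the 2^N state space.

    With ``absorbing`` the all-failed configuration has no outflow, so
    the probability mass there at time T is the first-hitting
    probability.
    """
    n = ens.n_agents
    if n > _EXACT_MAX_N:
        raise ValueError(f"exact method limited to N <= {_EXACT_MAX_N}, got {n}")
    nbrs = _neighbour_lists(ens)
    theta = ens.beta_inv
    full = (1 << n) - 1
    rows, cols, vals = [], [], []
    for state in range(1 << n):
        if absorbing and state == full:
            continue
        out = 0.0
        for i in range(n):
            s_i = _spin(state, i)
            local = sum(_spin(state, j) for j in nbrs[i])
            dE = 2.0 * s_i * (ens.coupling * local + ens.bias)
            rate = _flip_rate(dE, theta, ens.dynamics)
            if rate > 0:
                rows.append(state)
                cols.append(state ^ (1 << i))
                vals.append(rate)
                out += rate
        rows.append(state)
        cols.append(state)
        vals.append(-out)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(1 << n, 1 << n)
    )


def boltzmann_distribution(ens: SpinEnsemble) -> np.ndarray:
    """Stationary Boltzmann weights exp(-E/beta_inv), normalised (N <= 12)."""
    n = ens.n_agents
    if n > _EXACT_MAX_N:
        raise ValueError(f"limited to N <= {_EXACT_MAX_N}")
    edges = ens.edge_list()
    w = np.empty(1 << n)
    for state in range(1 << n):
        e = -ens.bias * sum(_spin(state, i) for i in range(n))
        e -= ens.coupling * sum(_spin(state, i) * _spin(state, j) for i, j in edges)
        w[state] = math.exp(-e / ens.beta_inv)
    return w / w.sum()


def spin_failure_probability(
    ens: SpinEnsemble, method: str = "exact", n_reps: int = 2000
) -> SpinFailureResult:
    """Probability of catastrophic (all-agent) failure within the horizon.

    ``exact`` solves the master equation (N <= 12) by the action of the
    matrix exponential; ``monte_carlo`` runs Gillespie trajectories and
    reports a binomial standard error.
    """
    if method == "exact":
        full = (1 << ens.n_agents) - 1
        Q = build_generator(ens, absorbing=ens.definition == "first_hit")
        p0 = np.zeros(1 << ens.n_agents)
        p0[0] = 1.0  # all functional
        pT = expm_multiply(Q.T.tocsc() * ens.horizon, p0)
        return SpinFailureResult(p_catastrophe=float(pT[full]), method="exact")
    if method != "monte_carlo":
        raise ValueError("method must be 'exact' or 'monte_carlo'")
    hits = _gillespie_hits(ens, n_reps)
    p = hits / n_reps
    se = math.sqrt(max(p * (1 - p), 1.0 / n_reps) / n_reps)
    return SpinFailureResult(
        p_catastrophe=p, method="monte_carlo", stderr=se, n_reps=n_reps
    )


def _gillespie_hits(ens: SpinEnsemble, n_reps: int) -> int:
    rng = np.random.default_rng(ens.seed)
    n = ens.n_agents
    nbrs = _neighbour_lists(ens)
    theta = ens.beta_inv
    T = ens.horizon
    first_hit = ens.definition == "first_hit"
    hits = 0
    rates = np.empty(n)
    for _ in range(n_reps):
        spins = np.ones(n, dtype=np.int8)
        t = 0.0
        while True:
            if first_hit and np.all(spins == -1):
                hits += 1
                break
            for i in range(n):
                local = sum(spins[j] for j in nbrs[i])
                dE = 2.0 * spins[i] * (ens.coupling * local + ens.bias)
                rates[i] = _flip_rate(dE, theta, ens.dynamics)
            total = rates.sum()
            t += rng.exponential(1.0 / total)
            if t > T:
                if not first_hit and np.all(spins == -1):
                    hits += 1
                break
            i = int(rng.choice(n, p=rates / total))
            spins[i] = -spins[i]
    return hits


def single_agent_failure_probability(
    bias: float,
    beta_inv: float = 1.0,
    horizon: float = 10.0,
    definition: str = "first_hit",
    dynamics: str = "heat_bath",
) -> float:
    """Closed-form catastrophe probability of one uncoupled agent.

    The two-state chain has fail rate a = w(+2h) and recovery rate
    b = w(-2h).  For ``first_hit`` the failed state is absorbing and
    P = 1 - exp(-a T); for ``at_horizon`` the occupancy is
    P = a/(a+b) * (1 - exp(-(a+b) T)).
    """
    a = _flip_rate(2.0 * bias, beta_inv, dynamics)
    b = _flip_rate(-2.0 * bias, beta_inv, dynamics)
    if definition == "first_hit":
        return 1.0 - math.exp(-a * horizon)
    if definition != "at_horizon":
        raise ValueError(f"definition must be one of {_DEFINITIONS}")
    return a / (a + b) * (1.0 - math.exp(-(a + b) * horizon))


def group_vs_individual(
    ens: SpinEnsemble, method: str | None = None, n_reps: int = 2000
) -> dict:
    """Catastrophe probability: coupled group vs independent agents vs one agent.

    All three share (h, beta_inv, T) and the catastrophe definition.
    ``p_independent`` is the same ensemble with J = 0; ``p_single`` is a
    lone agent.  With strong coupling the group probability falls far
    below the independent-agent value.
    """
    if ens.n_agents < 2:
        raise ValueError("group comparison needs N >= 2")
    if method is None:
        method = "exact" if ens.n_agents <= _EXACT_MAX_N else "monte_carlo"
    group = spin_failure_probability(ens, method=method, n_reps=n_reps)
    indep = spin_failure_probability(
        replace(ens, coupling=0.0), method=method, n_reps=n_reps
    )
    single = single_agent_failure_probability(
        ens.bias, ens.beta_inv, ens.horizon, ens.definition, ens.dynamics
    )
    return {
        "n_agents": ens.n_agents,
        "coupling": ens.coupling,
        "bias": ens.bias,
        "definition": ens.definition,
        "p_group": group.p_catastrophe,
        "p_group_se": group.stderr,
        "p_independent": indep.p_catastrophe,
        "p_independent_se": indep.stderr,
        "p_single": single,
        "p_single_power_n": single ** ens.n_agents,
        "method": method,
    }
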