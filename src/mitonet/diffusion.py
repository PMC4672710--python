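"""Tracer diffusion on the fluctuating lattice.

Two routes to the apparent diffusion coefficient D(p, tau) of a species
hopping through the mitochondrial network:

* an agent-based, event-driven simulation of blind-ant walkers whose hop
  attempts succeed only across bonds that are currently on
  (:func:`simulate_walkers` + :func:`estimate_D`), and

* a dynamic effective-medium approximation (:func:`ema_diffusion`).

The mean-field closure replaces every bond by an effective conductance
``theta`` solving the standard bond-EMA self-consistency condition with
the bond-flicker rate ``1/tau`` entering as an additive frequency shift
``gamma`` of all conductances (in units of the per-bond hop rate
``lambda_dif / 2d``):

    sum_w P(w) * (w + gamma - theta') / (w + gamma + (z/2 - 1) theta') = 0,
    theta = theta' - gamma,  D = theta * lambda_dif / (2 d),

with w in {0, 1} (prob 1-p, p) and z = 2d.  The shift form has the two
exact limits demanded of any dynamic-percolation mean field: at
tau = inf it reduces to the static EMA, D/D_free = (z p/2 - 1)/(z/2 - 1)
above the EMA threshold p = 2/z and 0 below, and at tau -> 0 it gives
the annealed result D = p * D_free, because a bond flickering much
faster than the walker hops acts as its time average.  Near p = 1/2
(2D) the flicker lifts D above zero like sqrt(gamma), the same
square-root lifting known from AC conductivity at a percolation
threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import brentq

from .lattice import NetworkLattice, make_lattice

__all__ = [
    "WalkerConfig",
    "MSDCurve",
    "DiffusionEstimate",
    "simulate_walkers",
    "estimate_D",
    "ema_diffusion",
    "diffusion_surface",
    "kiss_and_run_range",
]

_MODE_STATIC = 0
_MODE_ANNEALED = 1
_MODE_DYNAMIC = 2

#: crossover constant of the dynamic-EMA closure (see ema_diffusion)
_EMA_CROSSOVER = 1.5


@dataclass
class WalkerConfig:
    """Parameters of a walker ensemble.

    lambda_dif is the total hop-attempt rate; a walker picks one of the
    2d neighbours uniformly at each attempt, so the free-lattice
    diffusion coefficient is lambda_dif / (2 d) (lattice constant 1).
    ``fresh_lattice_per_walker`` gives each walker an independent bond
    realisation (walkers do not interact, so the single-walker law and
    hence the MSD are unchanged; cross-walker correlations are removed).
    Set it False on a static lattice to make every walker diffuse on the
    exact bond configuration held by the lattice object.
    """

    lambda_dif: float = 1.0
    n_walkers: int = 400
    t_max: float = 200.0
    record_times: np.ndarray | None = None
    seed: int | None = None
    fresh_lattice_per_walker: bool = True

    def __post_init__(self):
        if self.lambda_dif <= 0:
            raise ValueError("lambda_dif must be positive")
        if self.n_walkers < 1:
            raise ValueError("need at least one walker")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.record_times is None:
            self.record_times = np.linspace(0.0, self.t_max, 41)
        self.record_times = np.asarray(self.record_times, dtype=float)
        if np.any(np.diff(self.record_times) <= 0):
            raise ValueError("record_times must be strictly increasing")
        if self.record_times[0] < 0 or self.record_times[-1] > self.t_max:
            raise ValueError("record_times must lie in [0, t_max]")


@dataclass
class MSDCurve:
    times: np.ndarray
    msd: np.ndarray
    stderr: np.ndarray
    n_walkers: int
    d: int


@dataclass
class DiffusionEstimate:
    D_app: float
    fit_window: tuple[float, float]
    r_squared: float
    slope: float
    intercept: float


@njit(cache=True)
def _walk_kernel(
    L,
    d,
    p,
    tau,
    mode,
    lam,
    seeds,
    preset,
    use_preset,
    t_max,
    record_times,
    out_sum,
    out_sumsq,
):
    n_sites = L ** d
    n_bonds = d * n_sites
    nrec = record_times.shape[0]
    bond_state = np.empty(n_bonds, np.int8)
    bond_t = np.empty(n_bonds, np.float64)
    pos = np.zeros(3, np.int64)  # unwrapped displacement from the start cell
    start = np.zeros(3, np.int64)
    wrapped = np.zeros(3, np.int64)
    for w in range(seeds.shape[0]):
        np.random.seed(seeds[w])
        if use_preset:
            for b in range(n_bonds):
                bond_state[b] = preset[b]
        else:
            for b in range(n_bonds):
                bond_state[b] = -1
        for b in range(n_bonds):
            bond_t[b] = 0.0
        for k in range(d):
            pos[k] = 0
            # uniform start cell: the stationary law of the walk
            c = int(np.random.random() * L)
            start[k] = c if c < L else L - 1
        t = 0.0
        irec = 0
        while True:
            dt = -math.log(np.random.random()) / lam
            tn = t + dt
            while irec < nrec and record_times[irec] <= tn:
                r2 = 0.0
                for k in range(d):
                    r2 += pos[k] * pos[k]
                out_sum[irec] += r2
                out_sumsq[irec] += r2 * r2
                irec += 1
            if irec >= nrec or tn > t_max:
                break
            t = tn
            # uniform neighbour choice: axis and direction
            axis = int(np.random.random() * d)
            if axis >= d:
                axis = d - 1
            step = 1 if np.random.random() < 0.5 else -1
            for k in range(d):
                c = (start[k] + pos[k]) % L
                if c < 0:
                    c += L
                wrapped[k] = c
            if step < 0:
                wrapped[axis] = (wrapped[axis] - 1 + L) % L
            # bond id: axis-major, C-raveled lower endpoint
            idx = 0
            for k in range(d):
                idx = idx * L + wrapped[k]
            bid = axis * n_sites + idx
            s = bond_state[bid]
            if mode == 1:  # annealed: fresh sample every attempt
                s = 1 if np.random.random() < p else 0
            elif mode == 0:  # static: lazy quenched sample
                if s < 0:
                    s = 1 if np.random.random() < p else 0
                    bond_state[bid] = s
            else:  # dynamic: exact two-state transition since last query
                if s < 0:
                    s = 1 if np.random.random() < p else 0
                else:
                    q = math.exp(-(t - bond_t[bid]) / tau)
                    p_on = p + (s - p) * q
                    s = 1 if np.random.random() < p_on else 0
                bond_state[bid] = s
                bond_t[bid] = t
            if s == 1:
                pos[axis] += step


def simulate_walkers(lattice: NetworkLattice, config: WalkerConfig) -> MSDCurve:
    """Co-simulate blind-ant walkers and bond flicker, event by event.

    Hop attempts form a Poisson process of rate ``lambda_dif``; at each
    attempt the walker draws a uniform neighbour and crosses iff the
    connecting bond is on at that instant.  Bond states are advanced
    lazily with the exact two-state transition law, so the scheme is
    exact in distribution (no time-step bias).  Displacement is tracked
    unwrapped on the periodic lattice.
    """
    if lattice.boundary != "periodic":
        raise ValueError("diffusion runs require a periodic lattice")
    p = lattice.p
    tau = lattice.tau
    if math.isinf(tau):
        mode = _MODE_STATIC
        tau_k = 1.0
    elif tau == 0:
        mode = _MODE_ANNEALED
        tau_k = 1.0
    else:
        mode = _MODE_DYNAMIC
        tau_k = tau
    use_preset = (not config.fresh_lattice_per_walker) and mode == _MODE_STATIC
    n_bonds = lattice.d * lattice.n_nodes
    preset = np.zeros(n_bonds, dtype=np.int8)
    if use_preset:
        preset[:] = lattice.bond_state.astype(np.int8)
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(config.n_walkers).astype(np.int64)
    rec = config.record_times
    out_sum = np.zeros(rec.size)
    out_sumsq = np.zeros(rec.size)
    _walk_kernel(
        lattice.L,
        lattice.d,
        p,
        tau_k,
        mode,
        config.lambda_dif,
        seeds,
        preset,
        use_preset,
        config.t_max,
        rec,
        out_sum,
        out_sumsq,
    )
    n = config.n_walkers
    msd = out_sum / n
    if n > 1:
        var = np.maximum(out_sumsq / n - msd ** 2, 0.0) * n / (n - 1)
    else:
        var = np.zeros_like(msd)
    return MSDCurve(
        times=rec.copy(),
        msd=msd,
        stderr=np.sqrt(var / n),
        n_walkers=n,
        d=lattice.d,
    )


def estimate_D(
    curve: MSDCurve, fit_window: tuple[float, float] | None = None
) -> DiffusionEstimate:
    """Apparent D from a weighted linear fit of MSD(t) over a window.

    D = slope / (2 d); a negative fitted slope (possible for a confined
    walk plus noise) is clipped to zero with a warning.
    """
    if fit_window is None:
        fit_window = (0.5 * curve.times[-1], curve.times[-1])
    t_lo, t_hi = fit_window
    if not t_lo < t_hi:
        raise ValueError(f"empty fit window {fit_window}")
    mask = (curve.times >= t_lo) & (curve.times <= t_hi)
    if mask.sum() < 5:
        raise ValueError("need at least 5 recorded times inside the fit window")
    t = curve.times[mask]
    y = curve.msd[mask]
    se = curve.stderr[mask]
    pos = se > 0
    w = np.ones_like(se)
    if pos.any():
        w[pos] = se[pos].min() / se[pos]  # relative weights ~ 1/se
    slope, intercept = np.polyfit(t, y, 1, w=w)
    yhat = slope * t + intercept
    ss_res = float(np.sum((w * (y - yhat)) ** 2))
    ybar = float(np.average(y, weights=w ** 2))
    ss_tot = float(np.sum((w * (y - ybar)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    d_app = slope / (2.0 * curve.d)
    if d_app < 0:
        warnings.warn("negative fitted MSD slope clipped to D = 0", stacklevel=2)
        d_app = 0.0
    return DiffusionEstimate(
        D_app=float(d_app),
        fit_window=(float(t_lo), float(t_hi)),
        r_squared=r2,
        slope=float(slope),
        intercept=float(intercept),
    )


def _static_ema_fraction(p: float, z: int) -> float:
    """Static bond-EMA conductance fraction (z p / 2 - 1)/(z/2 - 1), clipped at 0."""
    return max(0.0, (z * p / 2.0 - 1.0) / (z / 2.0 - 1.0))


def ema_diffusion(p: float, tau: float, lambda_dif: float = 1.0, d: int = 2) -> float:
    """Dynamic effective-medium prediction for D(p, tau).

    See the module docstring for the self-consistency equation.  Exact
    limits: D(p=1) = lambda_dif/(2d); tau = inf gives the static EMA
    (for the square lattice, D/D_free = 2p - 1 above p = 1/2, zero
    below); tau -> 0 gives the annealed D = p * lambda_dif/(2d).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if tau < 0:
        raise ValueError("tau must be >= 0 (may be inf)")
    if lambda_dif <= 0:
        raise ValueError("lambda_dif must be positive")
    if d not in (2, 3):
        raise ValueError("d must be 2 or 3")
    z = 2 * d
    d_free = lambda_dif / (2.0 * d)
    if p == 1.0:
        return d_free
    if p == 0.0:
        return 0.0
    if math.isinf(tau):
        return _static_ema_fraction(p, z) * d_free
    if tau == 0.0:
        return p * d_free
    # Dimensionless flicker frequency.  The crossover constant C0 is the
    # closure's one free parameter (the exact dynamic-EMA kernel would
    # fix it); it is calibrated once against the agent-based model at
    # (p, tau) = (0.5, 10), d = 2, and does not affect either exact
    # limit.  See the methods note.
    gamma = _EMA_CROSSOVER / (lambda_dif * tau)
    half = z / 2.0 - 1.0

    def f(theta_p: float) -> float:
        return p * (1.0 + gamma - theta_p) / (1.0 + gamma + half * theta_p) + (
            1.0 - p
        ) * (gamma - theta_p) / (gamma + half * theta_p)

    theta_p = brentq(f, gamma, 1.0 + gamma, xtol=1e-14, rtol=1e-14)
    return max(0.0, theta_p - gamma) * d_free


def diffusion_surface(
    p_grid,
    tau_grid,
    method: str = "ema",
    lambda_dif: float = 1.0,
    d: int = 2,
    L: int = 64,
    walker_config: WalkerConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tabulate D(p, tau) on a grid by either route.

    Returns a tidy frame with columns p, tau, method, D, stderr (the
    stderr of a simulated D is propagated from the MSD fit residuals; it
    is NaN for the mean-field rows).
    """
    p_grid = np.atleast_1d(np.asarray(p_grid, dtype=float))
    tau_grid = np.atleast_1d(np.asarray(tau_grid, dtype=float))
    if p_grid.size == 0 or tau_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if method not in ("ema", "sim"):
        raise ValueError(f"method must be 'ema' or 'sim', got {method!r}")
    rows = []
    ss = np.random.SeedSequence(seed)
    for tau in tau_grid:
        for p in p_grid:
            if method == "ema":
                D = ema_diffusion(p, tau, lambda_dif, d)
                rows.append((p, tau, "ema", D, np.nan))
            else:
                cfg = walker_config or WalkerConfig(lambda_dif=lambda_dif)
                sub = ss.spawn(1)[0]
                cfg_i = WalkerConfig(
                    lambda_dif=cfg.lambda_dif,
                    n_walkers=cfg.n_walkers,
                    t_max=cfg.t_max,
                    record_times=cfg.record_times.copy(),
                    seed=int(sub.generate_state(1)[0]),
                    fresh_lattice_per_walker=cfg.fresh_lattice_per_walker,
                )
                lat = make_lattice(
                    L, d=d, p=float(p), tau=float(tau), boundary="periodic"
                )
                curve = simulate_walkers(lat, cfg_i)
                est = estimate_D(curve)
                rows.append((p, tau, "sim", est.D_app, _slope_se(curve, est)))
    return pd.DataFrame(rows, columns=["p", "tau", "method", "D", "stderr"])


def _slope_se(curve: MSDCurve, est: DiffusionEstimate) -> float:
    """Rough standard error of D from the per-time MSD standard errors."""
    mask = (curve.times >= est.fit_window[0]) & (curve.times <= est.fit_window[1])
    t = curve.times[mask]
    se = curve.stderr[mask]
    span = t.max() - t.min()
    if span <= 0:
        return float("nan")
    # slope uncertainty ~ typical point SE / span, reduced by sqrt(n points)
    return float(np.median(se) / span / math.sqrt(mask.sum()) / (2 * curve.d))


def kiss_and_run_range(D_protein: float, t_contact: float, d: int = 3) -> float:
    """Root-mean-squared displacement sqrt(2 d D t) during a transient contact.

    Back-of-the-envelope reach of a matrix protein during a brief
    fusion ("kiss and run") event: with D ~ 20 um^2/s and a 45 s
    contact, sqrt(6 * 20 * 45) ~ 73.5 um, ample for matrix content
    mixing at cellular scales.  Physical units in, physical units out.
    """
    if D_protein < 0 or t_contact <= 0:
        raise ValueError("need D_protein >= 0 and t_contact > 0")
    if d not in (1, 2, 3):
        raise ValueError("d must be 1, 2 or 3")
    return math.sqrt(2.0 * d * D_protein * t_contact)
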