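"""Blind-surveillance quality control of a mitochondrial population.

Four population fractions evolve in time: healthy or dysfunctional units
that are either fragmented (isolated) or part of the fused network,

    (h_f, h_n, d_f, d_n),  h_f + h_n + d_f + d_n = 1.

The model encodes three mechanisms:

* **blind fission** at rate ``lambda_fis``, identical for healthy and
  dysfunctional units;
* **selective fusion**: healthy fragments fuse into the network at rate
  ``lambda_fus``, dysfunctional ones at ``s * lambda_fus`` with
  selectivity ``s`` in [0, 1] (s < 1 means a functional unit is more
  likely to fuse);
* **size-selective but function-blind mitophagy** at rate ``mu``: only
  fragmented units can be degraded, healthy and dysfunctional alike.

Damage converts healthy to dysfunctional units at rate ``delta``;
biogenesis replaces every degraded unit with a fresh healthy fragment,
so the total is exactly conserved.  Because dysfunctional units linger
in the fragmented pool (they fuse more slowly), the fragment pool is
enriched for dysfunction and even blind mitophagy removes dysfunctional
units preferentially — increasing the (healthy) fusion rate raises the
steady-state healthy fraction h* = h_f + h_n whenever s < 1, while at
s = 1 (no selection) h* is independent of the fusion rate.

By default damage acts on fragmented units only (``damage="fragmented"``);
this is the variant in which fusion confers a pure surveillance benefit
and selection-free fusion (s = 1) confers none.  ``damage="both"`` or
``"network"`` let damage strike networked units too, in which case
networking additionally shelters dysfunctional units from mitophagy and
the fusion benefit is partly offset (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = ["QCParams", "QCState", "qc_rhs", "qc_steady_state", "sweep_fusion"]

_DAMAGE_MODES = ("fragmented", "network", "both")
_BIOGENESIS_MODES = ("healthy", "proportional")


@dataclass(frozen=True)
class QCParams:
    lambda_fus: float = 1.0
    s: float = 0.2
    lambda_fis: float = 0.5
    mu: float = 0.3
    delta: float = 0.05
    damage: str = "fragmented"
    biogenesis: str = "healthy"

    def __post_init__(self):
        for name in ("lambda_fus", "lambda_fis", "mu", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"selectivity s must lie in [0, 1], got {self.s}")
        if self.damage not in _DAMAGE_MODES:
            raise ValueError(f"damage must be one of {_DAMAGE_MODES}")
        if self.biogenesis not in _BIOGENESIS_MODES:
            raise ValueError(f"biogenesis must be one of {_BIOGENESIS_MODES}")


@dataclass(frozen=True)
class QCState:
    h_f: float
    h_n: float
    d_f: float
    d_n: float

    def as_array(self) -> np.ndarray:
        return np.array([self.h_f, self.h_n, self.d_f, self.d_n])

    @property
    def healthy_fraction(self) -> float:
        return self.h_f + self.h_n

    @property
    def d_frag_share(self) -> float:
        """Dysfunctional share of the fragmented pool."""
        tot = self.h_f + self.d_f
        return self.d_f / tot if tot > 0 else float("nan")

    @property
    def d_net_share(self) -> float:
        """Dysfunctional share of the networked pool."""
        tot = self.h_n + self.d_n
        return self.d_n / tot if tot > 0 else float("nan")


def _rate_matrix(params: QCParams) -> np.ndarray:
    """Linear generator A with d/dt (h_f, h_n, d_f, d_n) = A x."""
    lf, s, lx, mu, de = (
        params.lambda_fus,
        params.s,
        params.lambda_fis,
        params.mu,
        params.delta,
    )
    de_f = de if params.damage in ("fragmented", "both") else 0.0
    de_n = de if params.damage in ("network", "both") else 0.0
    A = np.zeros((4, 4))
    # fusion / fission exchange
    A[0, 0] -= lf
    A[1, 0] += lf
    A[1, 1] -= lx
    A[0, 1] += lx
    A[2, 2] -= s * lf
    A[3, 2] += s * lf
    A[3, 3] -= lx
    A[2, 3] += lx
    # damage
    A[0, 0] -= de_f
    A[2, 0] += de_f
    A[1, 1] -= de_n
    A[3, 1] += de_n
    # mitophagy of fragments
    A[0, 0] -= mu
    A[2, 2] -= mu
    # compensating biogenesis
    if params.biogenesis == "healthy":
        A[0, 0] += mu
        A[0, 2] += mu
    else:  # proportional replacement
        A[0, 0] += mu
        A[2, 2] += mu
    return A


def qc_rhs(state, params: QCParams) -> np.ndarray:
    """Time derivative of (h_f, h_n, d_f, d_n); components sum to zero."""
    x = state.as_array() if isinstance(state, QCState) else np.asarray(state, float)
    if x.shape != (4,):
        raise ValueError("state must have four components (h_f, h_n, d_f, d_n)")
    if np.any(x < 0):
        raise ValueError("state fractions must be non-negative")
    return _rate_matrix(params) @ x


def qc_steady_state(
    params: QCParams,
    method: str = "linear",
    x0=None,
    t_final: float = 2000.0,
    tol: float = 1e-10,
) -> QCState:
    """Steady state on the simplex.

    The dynamics are linear, so the default route solves the null-space
    problem A x = 0, sum(x) = 1 directly.  ``method="ode"`` integrates
    the system to a long horizon instead (used as an independent
    cross-check, and as a fallback whenever the null space is
    degenerate, e.g. lambda_fis = 0 with a trapped networked pool).
    Requires mu > 0 or delta = 0; with damage but no mitophagy the
    dysfunctional pool is absorbing and no healthy steady state exists.
    """
    if params.mu == 0 and params.delta > 0:
        raise ValueError(
            "no steady state with a healthy fraction: delta > 0 but mu = 0 "
            "(damage without removal is absorbing)"
        )
    A = _rate_matrix(params)
    if method == "ode":
        return _steady_by_integration(A, x0, t_final, tol)
    if method != "linear":
        raise ValueError("method must be 'linear' or 'ode'")
    _, sing, vt = np.linalg.svd(A)
    null_dim = int(np.sum(sing < 1e-12 * max(1.0, sing[0])))
    if null_dim != 1:
        return _steady_by_integration(A, x0, t_final, tol)
    v = vt[-1]
    total = v.sum()
    if abs(total) < 1e-12:
        return _steady_by_integration(A, x0, t_final, tol)
    x = v / total
    if np.any(x < -1e-9):
        return _steady_by_integration(A, x0, t_final, tol)
    x = np.clip(x, 0.0, None)
    x = x / x.sum()
    resid = float(np.max(np.abs(A @ x)))
    if resid > 1e-8:
        raise RuntimeError(f"steady-state residual {resid:.2e} above tolerance")
    return QCState(*x)


def _steady_by_integration(A, x0, t_final, tol) -> QCState:
    if x0 is None:
        x0 = np.full(4, 0.25)
    x0 = np.asarray(x0, float)
    sol = solve_ivp(
        lambda t, x: A @ x,
        (0.0, t_final),
        x0,
        method="LSODA",
        rtol=1e-12,
        atol=1e-14,
    )
    x = sol.y[:, -1]
    if float(np.max(np.abs(A @ x))) > max(tol, 1e-9):
        raise RuntimeError("integration did not reach a steady state; increase t_final")
    x = np.clip(x, 0.0, None)
    return QCState(*(x / x.sum()))


def sweep_fusion(params: QCParams, lambda_fus_grid) -> pd.DataFrame:
    """Steady-state healthy fraction along a fusion-rate grid.

    Columns: lambda_fus, s, mu, delta, h_star, d_frag_share,
    d_net_share.  With s < 1 and delta, mu > 0 the healthy fraction h*
    is non-decreasing in lambda_fus; at s = 1 the profile is flat.
    """
    grid = np.asarray(lambda_fus_grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("lambda_fus_grid must be non-empty and increasing")
    rows = []
    for lf in grid:
        st = qc_steady_state(replace(params, lambda_fus=float(lf)))
        rows.append(
            {
                "lambda_fus": lf,
                "s": params.s,
                "mu": params.mu,
                "delta": params.delta,
                "h_star": st.healthy_fraction,
                "d_frag_share": st.d_frag_share,
                "d_net_share": st.d_net_share,
            }
        )
    return pd.DataFrame(rows)
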