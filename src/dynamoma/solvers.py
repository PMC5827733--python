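"""Linear- and quadratic-programming primitives for flux problems.

All linear programs (feasibility, flux variability, L1 flux-sum
minimization) are delegated to HiGHS through :func:`scipy.optimize.linprog`.

The strictly convex quadratic program at the heart of the MOMA step,

    min ½ ‖v − v_ref‖²   s.t.   S·v = 0,   lb ≤ v ≤ ub,

is solved by a dense primal active-set method: starting from a feasible
point, the equality-constrained subproblem for the current working set of
bound constraints is solved through its KKT normal equations, blocking
bounds are added on the line search, and bounds with negative Lagrange
multipliers are released until the KKT conditions hold.  Problem sizes
here are small (tens to a few hundred reactions), so dense linear algebra
is both simple and fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.optimize import linprog

_LP_OPTS = {"presolve": True}


class LPInfeasibleError(RuntimeError):
    """An LP (feasibility / FVA / L1 minimization) has no solution."""


class QPError(RuntimeError):
    """The active-set QP failed to converge."""


# ---------------------------------------------------------------------------
# LP helpers


def _bounds_list(lb: np.ndarray, ub: np.ndarray) -> list[tuple[float, float]]:
    return list(zip(lb.tolist(), ub.tolist()))


def feasible_point(S: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray | None:
    """Any v with S·v = 0 and lb ≤ v ≤ ub, or None if infeasible."""
    n = S.shape[1]
    res = linprog(
        c=np.zeros(n),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=_bounds_list(lb, ub),
        method="highs",
        options=_LP_OPTS,
    )
    return res.x if res.status == 0 else None


def optimize_flux(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray,
    maximize: bool = False,
) -> tuple[float, np.ndarray]:
    """min (or max) cᵀv subject to S·v = 0 and bounds."""
    res = linprog(
        c=-c if maximize else c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=_bounds_list(lb, ub),
        method="highs",
        options=_LP_OPTS,
    )
    if res.status != 0:
        raise LPInfeasibleError(f"LP failed with status {res.status}: {res.message}")
    return (-res.fun if maximize else res.fun), res.x


def fva(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, indices: list[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Flux variability analysis: per-reaction (min, max) flux."""
    n = S.shape[1]
    if indices is None:
        indices = list(range(n))
    vmin = np.zeros(len(indices))
    vmax = np.zeros(len(indices))
    for k, j in enumerate(indices):
        c = np.zeros(n)
        c[j] = 1.0
        vmin[k], _ = optimize_flux(S, lb, ub, c)
        vmax[k], _ = optimize_flux(S, lb, ub, c, maximize=True)
    return vmin, vmax


def minimize_l1(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    weight_indices: list[int],
) -> np.ndarray:
    """min Σ_{j∈weight_indices} |v_j| s.t. S·v = 0 and bounds.

    Implemented with auxiliary variables t_j ≥ ±v_j.
    """
    m, n = S.shape
    k = len(weight_indices)
    # variables: [v (n), t (k)]
    c = np.concatenate([np.zeros(n), np.ones(k)])
    A_eq = np.hstack([S, np.zeros((m, k))])
    b_eq = np.zeros(m)
    # t_j >= v_j  ->  v_j - t_j <= 0 ;  t_j >= -v_j  ->  -v_j - t_j <= 0
    A_ub = np.zeros((2 * k, n + k))
    for row, j in enumerate(weight_indices):
        A_ub[2 * row, j] = 1.0
        A_ub[2 * row, n + row] = -1.0
        A_ub[2 * row + 1, j] = -1.0
        A_ub[2 * row + 1, n + row] = -1.0
    b_ub = np.zeros(2 * k)
    t_hi = max(np.max(np.abs(lb)), np.max(np.abs(ub)))
    bounds = _bounds_list(lb, ub) + [(0.0, t_hi)] * k
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs", options=_LP_OPTS,
    )
    if res.status != 0:
        raise LPInfeasibleError(f"L1 minimization failed: {res.message}")
    return res.x[:n]


def diagnose_infeasibility(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    metabolite_ids: list[str],
    reaction_ids: list[str],
) -> str:
    """Describe which metabolite balances need relaxing for feasibility.

    Solves a slack LP (S·v + s⁺ − s⁻ = 0, minimize Σ slack) and names the
    metabolites with non-zero slack — a compact stand-in for an
    irreducible infeasible subsystem.
    """
    m, n = S.shape
    A_eq = np.hstack([S, np.eye(m), -np.eye(m)])
    b_eq = np.zeros(m)
    c = np.concatenate([np.zeros(n), np.ones(2 * m)])
    bounds = _bounds_list(lb, ub) + [(0.0, None)] * (2 * m)
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs", options=_LP_OPTS)
    if res.status != 0 or res.fun is None:
        return "infeasible (bound conflict; no balance relaxation found)"
    slack = res.x[n:n + m] + res.x[n + m:]
    bad = [metabolite_ids[i] for i in np.nonzero(slack > 1e-9)[0]]
    if not bad:
        return "infeasible (cause not localized)"
    return "conflicting metabolite balances: " + ", ".join(sorted(bad))


# ---------------------------------------------------------------------------
# quadratic program


@dataclass
class QPResult:
    x: np.ndarray
    iterations: int
    kkt_residual: float
    active_bounds: list[int] = field(default_factory=list)


def _subproblem(
    S: np.ndarray,
    v_ref: np.ndarray,
    fixed: dict[int, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Solve min ‖v − v_ref‖² s.t. S·v = 0 and v_j fixed for j in `fixed`.

    Returns (v, lam) where lam are the equality multipliers in the
    convention grad + Sᵀ·lam = 0 on the free variables.
    """
    n = S.shape[1]
    free = np.array([j for j in range(n) if j not in fixed], dtype=int)
    v = np.zeros(n)
    d = np.zeros(S.shape[0])
    for j, val in fixed.items():
        v[j] = val
        d -= S[:, j] * val
    Sf = S[:, free]
    rf = v_ref[free]
    # v_f = r_f + Sfᵀ·mu with (Sf Sfᵀ)·mu = d − Sf·r_f
    rhs = d - Sf @ rf
    mu, *_ = linalg.lstsq(Sf @ Sf.T, rhs, lapack_driver="gelsd")
    v[free] = rf + Sf.T @ mu
    return v, -mu


def solve_box_qp(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    v_ref: np.ndarray,
    x0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int | None = None,
) -> QPResult:
    """Primal active-set solve of min ‖v − v_ref‖² s.t. S·v=0, lb ≤ v ≤ ub.

    ``x0`` must be feasible if given; otherwise a phase-I LP finds a
    start.  Raises :class:`LPInfeasibleError` when no feasible point
    exists and :class:`QPError` on convergence failure.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[1]
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    pinned = {j for j in range(n) if ub[j] - lb[j] <= tol}

    if x0 is None:
        x0 = feasible_point(S, lb, ub)
        if x0 is None:
            raise LPInfeasibleError("QP constraints are infeasible")
    x = np.clip(np.asarray(x0, dtype=float), lb, ub)

    # working set: j -> bound value ("lo" or "hi" tracked by value)
    work: dict[int, float] = {j: lb[j] for j in pinned}
    feas_tol = 1e-9
    for j in range(n):
        if j in pinned:
            continue
        if x[j] - lb[j] <= feas_tol:
            work[j] = lb[j]
        elif ub[j] - x[j] <= feas_tol:
            work[j] = ub[j]

    if max_iter is None:
        max_iter = 100 + 20 * n

    for it in range(max_iter):
        target, lam = _subproblem(S, v_ref, work)
        p = target - x
        step = float(np.max(np.abs(p)))
        if step > tol:
            # line search against the inactive bounds
            alpha = 1.0
            blocker = -1
            blocker_val = 0.0
            for j in range(n):
                if j in work:
                    continue
                if p[j] > tol:
                    a = (ub[j] - x[j]) / p[j]
                    if a < alpha - 1e-15:
                        alpha, blocker, blocker_val = a, j, ub[j]
                elif p[j] < -tol:
                    a = (lb[j] - x[j]) / p[j]
                    if a < alpha - 1e-15:
                        alpha, blocker, blocker_val = a, j, lb[j]
            if alpha >= 1.0:
                x = target
            else:
                x = x + max(alpha, 0.0) * p
                work[blocker] = blocker_val
                x[blocker] = blocker_val
                continue
        # at the working-set optimum: check bound multipliers
        grad = x - v_ref
        st_lam = S.T @ lam
        worst = None
        worst_violation = tol
        for j, val in work.items():
            if j in pinned:
                continue
            mu = grad[j] + st_lam[j]
            # at a lower bound, mu must be >= 0; at an upper, <= 0
            violation = -mu if val == lb[j] else mu
            if violation > worst_violation:
                worst_violation = violation
                worst = j
        if worst is None:
            kkt = float(np.max(np.abs(S @ x))) if S.size else 0.0
            return QPResult(
                x=x,
                iterations=it + 1,
                kkt_residual=kkt,
                active_bounds=sorted(j for j in work if j not in pinned),
            )
        del work[worst]
    raise QPError(f"active-set QP did not converge in {max_iter} iterations")
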