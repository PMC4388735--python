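"""Exact-arithmetic linear and mixed-integer optimization primitives.

The LP path is a self-contained two-phase primal simplex over
:class:`fractions.Fraction` with Bland's anti-cycling rule: on rational input
it returns fluxes satisfying every constraint with zero residual, and the
returned solution is always a basic feasible solution (a vertex of the
feasible set). Problem sizes in scope (toy network, flux modules, small
random fixtures) are far below anything that needs a floating-point fast
path.

The MILP path (used for pathway-length minimization) delegates the
branch-and-bound to HiGHS via :func:`scipy.optimize.milp` and then certifies
the witness exactly: the support selected by the integer solution is fixed,
the remaining fluxes are re-solved with the exact LP, and the active count
is recomputed from the exact solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np

from ._rational import Bound
from .netmodel import FluxVector, StoichModel

__all__ = [
    "LPResult",
    "FBASolution",
    "FVAResult",
    "solve_exact_lp",
    "solve_model_lp",
    "solve_fba",
    "fva",
    "solve_milp",
]

_ZERO = Fraction(0)
_ONE = Fraction(1)


# ----------------------------------------------------------------------
# Standard-form exact simplex
# ----------------------------------------------------------------------

@dataclass
class LPResult:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective: Optional[Fraction] = None
    x: Optional[list[Fraction]] = None
    ray: Optional[list[Fraction]] = None  # recession direction if unbounded


def _reduced_cost(T, basis, cost, j, m):
    rc = cost[j]
    for i in range(m):
        cb = cost[basis[i]]
        if cb != 0 and T[i][j] != 0:
            rc -= cb * T[i][j]
    return rc


def _pivot(T, basis, i, j):
    row = T[i]
    piv = row[j]
    if piv != 1:
        T[i] = row = [v / piv for v in row]
    for k, other in enumerate(T):
        if k != i and other[j] != 0:
            f = other[j]
            T[k] = [a - f * b for a, b in zip(other, row)]
    basis[i] = j


def _optimize(T, basis, cost, allowed, m, rhs_col):
    """Bland-rule simplex on tableau T (rows = B^-1 A | B^-1 b)."""
    while True:
        enter = -1
        for j in allowed:
            if _reduced_cost(T, basis, cost, j, m) < 0:
                enter = j
                break
        if enter < 0:
            return "optimal", None
        leave = -1
        best = None
        for i in range(m):
            a = T[i][enter]
            if a > 0:
                ratio = T[i][rhs_col] / a
                if best is None or ratio < best or (
                    ratio == best and basis[i] < basis[leave]
                ):
                    best = ratio
                    leave = i
        if leave < 0:
            return "unbounded", enter
        _pivot(T, basis, leave, enter)


def _simplex_standard(A, b, c):
    """min c.x  s.t.  A x = b, x >= 0, exact. Returns LPResult in x-space."""
    m = len(A)
    n = len(c)
    T = []
    for i in range(m):
        bi = b[i]
        row = list(A[i])
        if bi < 0:
            bi = -bi
            row = [-v for v in row]
        T.append(row + [_ZERO] * m + [bi])
    for i in range(m):
        T[i][n + i] = _ONE
    basis = list(range(n, n + m))
    rhs_col = n + m

    # phase 1: minimize the sum of artificials
    cost1 = [_ZERO] * n + [_ONE] * m
    _optimize(T, basis, cost1, range(n + m), m, rhs_col)
    art_obj = sum(cost1[basis[i]] * T[i][rhs_col] for i in range(m))
    if art_obj != 0:
        return LPResult(status="infeasible")
    # drive remaining artificials out of the basis; drop redundant rows
    drop = []
    for i in range(m):
        if basis[i] >= n:
            for j in range(n):
                if T[i][j] != 0:
                    _pivot(T, basis, i, j)
                    break
            else:
                drop.append(i)
    if drop:
        for i in reversed(drop):
            del T[i]
            del basis[i]
        m = len(T)

    # phase 2
    cost2 = list(c) + [_ZERO] * (rhs_col - n)
    status, enter = _optimize(T, basis, cost2, range(n), m, rhs_col)
    if status == "unbounded":
        ray = [_ZERO] * n
        ray[enter] = _ONE
        for i in range(m):
            if basis[i] < n:
                ray[basis[i]] = -T[i][enter]
        return LPResult(status="unbounded", ray=ray)
    x = [_ZERO] * n
    for i in range(m):
        if basis[i] < n:
            x[basis[i]] = T[i][rhs_col]
    obj = sum(ci * xi for ci, xi in zip(c, x) if ci != 0) or _ZERO
    return LPResult(status="optimal", objective=obj, x=x)


def solve_exact_lp(
    c: Sequence[Fraction],
    A: Sequence[Sequence[Fraction]],
    b: Sequence[Fraction],
    lb: Sequence[Bound],
    ub: Sequence[Bound],
    sense: str = "min",
) -> LPResult:
    """Exact LP: optimize c.x subject to A x = b and lb <= x <= ub.

    ``None`` bounds mean unbounded in that direction. Returns a basic
    optimal solution, an infeasibility verdict, or an unboundedness
    certificate (a recession direction improving the objective).
    """
    if sense not in ("min", "max"):
        raise ValueError("sense must be 'min' or 'max'")
    n = len(c)
    m = len(A)
    cc = [(-ci if sense == "max" else ci) for ci in c]

    cols: list[list[Fraction]] = []
    costs: list[Fraction] = []
    # recover[k] = (orig index, sign, offset-term) for standard var k
    recover: list[tuple[int, int, Fraction]] = []
    bb = list(b)
    extra_rows: list[tuple[int, Fraction]] = []  # (std var index, rhs) for u <= cap

    for j in range(n):
        col = [A[i][j] for i in range(m)]
        lo, hi = lb[j], ub[j]
        if lo is not None:
            if lo != 0:
                for i in range(m):
                    bb[i] -= col[i] * lo
            cols.append(col)
            costs.append(cc[j])
            recover.append((j, +1, lo))
            if hi is not None:
                extra_rows.append((len(cols) - 1, hi - lo))
        elif hi is not None:
            # x = hi - u, u >= 0
            if hi != 0:
                for i in range(m):
                    bb[i] -= col[i] * hi
            cols.append([-v for v in col])
            costs.append(-cc[j])
            recover.append((j, -1, hi))
        else:
            cols.append(col)
            costs.append(cc[j])
            recover.append((j, +1, _ZERO))
            cols.append([-v for v in col])
            costs.append(-cc[j])
            recover.append((j, -1, _ZERO))

    n_std = len(cols)
    n_total = n_std + len(extra_rows)
    rows = [[cols[k][i] for k in range(n_std)] + [_ZERO] * len(extra_rows)
            for i in range(m)]
    rhs = list(bb)
    for e, (k, cap) in enumerate(extra_rows):
        row = [_ZERO] * n_total
        row[k] = _ONE
        row[n_std + e] = _ONE  # slack
        rows.append(row)
        rhs.append(cap)
    costs = costs + [_ZERO] * len(extra_rows)

    res = _simplex_standard(rows, rhs, costs)
    if res.status == "infeasible":
        return res
    if res.status == "unbounded":
        ray = [_ZERO] * n
        for k, (j, sign, _off) in enumerate(recover):
            ray[j] += sign * res.ray[k]
        return LPResult(status="unbounded", ray=ray)
    x = [_ZERO] * n
    seen_offset = [False] * n
    for k, (j, sign, off) in enumerate(recover):
        if not seen_offset[j]:
            x[j] += off
            seen_offset[j] = True
        elif sign == -1 and off != 0:  # free var: only one offset (both zero)
            pass
        x[j] += sign * res.x[k]
    obj = sum(ci * xi for ci, xi in zip(c, x) if ci != 0) or _ZERO
    return LPResult(status="optimal", objective=obj, x=x)


# ----------------------------------------------------------------------
# Model-level LP helpers
# ----------------------------------------------------------------------

def _model_system(
    model: StoichModel,
    equalities: Sequence[tuple[Mapping[str, Fraction], Fraction]] = (),
):
    """Rows of N (internal species) plus extra equality rows, with bounds."""
    _, rids, n_mat = model.stoich_matrix()
    col_of = {rid: j for j, rid in enumerate(rids)}
    A = [list(row) for row in n_mat]
    b = [_ZERO] * len(A)
    for coeffs, rhs in equalities:
        row = [_ZERO] * len(rids)
        for rid, v in coeffs.items():
            if rid not in col_of:
                raise KeyError(f"unknown reaction id {rid!r} in equality row")
            row[col_of[rid]] += v
        A.append(row)
        b.append(rhs)
    lb = [r.lower_bound for r in model.reactions]
    ub = [r.upper_bound for r in model.reactions]
    return rids, A, b, lb, ub


def solve_model_lp(
    model: StoichModel,
    objective: Mapping[str, Fraction],
    sense: str = "max",
    equalities: Sequence[tuple[Mapping[str, Fraction], Fraction]] = (),
    bound_overrides: Mapping[str, tuple[Bound, Bound]] | None = None,
) -> LPResult:
    """Optimize an arbitrary linear functional of the fluxes over the model.

    ``equalities`` are extra rows (coefficient dict, rhs) appended to the
    steady-state system — e.g. fixing the primary objective at its optimum.
    """
    rids, A, b, lb, ub = _model_system(model, equalities)
    if bound_overrides:
        for rid, (lo, hi) in bound_overrides.items():
            j = rids.index(rid)
            lb[j], ub[j] = lo, hi
    c = [objective.get(rid, _ZERO) for rid in rids]
    return solve_exact_lp(c, A, b, lb, ub, sense=sense)


# ----------------------------------------------------------------------
# FBA / FVA
# ----------------------------------------------------------------------

@dataclass
class FBASolution:
    status: str
    objective_value: Optional[Fraction] = None
    flux: Optional[FluxVector] = None
    ray: Optional[FluxVector] = None  # certificate when unbounded


@dataclass
class FVAResult:
    """Per-reaction exact flux range with the objective fixed.

    ``None`` endpoints mean the flux is unbounded in that direction.
    """

    ranges: dict[str, tuple[Bound, Bound]]

    def __getitem__(self, rid: str) -> tuple[Bound, Bound]:
        return self.ranges[rid]

    def width_nonzero(self, rid: str) -> bool:
        lo, hi = self.ranges[rid]
        return lo is None or hi is None or lo != hi


def solve_fba(
    model: StoichModel,
    sense: str = "max",
    objective: Mapping[str, Fraction] | None = None,
) -> FBASolution:
    """Flux balance analysis: optimize c.J subject to N.J = 0 and bounds."""
    if objective is None:
        objective = {r.id: r.objective_coeff for r in model.reactions
                     if r.objective_coeff != 0}
    if not objective:
        raise ValueError("model has no objective coefficient; supply one")
    res = solve_model_lp(model, objective, sense=sense)
    rids = model.reaction_ids()
    if res.status == "optimal":
        return FBASolution(
            status="optimal",
            objective_value=res.objective,
            flux=FluxVector(dict(zip(rids, res.x))),
        )
    if res.status == "unbounded":
        return FBASolution(status="unbounded",
                           ray=FluxVector(dict(zip(rids, res.ray))))
    return FBASolution(status="infeasible")


def fva(
    model: StoichModel,
    fix_objective_at: Fraction,
    reactions: Sequence[str] | None = None,
    objective: Mapping[str, Fraction] | None = None,
) -> FVAResult:
    """Exact flux variability analysis at a fixed objective value."""
    if objective is None:
        objective = {r.id: r.objective_coeff for r in model.reactions
                     if r.objective_coeff != 0}
    equalities = [(dict(objective), fix_objective_at)]
    rids, A, b, lb, ub = _model_system(model, equalities)
    targets = list(reactions) if reactions is not None else rids
    ranges: dict[str, tuple[Bound, Bound]] = {}
    col = {rid: j for j, rid in enumerate(rids)}
    for rid in targets:
        c = [_ZERO] * len(rids)
        c[col[rid]] = _ONE
        endpoints = []
        for sense in ("min", "max"):
            res = solve_exact_lp(c, A, b, lb, ub, sense=sense)
            if res.status == "infeasible":
                raise ValueError(
                    f"objective value {fix_objective_at} is not attainable"
                )
            endpoints.append(None if res.status == "unbounded"
                             else res.x[col[rid]])
        ranges[rid] = (endpoints[0], endpoints[1])
    return FVAResult(ranges)


# ----------------------------------------------------------------------
# MILP (activity-indicator minimization)
# ----------------------------------------------------------------------

def solve_milp(
    model: StoichModel,
    indicator_spec: Mapping[str, tuple[Bound, Bound]],
    fix_objective_at: Fraction,
    objective: Mapping[str, Fraction] | None = None,
) -> tuple[int, FluxVector]:
    """Minimize the number of active reactions at a fixed primary optimum.

    ``indicator_spec`` maps each counted reaction to the (negative, positive)
    activity bounds M used to link |J_j| <= M_j y_j with binary y_j; both
    must be finite. Returns the minimal active count together with an
    exactly certified witness flux: the integer solution's support is fixed
    and re-solved with the exact LP, and the count is recomputed from that
    exact flux.
    """
    from scipy.optimize import LinearConstraint, milp

    if objective is None:
        objective = {r.id: r.objective_coeff for r in model.reactions
                     if r.objective_coeff != 0}
    rids, A, b, lb, ub = _model_system(model, [(dict(objective), fix_objective_at)])
    col = {rid: j for j, rid in enumerate(rids)}
    n = len(rids)
    counted = list(indicator_spec)
    for rid in counted:
        neg, pos = indicator_spec[rid]
        if neg is None or pos is None:
            raise ValueError(
                f"no finite activity bound for {rid!r}; supply explicit bounds"
            )
    k = len(counted)

    def f(x: Bound, sign: int) -> float:
        return float(x) if x is not None else sign * np.inf

    # variables: J (n) then y (k)
    c_vec = np.concatenate([np.zeros(n), np.ones(k)])
    a_eq = np.zeros((len(A), n + k))
    for i, row in enumerate(A):
        for j, v in enumerate(row):
            if v != 0:
                a_eq[i, j] = float(v)
    constraints = [LinearConstraint(a_eq, [float(x) for x in b], [float(x) for x in b])]
    a_ind = np.zeros((2 * k, n + k))
    lo_ind = np.full(2 * k, -np.inf)
    hi_ind = np.zeros(2 * k)
    for t, rid in enumerate(counted):
        j = col[rid]
        neg, pos = indicator_spec[rid]
        a_ind[2 * t, j] = 1.0          # J_j - pos*y_j <= 0
        a_ind[2 * t, n + t] = -float(pos)
        a_ind[2 * t + 1, j] = -1.0     # -J_j + neg*y_j <= 0  (J_j >= neg*y_j)
        a_ind[2 * t + 1, n + t] = float(neg) if neg is not None else 0.0
    constraints.append(LinearConstraint(a_ind, lo_ind, hi_ind))
    from scipy.optimize import Bounds

    lo = np.array([f(x, -1) for x in lb] + [0.0] * k)
    hi = np.array([f(x, +1) for x in ub] + [1.0] * k)
    integrality = np.concatenate([np.zeros(n), np.ones(k)])
    res = milp(c=c_vec, constraints=constraints,
               bounds=Bounds(lo, hi), integrality=integrality)
    if not res.success:
        raise ValueError(f"MILP failed: {res.message}")

    active = {counted[t] for t in range(k) if res.x[n + t] > 0.5}
    # exact certification: force the complement to zero and re-solve exactly
    overrides = {rid: (_ZERO, _ZERO) for rid in counted if rid not in active}
    exact = solve_model_lp(
        model, objective, sense="max",
        equalities=[(dict(objective), fix_objective_at)],
        bound_overrides=overrides,
    )
    if exact.status != "optimal":
        raise RuntimeError(
            "float MILP support could not be certified by the exact LP"
        )
    witness = FluxVector(dict(zip(rids, exact.x)))
    count = sum(1 for rid in counted if witness[rid] != 0)
    return count, witness
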