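"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: vertex
enumeration is re-done by brute force over active bound sets, ranks by a
fresh elimination, supports by recounting.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import pytest

import fluxtope as ft
from fluxtope.polyhedra import _optimal_system, rational_rank, rref


@pytest.fixture(scope="session")
def toy():
    return ft.build_toy_model()


@pytest.fixture(scope="session")
def toy_split(toy):
    return ft.split_reversible(toy)


@pytest.fixture(scope="session")
def z_star(toy):
    sol = ft.solve_fba(toy)
    assert sol.status == "optimal"
    return sol.objective_value


def brute_force_vertices(model, z_star):
    """All basic feasible points of the optimal polyhedron by enumeration.

    Tries every way of pinning variables at a finite bound, keeps the
    combinations whose active constraints have full rank, solves the square
    system exactly, and filters by feasibility.  Only meaningful on pointed
    polyhedra (split models).
    """
    rids, A, b, lb, ub = _optimal_system(model, z_star)
    n = len(rids)
    cands = []
    for j in range(n):
        opts = [None]
        if lb[j] is not None:
            opts.append(lb[j])
        if ub[j] is not None and ub[j] != lb[j]:
            opts.append(ub[j])
        cands.append(opts)
    found = set()
    for combo in itertools.product(*cands):
        rows = [list(r) for r in A]
        rhs = list(b)
        for j, ch in enumerate(combo):
            if ch is not None:
                row = [Fraction(0)] * n
                row[j] = Fraction(1)
                rows.append(row)
                rhs.append(ch)
        if rational_rank(rows) != n:
            continue
        red, piv = rref([r + [v] for r, v in zip(rows, rhs)])
        if n in piv:
            continue  # inconsistent
        x = [Fraction(0)] * n
        for row, p in zip(red, piv):
            x[p] = row[-1]
        if not all(
            (lb[j] is None or x[j] >= lb[j])
            and (ub[j] is None or x[j] <= ub[j])
            for j in range(n)
        ):
            continue
        if all(sum(a * xx for a, xx in zip(row, x)) == v
               for row, v in zip(A, b)):
            found.add(tuple(x))
    return found


def models_equal(a, b) -> bool:
    """Structural model equality (ids, stoichiometry, bounds, flags)."""
    if [(s.id, s.is_boundary) for s in a.species] != \
       [(s.id, s.is_boundary) for s in b.species]:
        return False
    if len(a.reactions) != len(b.reactions):
        return False
    for ra, rb in zip(a.reactions, b.reactions):
        if (ra.id, ra.reversible, ra.lower_bound, ra.upper_bound,
                ra.objective_coeff, ra.gpr) != \
           (rb.id, rb.reversible, rb.lower_bound, rb.upper_bound,
                rb.objective_coeff, rb.gpr):
            return False
        if dict(ra.stoichiometry) != dict(rb.stoichiometry):
            return False
    return True


@pytest.fixture(scope="session")
def oracle_vertices():
    return brute_force_vertices


@pytest.fixture(scope="session")
def model_equality():
    return models_equal
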