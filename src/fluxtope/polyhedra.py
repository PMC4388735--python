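"""Exact polyhedral computations on the optimal solution space.

The optimal solution space of a flux balance problem is a (possibly
unbounded) polyhedron.  Every optimal flux J* can be written as a Minkowski
sum: a convex combination of vertices, plus a conical combination of extreme
rays, plus a linear combination of lineality directions,

    J* = sum_k alpha_k v_k + sum_k beta_k r_k + sum_k gamma_k l_k,

with sum(alpha) = 1, alpha >= 0, beta >= 0 and gamma free.  Linealities
(two-sided unbounded directions) exist only while reversible reactions are
kept intact; after splitting, the polyhedron is pointed up to nothing.

Generators are computed with an exact double description method over
rationals: the homogenized constraint system is intersected with one
halfspace at a time while a minimal set of extreme rays (and a lineality
basis) is maintained; adjacency of rays is decided combinatorially from
their tight constraint sets.  Everything is tolerance-free.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator, Mapping, Optional, Sequence

from ._rational import Bound, canonical_sign, primitive
from .netmodel import FluxVector, StoichModel

__all__ = [
    "Vertex",
    "Ray",
    "Lineality",
    "OptimalSpace",
    "double_description",
    "polyhedron_generators",
    "enumerate_vertices",
    "enumerate_rays",
    "lineality_space",
    "build_optimal_space",
    "count_vertices",
    "reconstruct_vertex",
    "iter_reconstructed_vertices",
    "decompose_in_space",
]

_ZERO = Fraction(0)
_ONE = Fraction(1)

Vec = list


# ----------------------------------------------------------------------
# Exact linear algebra helpers
# ----------------------------------------------------------------------

def _dot(a: Vec, b: Vec) -> Fraction:
    return sum((x * y for x, y in zip(a, b) if x != 0 and y != 0), _ZERO)


def rref(rows: Sequence[Sequence[Fraction]]) -> tuple[list[Vec], list[int]]:
    """Reduced row echelon form; returns (nonzero rows, pivot columns)."""
    mat = [list(r) for r in rows]
    if not mat:
        return [], []
    ncols = len(mat[0])
    pivots: list[int] = []
    r = 0
    for c in range(ncols):
        piv = next((i for i in range(r, len(mat)) if mat[i][c] != 0), None)
        if piv is None:
            continue
        mat[r], mat[piv] = mat[piv], mat[r]
        inv = mat[r][c]
        if inv != 1:
            mat[r] = [v / inv for v in mat[r]]
        for i in range(len(mat)):
            if i != r and mat[i][c] != 0:
                f = mat[i][c]
                mat[i] = [a - f * b for a, b in zip(mat[i], mat[r])]
        pivots.append(c)
        r += 1
        if r == len(mat):
            break
    return mat[:r], pivots


def rational_rank(rows: Sequence[Sequence[Fraction]]) -> int:
    return len(rref(rows)[0])


def nullspace(rows: Sequence[Sequence[Fraction]], dim: int) -> list[Vec]:
    """Basis of {x : rows . x = 0} by back-substitution from the RREF."""
    red, pivots = rref(rows)
    free = [c for c in range(dim) if c not in pivots]
    basis = []
    for f in free:
        v = [_ZERO] * dim
        v[f] = _ONE
        for row, p in zip(red, pivots):
            v[p] = -row[f]
        basis.append(v)
    return basis


# ----------------------------------------------------------------------
# Double description
# ----------------------------------------------------------------------

def double_description(
    equalities: Sequence[Sequence[Fraction]],
    inequalities: Sequence[Sequence[Fraction]],
    dim: int,
) -> tuple[list[Vec], list[Vec]]:
    """Generators of the cone {y : E y = 0, B y >= 0}.

    Returns ``(lineality_basis, extreme_rays)``; the rays are extreme modulo
    the lineality space and scaled to primitive integer vectors.
    """
    L: list[Vec] = nullspace(equalities, dim)
    R: list[Vec] = []
    Z: list[frozenset[int]] = []  # per ray: indices of tight inequalities

    for q, a in enumerate(inequalities):
        # 1. reduce the lineality space if a cuts it
        hit = next(((i, _dot(a, l)) for i, l in enumerate(L)
                    if _dot(a, l) != 0), None)
        if hit is not None:
            i0, s0 = hit
            l0 = L[i0]
            if s0 < 0:
                l0 = [-v for v in l0]
                s0 = -s0
            newL = []
            for i, l in enumerate(L):
                if i == i0:
                    continue
                s = _dot(a, l)
                if s != 0:
                    l = [x - (s / s0) * y for x, y in zip(l, l0)]
                newL.append(l)
            L = newL
            for k in range(len(R)):
                s = _dot(a, R[k])
                if s != 0:
                    R[k] = primitive(
                        [x - (s / s0) * y for x, y in zip(R[k], l0)]
                    )
                Z[k] = Z[k] | {q}
            R.append(primitive(l0))
            Z.append(frozenset(range(q)))
            continue

        # 2. classic double-description step
        svals = [_dot(a, r) for r in R]
        minus = [k for k, s in enumerate(svals) if s < 0]
        if not minus:
            Z = [z | {q} if svals[k] == 0 else z for k, z in enumerate(Z)]
            continue
        plus = [k for k, s in enumerate(svals) if s > 0]
        zero = [k for k, s in enumerate(svals) if s == 0]
        newR = [R[k] for k in plus] + [R[k] for k in zero]
        newZ = [Z[k] for k in plus] + [Z[k] | {q} for k in zero]
        for kp in plus:
            for km in minus:
                common = Z[kp] & Z[km]
                if not _adjacent(common, kp, km, Z):
                    continue
                comb = [svals[kp] * rm - svals[km] * rp
                        for rp, rm in zip(R[kp], R[km])]
                newR.append(primitive(comb))
                newZ.append(common | {q})
        R, Z = newR, newZ
    return L, R


def _adjacent(common: frozenset[int], kp: int, km: int,
              Z: list[frozenset[int]]) -> bool:
    for t, zt in enumerate(Z):
        if t != kp and t != km and common <= zt:
            return False
    return True


# ----------------------------------------------------------------------
# Polyhedron generators in (x, lambda) homogenization
# ----------------------------------------------------------------------

def polyhedron_generators(
    A: Sequence[Sequence[Fraction]],
    b: Sequence[Fraction],
    lb: Sequence[Bound],
    ub: Sequence[Bound],
) -> tuple[list[Vec], list[Vec], list[Vec]]:
    """Vertices, extreme rays, and lineality basis of {A x = b, lb<=x<=ub}.

    Works for unbounded polyhedra; vertices are reported modulo the
    lineality space (canonical representatives with the lineality pivot
    coordinates reduced to zero), matching the convention that a polyhedron
    with lineality has "vertices" standing for its minimal faces.
    """
    n = len(lb)
    dim = n + 1  # homogenization variable lambda last
    eqs = [list(row) + [-bi] for row, bi in zip(A, b)]
    ineqs: list[Vec] = []
    lam = [_ZERO] * n + [_ONE]
    ineqs.append(lam)  # lambda >= 0
    for j in range(n):
        if lb[j] is not None:
            row = [_ZERO] * dim
            row[j] = _ONE
            row[n] = -lb[j]
            ineqs.append(row)  # x_j - lb_j * lambda >= 0
        if ub[j] is not None:
            row = [_ZERO] * dim
            row[j] = -_ONE
            row[n] = ub[j]
            ineqs.append(row)  # ub_j * lambda - x_j >= 0

    L, R = double_description(eqs, ineqs, dim)
    # lineality directions have lambda = 0 automatically (lambda >= 0 holds
    # in both directions); canonicalize rays modulo L for determinism.
    # Pivots are taken on the highest-index coordinates so that vertex
    # representatives concentrate flux on the earliest reactions.
    Lx = [l[:n][::-1] for l in L]
    Lred_rev, pivots_rev = rref(Lx)
    Lred = [row[::-1] for row in Lred_rev]
    pivots = [n - 1 - p for p in pivots_rev]
    lin = [canonical_sign(primitive(l)) for l in Lred]

    def reduce_mod_lineality(vec_x: Vec) -> Vec:
        out = list(vec_x)
        for row, p in zip(Lred, pivots):
            f = out[p]
            if f != 0:
                piv = row[p]
                out = [a - (f / piv) * c for a, c in zip(out, row)]
        return out

    vertices: list[Vec] = []
    rays: list[Vec] = []
    for r in R:
        lam_v = r[n]
        x = reduce_mod_lineality(r[:n])
        if lam_v > 0:
            vertices.append([v / lam_v for v in x])
        else:
            rays.append(primitive(x))
    vertices = _dedupe_sorted(vertices)
    rays = _dedupe_sorted(rays)
    lin.sort(key=tuple)
    return vertices, rays, lin


def _dedupe_sorted(vecs: list[Vec]) -> list[Vec]:
    seen = set()
    out = []
    for v in vecs:
        key = tuple(v)
        if key not in seen:
            seen.add(key)
            out.append(v)
    out.sort(key=lambda v: (tuple(i for i, x in enumerate(v) if x != 0),
                            tuple(v)))
    return out


# ----------------------------------------------------------------------
# Model-facing generator types
# ----------------------------------------------------------------------

@dataclass
class Vertex:
    flux: FluxVector
    module_id: Optional[str] = None  # None = whole-model vertex


@dataclass
class Ray:
    direction: FluxVector
    kind: str = "cycle"  # "split-pair" | "cycle" | "input-output"


@dataclass
class Lineality:
    direction: FluxVector


def _optimal_system(model: StoichModel, fixed_objective: Optional[Fraction]):
    _, rids, n_mat = model.stoich_matrix()
    A = [list(r) for r in n_mat]
    b = [_ZERO] * len(A)
    if fixed_objective is not None:
        c_row = [model.get_reaction(rid).objective_coeff for rid in rids]
        if any(v != 0 for v in c_row):
            A.append(c_row)
            b.append(fixed_objective)
    lb = [r.lower_bound for r in model.reactions]
    ub = [r.upper_bound for r in model.reactions]
    return rids, A, b, lb, ub


def enumerate_vertices(
    model: StoichModel,
    fixed_objective: Optional[Fraction] = None,
    module_id: Optional[str] = None,
) -> list[Vertex]:
    """All extreme points of the (optimal) flux polyhedron, exact."""
    rids, A, b, lb, ub = _optimal_system(model, fixed_objective)
    verts, _rays, _lin = polyhedron_generators(A, b, lb, ub)
    return [Vertex(FluxVector(dict(zip(rids, v))), module_id) for v in verts]


def enumerate_rays(
    model: StoichModel,
    fixed_objective: Optional[Fraction] = None,
    split_map: Optional[Mapping[str, tuple[str, str] | str]] = None,
) -> list[Ray]:
    """Extreme rays of the recession cone of the (optimal) polyhedron."""
    rids, A, b, lb, ub = _optimal_system(model, fixed_objective)
    _verts, rays, _lin = polyhedron_generators(A, b, lb, ub)
    boundary = {s.id for s in model.species if s.is_boundary}
    pairs = set()
    if split_map:
        for entry in split_map.values():
            if not isinstance(entry, str):
                pairs.add(frozenset(entry))
    out = []
    for r in rays:
        flux = FluxVector(dict(zip(rids, r)))
        out.append(Ray(flux, _classify_ray(model, flux, boundary, pairs)))
    return out


def _classify_ray(model, flux, boundary, pairs) -> str:
    support = flux.support()
    if support in pairs:
        return "split-pair"
    for rid in support:
        for sid, coeff in model.get_reaction(rid).stoichiometry.items():
            if sid in boundary:
                return "input-output"
    return "cycle"


def lineality_space(model: StoichModel) -> list[Lineality]:
    """Basis of the lineality space: nullspace of N over the free columns.

    Free columns are reactions unbounded in both directions (reversible,
    no finite bound).  A split model has none, hence an empty list.
    """
    rids = model.reaction_ids()
    free = [rid for rid in rids
            if model.get_reaction(rid).lower_bound is None
            and model.get_reaction(rid).upper_bound is None]
    if not free:
        return []
    _, _, n_mat = model.stoich_matrix()
    col = {rid: j for j, rid in enumerate(rids)}
    sub = [[row[col[rid]] for rid in free] for row in n_mat]
    basis = nullspace(sub, len(free))
    out = []
    for v in basis:
        values = {rid: _ZERO for rid in rids}
        for rid, x in zip(free, v):
            values[rid] = x
        vec = canonical_sign(primitive([values[rid] for rid in rids]))
        out.append(Lineality(FluxVector(dict(zip(rids, vec)))))
    out.sort(key=lambda l: tuple(l.direction.values.values()))
    return out


# ----------------------------------------------------------------------
# Optimal space: per-module vertices + whole-model rays/linealities
# ----------------------------------------------------------------------

@dataclass
class OptimalSpace:
    """Minkowski-sum description of the optimal solution space.

    Vertices are stored per flux module and combined lazily; the full
    vertex set is the product over essential modules of their vertex lists
    merged with the fixed flux.  ``s`` is that product, ``t`` and ``u`` are
    the ray and lineality counts.
    """

    decomposition: "OptimumDecomposition"  # noqa: F821 (modules_detect)
    module_vertices: dict[str, list[Vertex]]
    rays: list[Ray]
    linealities: list[Lineality]
    reaction_ids: list[str]

    @property
    def s(self) -> int:
        return count_vertices(self)[0]

    @property
    def t(self) -> int:
        return len(self.rays)

    @property
    def u(self) -> int:
        return len(self.linealities)

    def subnetwork_ids(self) -> list[str]:
        """Modules that contribute alternatives (>= 2 vertices)."""
        return [mid for mid, vs in self.module_vertices.items() if len(vs) >= 2]


def build_optimal_space(model: StoichModel, z_star: Optional[Fraction] = None,
                        split_map=None) -> OptimalSpace:
    """Run the full pipeline: FBA -> FVA -> modules -> per-module enumeration.

    Module polytopes are enumerated on the extracted submodels (with the
    interface fixed by unit-flux pseudo-reactions); rays and linealities are
    enumerated on the whole model with the objective held at its optimum.
    """
    from . import lp_core, modules_detect

    if z_star is None:
        sol = lp_core.solve_fba(model, sense="max")
        if sol.status != "optimal":
            raise ValueError(f"FBA did not reach an optimum: {sol.status}")
        z_star = sol.objective_value
    deco = modules_detect.decompose_modules(model, z_star)
    module_vertices: dict[str, list[Vertex]] = {}
    for module in deco.modules:
        sub = modules_detect.build_module_model(model, module, z_star=z_star)
        verts = enumerate_vertices(sub, module_id=module.id)
        module_vertices[module.id] = [
            Vertex(
                FluxVector({rid: v.flux[rid] for rid in module.reactions}),
                module.id,
            )
            for v in verts
        ]
    rays = enumerate_rays(model, fixed_objective=z_star, split_map=split_map)
    lins = lineality_space(model)
    return OptimalSpace(
        decomposition=deco,
        module_vertices=module_vertices,
        rays=rays,
        linealities=lins,
        reaction_ids=model.reaction_ids(),
    )


def count_vertices(space: OptimalSpace) -> tuple[int, int]:
    """(product, sum) of per-module vertex counts.

    The product is the number of whole-network vertices; the sum is the
    number of module vertices actually enumerated.  With no modules the
    optimum is unique: product 1, sum 0.
    """
    product = 1
    total = 0
    for vs in space.module_vertices.values():
        product *= max(len(vs), 1)
        total += len(vs)
    return product, total


def reconstruct_vertex(space: OptimalSpace,
                       choice: Mapping[str, int]) -> FluxVector:
    """Merge the fixed flux with one chosen vertex per module."""
    values = dict(space.decomposition.fixed_flux.values)
    for mid, vlist in space.module_vertices.items():
        if not vlist:
            continue
        idx = choice[mid]
        if not (0 <= idx < len(vlist)):
            raise IndexError(f"module {mid!r} has no vertex {idx}")
        values.update(vlist[idx].flux.values)
    return FluxVector({rid: values[rid] for rid in space.reaction_ids})


def iter_reconstructed_vertices(
    space: OptimalSpace,
) -> Iterator[tuple[dict[str, int], FluxVector]]:
    """Lazily iterate all vertex combinations without materializing them."""
    mids = [mid for mid, vs in space.module_vertices.items() if vs]
    counts = [len(space.module_vertices[mid]) for mid in mids]
    for combo in itertools.product(*(range(c) for c in counts)):
        choice = dict(zip(mids, combo))
        yield choice, reconstruct_vertex(space, choice)


# ----------------------------------------------------------------------
# Minkowski membership
# ----------------------------------------------------------------------

@dataclass
class Decomposition:
    alpha: list[Fraction]
    beta: list[Fraction]
    gamma: list[Fraction]


@dataclass
class Rejection:
    reason: str


def decompose_in_space(space: OptimalSpace, j: FluxVector,
                       model: StoichModel, z_star: Fraction):
    """Express j as a Minkowski sum over the space, or reject it.

    Optimal-feasibility is checked exactly first; a violated constraint is
    returned as the rejection certificate.  For an optimal-feasible flux a
    valid weight assignment always exists (completeness of the generator
    description) and one is found by exact LP feasibility.
    """
    # certificate-producing feasibility check
    if set(j.values) != set(space.reaction_ids):
        return Rejection("flux is not defined on the model's reactions")
    if not j.is_steady_state(model):
        return Rejection("steady-state violation: N.J != 0")
    if not j.within_bounds(model):
        for r in model.reactions:
            v = j[r.id]
            if r.lower_bound is not None and v < r.lower_bound:
                return Rejection(f"bound violation: {r.id} = {v} < {r.lower_bound}")
            if r.upper_bound is not None and v > r.upper_bound:
                return Rejection(f"bound violation: {r.id} = {v} > {r.upper_bound}")
    zval = j.objective_value(model)
    if zval != z_star:
        return Rejection(f"objective {zval} != optimum {z_star}")

    from .lp_core import solve_exact_lp

    verts = [v for _, v in iter_reconstructed_vertices(space)]
    if not verts:
        verts = [space.decomposition.fixed_flux]
    rids = space.reaction_ids
    s, t, u = len(verts), len(space.rays), len(space.linealities)
    cols = (
        [[v[rid] for rid in rids] for v in verts]
        + [[r.direction[rid] for rid in rids] for r in space.rays]
        + [[l.direction[rid] for rid in rids] for l in space.linealities]
    )
    A = [[cols[k][i] for k in range(s + t + u)] for i in range(len(rids))]
    b = [j[rid] for rid in rids]
    A.append([_ONE] * s + [_ZERO] * (t + u))  # convexity row
    b.append(_ONE)
    lb: list[Bound] = [_ZERO] * (s + t) + [None] * u
    ub: list[Bound] = [None] * (s + t + u)
    res = solve_exact_lp([_ZERO] * (s + t + u), A, b, lb, ub, sense="min")
    if res.status != "optimal":
        return Rejection(
            "optimal-feasible flux not representable by the generators "
            "(incomplete description)"
        )
    return Decomposition(alpha=res.x[:s], beta=res.x[s:s + t],
                         gamma=res.x[s + t:])
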