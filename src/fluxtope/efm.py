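"""Elementary flux modes (EFMs) for small networks.

An EFM is a steady-state flux pattern with minimal support that respects
all irreversibility constraints; minimality is certified by the rank test:
the stoichiometric matrix restricted to the support columns must have
nullity exactly one.

EFMs are enumerated as the extreme rays of the split flux cone
{v >= 0 : N v = 0} (numeric flux bounds play no role), mapped back through
the forward-minus-backward projection.  Spurious two-cycle modes collapse to
zero and are dropped; a fully reversible mode appears in both orientations
and is reported once, in a canonical direction.  On an already-irreversible
model the cone rays are the EFMs directly, so calling this on a split model
keeps the two-cycle modes — matching the convention that each split pair
forms an EFM of its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

from ._rational import canonical_sign, primitive
from .netmodel import FluxVector, StoichModel, split_reversible, unsplit_flux
from .polyhedra import Vertex, double_description, rational_rank

__all__ = [
    "EFM",
    "RankTestReport",
    "MatchReport",
    "enumerate_efms",
    "optimal_yield_filter",
    "rank_test",
    "rank_test_svd",
    "match_vertices_to_efms",
]

_ZERO = Fraction(0)
_ONE = Fraction(1)

#: refuse plain enumeration above this many (split) reactions
SIZE_GUARD = 40


@dataclass
class EFM:
    flux: FluxVector
    support: frozenset[str]
    normalized_to: tuple[str, Fraction] | str  # (reaction, value) or "primitive"


@dataclass
class RankTestReport:
    support_size: int
    rank: int
    nullity: int

    @property
    def verdict(self) -> bool:
        return self.nullity == 1


@dataclass
class MatchReport:
    """Vertex-to-EFM correspondence (proportional flux, identical support)."""

    vertex_to_efm: list[Optional[int]]  # index into the EFM list or None
    n_efms: int

    @property
    def matched_efm_indices(self) -> set[int]:
        return {k for k in self.vertex_to_efm if k is not None}

    @property
    def n_matched_efms(self) -> int:
        return len(self.matched_efm_indices)

    @property
    def n_composite_vertices(self) -> int:
        return sum(1 for k in self.vertex_to_efm if k is None)

    def is_bijection(self) -> bool:
        matched = [k for k in self.vertex_to_efm if k is not None]
        return (len(matched) == len(self.vertex_to_efm) == self.n_efms
                and len(set(matched)) == len(matched))


def enumerate_efms(model: StoichModel) -> list[EFM]:
    """All elementary flux modes of the network (ignores numeric bounds)."""
    needs_split = any(r.reversible for r in model.reactions)
    if needs_split:
        sm = split_reversible(model)
        work, split_map = sm.model, sm.split_map
    else:
        work, split_map = model, None
    rids = work.reaction_ids()
    if len(rids) > SIZE_GUARD:
        raise ValueError(
            f"{len(rids)} reactions exceeds the EFM size guard "
            f"({SIZE_GUARD}); enumerate per flux module instead"
        )
    _, _, n_mat = work.stoich_matrix()
    dim = len(rids)
    ineqs = []
    for j in range(dim):
        row = [_ZERO] * dim
        row[j] = _ONE
        ineqs.append(row)
    lin, rays = double_description(n_mat, ineqs, dim)
    assert not lin, "flux cone with nonnegative variables is pointed"

    out_vecs: list[dict[str, Fraction]] = []
    if needs_split:
        seen = set()
        for ray in rays:
            flux = unsplit_flux(FluxVector(dict(zip(rids, ray))), split_map)
            ordered = [flux[rid] for rid in model.reaction_ids()]
            if all(v == 0 for v in ordered):
                continue  # spurious two-cycle of a split pair
            canon = tuple(canonical_sign(primitive(ordered)))
            if canon in seen:
                continue
            seen.add(canon)
            out_vecs.append(dict(zip(model.reaction_ids(), canon)))
    else:
        for ray in rays:
            out_vecs.append(dict(zip(rids, ray)))

    objective = [r.id for r in model.reactions if r.objective_coeff != 0]
    obj_id = objective[0] if len(objective) == 1 else None
    efms = []
    for values in out_vecs:
        flux = FluxVector(values)
        support = flux.support()
        if obj_id is not None and obj_id in support:
            scale = flux[obj_id]
            flux = FluxVector({k: v / scale for k, v in flux.values.items()})
            norm: tuple[str, Fraction] | str = (obj_id, _ONE)
        else:
            norm = "primitive"
        efms.append(EFM(flux=flux, support=support, normalized_to=norm))
    efms.sort(key=lambda e: (sorted(e.support),
                             tuple(e.flux[r] for r in sorted(e.flux.values))))
    return efms


def optimal_yield_filter(
    efms: Sequence[EFM],
    model: StoichModel,
    z_star: Fraction,
) -> list[EFM]:
    """EFMs that attain the optimum when scaled to saturate the bounds.

    Non-operational modes (zero objective flux) are always excluded.  With
    a single restricting nonzero constraint the filter is exact; with more
    than one it remains a necessary yield condition and a warning is
    emitted.
    """
    restricting = []
    for r in model.reactions:
        if r.upper_bound is not None and r.upper_bound != 0:
            restricting.append((r.id, +1, r.upper_bound))
        if r.lower_bound is not None and r.lower_bound != 0:
            restricting.append((r.id, -1, r.lower_bound))
    if len(restricting) > 1:
        import warnings

        warnings.warn(
            "more than one restricting nonzero constraint; the optimal-yield "
            "filter is only a necessary condition", stacklevel=2)
    objective = {r.id: r.objective_coeff for r in model.reactions
                 if r.objective_coeff != 0}
    kept = []
    for e in efms:
        zval = sum((objective.get(rid, _ZERO) * e.flux[rid]
                    for rid in e.flux.values), _ZERO)
        if zval <= 0:
            continue
        scale = None
        for rid, sign, bound in restricting:
            v = e.flux.values.get(rid, _ZERO)
            if sign > 0 and v > 0:
                s = bound / v
            elif sign < 0 and v < 0:
                s = bound / v
            else:
                continue
            if scale is None or s < scale:
                scale = s
        if scale is None:
            continue  # unconstrained positive-yield mode: unbounded FBA
        if scale * zval == z_star:
            kept.append(e)
    return kept


def rank_test(flux: FluxVector, model: StoichModel) -> RankTestReport:
    """Exact support-minimality test: nullity of N over the support columns.

    Rank is computed by fraction-based Gaussian elimination, so the verdict
    is tolerance-free.
    """
    support = sorted(flux.support())
    if not support:
        raise ValueError("zero flux vector has an empty support")
    _, rids, n_mat = model.stoich_matrix()
    col = {rid: j for j, rid in enumerate(rids)}
    cols = [col[rid] for rid in support]
    sub = [[row[j] for j in cols] for row in n_mat]
    rank = rational_rank(sub)
    return RankTestReport(support_size=len(support), rank=rank,
                          nullity=len(support) - rank)


def rank_test_svd(flux: FluxVector, model: StoichModel,
                  tol: float = 1e-9) -> RankTestReport:
    """Floating-point cross-check of :func:`rank_test` via singular values."""
    import numpy as np

    support = sorted(flux.support())
    if not support:
        raise ValueError("zero flux vector has an empty support")
    _, rids, n_mat = model.stoich_matrix()
    col = {rid: j for j, rid in enumerate(rids)}
    sub = np.array([[float(row[col[rid]]) for rid in support]
                    for row in n_mat])
    sv = np.linalg.svd(sub, compute_uv=False) if sub.size else np.array([])
    rank = int((sv > tol * (sv[0] if sv.size else 1.0)).sum())
    return RankTestReport(support_size=len(support), rank=rank,
                          nullity=len(support) - rank)


def match_vertices_to_efms(
    vertices: Sequence[Vertex],
    efms: Sequence[EFM],
) -> MatchReport:
    """Match each vertex to the EFM it is an instance of, if any.

    A vertex is an instance of an EFM when both have the same support and
    the fluxes are proportional; otherwise it is composite (a combination
    of several EFMs).
    """
    by_support: dict[frozenset[str], list[int]] = {}
    for k, e in enumerate(efms):
        by_support.setdefault(e.support, []).append(k)
    mapping: list[Optional[int]] = []
    for v in vertices:
        support = v.flux.support()
        found = None
        for k in by_support.get(support, []):
            if _proportional(v.flux, efms[k].flux, support):
                found = k
                break
        mapping.append(found)
    return MatchReport(vertex_to_efm=mapping, n_efms=len(efms))


def _proportional(a: FluxVector, b: FluxVector,
                  support: frozenset[str]) -> bool:
    ratio = None
    for rid in support:
        if b[rid] == 0:
            return False
        r = a[rid] / b[rid]
        if ratio is None:
            ratio = r
        elif r != ratio:
            return False
    return ratio is not None and ratio > 0
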