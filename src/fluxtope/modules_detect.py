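"""Flux-module decomposition of the optimum's variable part.

At the FBA optimum the network splits into a *fixed* part — reactions whose
flux is the same in every optimal solution (zero-width FVA interval) — and a
*variable* part.  The variable part decomposes into flux modules: disjoint
reaction sets A whose internal fluxes vary across optima while their net
input-output stoichiometry d = N_A J_A stays fixed (d != 0 marks a module
essential for optimality).

Modules are discovered as connected components of the species-reaction
graph restricted to variable reactions, then *verified*: for every species a
component touches, the net production by the component is minimized and
maximized over the optimum with two exact LPs; a constant value for every
species certifies the component as a module.  Components that fail are
merged with the other failing components (they must co-vary) and the check
repeats to a fixed point, so correctness does not depend on the discovery
heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import networkx as nx

from .lp_core import FVAResult, fva, solve_exact_lp, _model_system
from .netmodel import FluxVector, Reaction, Species, StoichModel

__all__ = [
    "FModule",
    "OptimumDecomposition",
    "find_variable_reactions",
    "decompose_modules",
    "module_interface",
    "build_module_model",
]

_ZERO = Fraction(0)
_ONE = Fraction(1)


@dataclass
class FModule:
    id: str
    reactions: frozenset[str]
    interface: dict[str, Fraction]  # species -> d, zero entries omitted
    essential: bool
    internal_species: frozenset[str]

    def __post_init__(self) -> None:
        self.essential = any(v != 0 for v in self.interface.values())


@dataclass
class OptimumDecomposition:
    """Fixed flux plus the flux modules covering all variable reactions.

    Interface magnitudes are expressed at the fixed objective value
    ``objective_value`` (i.e. per ``objective_value`` units of objective
    flux); ``interface_scale`` records that convention.
    """

    fixed_flux: FluxVector
    modules: list[FModule]
    objective_value: Fraction

    @property
    def interface_scale(self) -> Fraction:
        return self.objective_value

    def variable_reactions(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.modules:
            out |= m.reactions
        return frozenset(out)


def find_variable_reactions(
    model: StoichModel,
    z_star: Fraction,
    fva_result: Optional[FVAResult] = None,
) -> set[str]:
    """Reactions whose exact FVA interval at the optimum has nonzero width."""
    if fva_result is None:
        fva_result = fva(model, z_star)
    return {rid for rid in model.reaction_ids()
            if fva_result.width_nonzero(rid)}


def _net_production_range(model, z_star, reactions, sid):
    """Exact (min, max) of sum_{r in A} n_{s,r} J_r over the optimum."""
    rids, A, b, lb, ub = _model_system(
        model,
        [({r.id: r.objective_coeff for r in model.reactions
           if r.objective_coeff != 0}, z_star)],
    )
    col = {rid: j for j, rid in enumerate(rids)}
    c = [_ZERO] * len(rids)
    for rid in reactions:
        coeff = model.get_reaction(rid).stoichiometry.get(sid, _ZERO)
        if coeff != 0:
            c[col[rid]] += coeff
    lo = solve_exact_lp(c, A, b, lb, ub, sense="min")
    hi = solve_exact_lp(c, A, b, lb, ub, sense="max")
    if lo.status != "optimal" or hi.status != "optimal":
        return None, None  # unbounded net production: certainly not constant
    return lo.objective, hi.objective


def _verify_component(model, z_star, reactions) -> Optional[dict[str, Fraction]]:
    """Return the exact interface d if constant over the optimum, else None."""
    touched: set[str] = set()
    for rid in reactions:
        touched |= set(model.get_reaction(rid).stoichiometry)
    d: dict[str, Fraction] = {}
    for sid in sorted(touched):
        lo, hi = _net_production_range(model, z_star, reactions, sid)
        if lo is None or lo != hi:
            return None
        if lo != 0:
            d[sid] = lo
    return d


def decompose_modules(
    model: StoichModel,
    z_star: Fraction,
    variable: Optional[set[str]] = None,
    fva_result: Optional[FVAResult] = None,
) -> OptimumDecomposition:
    """Partition the variable reactions into verified flux modules."""
    if fva_result is None:
        fva_result = fva(model, z_star)
    if variable is None:
        variable = find_variable_reactions(model, z_star, fva_result)

    fixed_values = {
        rid: fva_result[rid][0]
        for rid in model.reaction_ids()
        if rid not in variable
    }
    fixed_flux = FluxVector(fixed_values)

    boundary = {s.id for s in model.species if s.is_boundary}
    graph = nx.Graph()
    graph.add_nodes_from(variable)
    for rid in variable:
        for sid in model.get_reaction(rid).stoichiometry:
            if sid not in boundary:
                graph.add_edge(rid, ("species", sid))
    components = [
        frozenset(n for n in comp if not isinstance(n, tuple))
        for comp in nx.connected_components(graph)
    ]
    components = [c for c in components if c]

    # verify; merge co-varying failures to a fixed point
    for _round in range(len(components) + 1):
        verified: list[tuple[frozenset[str], dict[str, Fraction]]] = []
        failing: list[frozenset[str]] = []
        for comp in components:
            d = _verify_component(model, z_star, comp)
            if d is None:
                failing.append(comp)
            else:
                verified.append((comp, d))
        if not failing:
            break
        if len(failing) == 1:
            raise RuntimeError(
                "module verification failed for an isolated component; "
                "the variable set is inconsistent"
            )
        merged = frozenset().union(*failing)
        components = [c for c, _ in verified] + [merged]
    else:  # pragma: no cover - merge loop is finite by construction
        raise RuntimeError("module merge loop did not converge")

    verified.sort(key=lambda cd: sorted(cd[0]))
    touched_by = {}
    for r in model.reactions:
        for sid in r.stoichiometry:
            touched_by.setdefault(sid, set()).add(r.id)
    modules = []
    for k, (comp, d) in enumerate(verified, start=1):
        internal = frozenset(
            sid for sid in touched_by
            if touched_by[sid] <= comp and sid not in boundary
        )
        modules.append(FModule(
            id=f"M{k}",
            reactions=comp,
            interface=d,
            essential=any(v != 0 for v in d.values()),
            internal_species=internal,
        ))
    return OptimumDecomposition(fixed_flux=fixed_flux, modules=modules,
                                objective_value=z_star)


def module_interface(model: StoichModel, module: FModule,
                     z_star: Fraction) -> dict[str, Fraction]:
    """Recompute the exact interface d of a verified module.

    Raises if any species' net production turns out non-constant over the
    optimum — that would violate the module invariant.
    """
    d = _verify_component(model, z_star, module.reactions)
    if d is None:
        raise RuntimeError(
            f"module {module.id}: interface is not constant over the optimum"
        )
    return d


def build_module_model(
    model: StoichModel,
    module: FModule,
    d: Optional[dict[str, Fraction]] = None,
    z_star: Optional[Fraction] = None,
) -> StoichModel:
    """Extract the submodel of a module with its interface held fixed.

    Contains exactly the module's reactions and species.  For an essential
    module a unit-flux input pseudo-reaction supplies the net-consumed
    species and a unit-flux output pseudo-reaction removes the net-produced
    ones; a dummy species produced by the input and consumed by the output
    forces both to run.  If the module contains objective reactions, their
    contribution to the optimum is pinned with an equality pseudo-constraint
    row via bounds on a reporter reaction.
    """
    if d is None:
        d = dict(module.interface)
    essential = any(v != 0 for v in d.values())
    rids = sorted(module.reactions)
    touched: set[str] = set()
    for rid in rids:
        touched |= set(model.get_reaction(rid).stoichiometry)
    boundary = {s.id for s in model.species if s.is_boundary}

    species = [Species(sid, False) for sid in sorted(touched - boundary)]
    species += [Species(sid, True) for sid in sorted(touched & boundary)]
    reactions = []
    for rid in rids:
        r = model.get_reaction(rid)
        reactions.append(Reaction(
            id=r.id,
            stoichiometry=dict(r.stoichiometry),
            reversible=r.reversible,
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            objective_coeff=_ZERO,
            gpr=r.gpr,
        ))
    if essential:
        dummy = "__module_io__"
        species.append(Species(dummy, False))
        inputs = {sid: -v for sid, v in d.items() if v < 0}
        outputs = {sid: v for sid, v in d.items() if v > 0}
        in_st = dict(inputs)
        in_st[dummy] = _ONE
        out_st = {sid: -v for sid, v in outputs.items()}
        out_st[dummy] = -_ONE
        reactions.append(Reaction("__in__", in_st, False, _ONE, _ONE))
        reactions.append(Reaction("__out__", out_st, False, _ONE, _ONE))

    # pin the module's objective contribution if it owns objective reactions
    obj_rxns = [rid for rid in rids
                if model.get_reaction(rid).objective_coeff != 0]
    if obj_rxns and z_star is not None:
        contrib = _module_objective_contribution(model, module, z_star)
        rep_species = "__obj_balance__"
        species.append(Species(rep_species, False))
        for rxn in reactions:
            if rxn.id in obj_rxns:
                coeff = model.get_reaction(rxn.id).objective_coeff
                rxn.stoichiometry[rep_species] = coeff
        reactions.append(Reaction(
            "__obj__", {rep_species: -_ONE}, False, contrib, contrib))

    sub = StoichModel(species, reactions, name=f"{model.name}:{module.id}")
    sub.validate()
    return sub


def _module_objective_contribution(model, module, z_star) -> Fraction:
    lo, hi = None, None
    rids, A, b, lb, ub = _model_system(
        model,
        [({r.id: r.objective_coeff for r in model.reactions
           if r.objective_coeff != 0}, z_star)],
    )
    col = {rid: j for j, rid in enumerate(rids)}
    c = [_ZERO] * len(rids)
    for rid in module.reactions:
        c[col[rid]] += model.get_reaction(rid).objective_coeff
    res_lo = solve_exact_lp(c, A, b, lb, ub, sense="min")
    res_hi = solve_exact_lp(c, A, b, lb, ub, sense="max")
    if (res_lo.status != "optimal" or res_hi.status != "optimal"
            or res_lo.objective != res_hi.objective):
        raise RuntimeError(
            f"module {module.id}: objective contribution varies over optimum"
        )
    return res_lo.objective
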