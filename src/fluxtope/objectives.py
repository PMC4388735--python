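"""Secondary objectives over the optimal solution space.

Three secondary objectives rank the alternative optima left by flux
balance analysis:

* ``P_L`` — pathway length, the number of reactions carrying flux;
* ``P_J`` — the sum of absolute flux values;
* ``P_C`` — the protein-cost-weighted sum of absolute fluxes, where each
  reaction's cost c_j derives from its gene-protein-reaction (GPR) rule:
  an AND (complex) sums the protein lengths, an OR (isozymes) takes the
  minimum, maximum, or average, and the result is scaled by the mean
  length over all annotated proteins, so c_j < 1 marks a cheaper-than-
  average enzyme.  Reactions without annotation get c_j = 1, and the
  "equal" rule (all c_j = 1) makes P_C coincide with P_J.

P_L is minimized with a mixed-integer program (big-M activity indicators
from exact FVA); P_J and P_C are plain LPs on the split model, where
absolute values reduce to sums of nonnegative fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from statistics import mean
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._rational import Bound, to_rational
from .lp_core import fva, solve_milp, solve_model_lp
from .netmodel import FluxVector, StoichModel
from .polyhedra import OptimalSpace, iter_reconstructed_vertices

__all__ = [
    "CostVector",
    "SecondaryResult",
    "pathway_length",
    "pathway_flux_sum",
    "pathway_cost",
    "build_cost_vector",
    "minimize_pathway_length",
    "minimize_linear_secondary",
    "vertex_statistics",
]

_ZERO = Fraction(0)
_ONE = Fraction(1)

#: fallback activity bound for directions with an unbounded FVA interval.
#: Cycle directions make some split fluxes formally unbounded, but a
#: support-minimal optimum never rides a cycle, so any cap well above the
#: magnitudes reachable without cycling is safe in practice; the returned
#: witness is certified exactly either way.
DEFAULT_ACTIVITY_CAP = Fraction(1024)


@dataclass
class CostVector:
    costs: dict[str, Fraction]  # reaction id -> c_j
    rule: str  # min | max | average | equal
    scale: Fraction  # mean protein length used for normalization

    def __getitem__(self, rid: str) -> Fraction:
        return self.costs[rid]


@dataclass
class SecondaryResult:
    objective: str  # "P_L" | "P_J" | "P_C"
    optimal_value: Fraction
    witness_flux: FluxVector
    n_optimal_vertices: Optional[int] = None


# ----------------------------------------------------------------------
# The three statistics (exact zero tests; thresholded variant for floats)
# ----------------------------------------------------------------------

def pathway_length(flux: FluxVector, zero_tol: float | None = None) -> int:
    """Number of reactions carrying flux. Exact zero test on rationals.

    ``zero_tol`` (default None = exact) applies only when scoring
    externally supplied floating-point fluxes.
    """
    if zero_tol is None:
        return sum(1 for v in flux.values.values() if v != 0)
    return sum(1 for v in flux.values.values() if abs(v) > zero_tol)


def pathway_flux_sum(flux: FluxVector) -> Fraction:
    return sum((abs(v) for v in flux.values.values()), _ZERO)


def pathway_cost(flux: FluxVector, costs: CostVector) -> Fraction:
    total = _ZERO
    for rid, v in flux.values.items():
        if rid not in costs.costs:
            raise KeyError(f"no cost entry for reaction {rid!r}")
        if v != 0:
            total += costs.costs[rid] * abs(v)
    return total


# ----------------------------------------------------------------------
# GPR-derived costs
# ----------------------------------------------------------------------

def build_cost_vector(
    model: StoichModel,
    protein_lengths: Mapping[str, int | Fraction],
    rule: str = "average",
) -> CostVector:
    """Per-reaction cost from GPR rules and protein lengths.

    AND sums lengths (a complex needs all subunits), OR applies the chosen
    rule over its branches (isozymes), and the result is divided by the
    mean length of all proteins referenced by the model so that costs are
    centered on 1.  ``rule="equal"`` sets every cost to 1.
    """
    if rule not in ("min", "max", "average", "equal"):
        raise ValueError(f"unknown cost rule {rule!r}")
    if rule == "equal":
        return CostVector({r.id: _ONE for r in model.reactions}, rule, _ONE)
    referenced: set[str] = set()
    trees = {}
    for r in model.reactions:
        if r.gpr:
            tree = _parse_gpr(r.gpr)
            trees[r.id] = tree
            referenced |= _gpr_proteins(tree)
    missing = sorted(p for p in referenced if p not in protein_lengths)
    if missing:
        raise KeyError(f"unknown protein ids in GPR rules: {', '.join(missing)}")
    if referenced:
        scale = sum((to_rational(protein_lengths[p]) for p in sorted(referenced)),
                    _ZERO) / len(referenced)
    else:
        scale = _ONE
    costs = {}
    for r in model.reactions:
        if r.id in trees:
            raw = _eval_gpr(trees[r.id], protein_lengths, rule)
            costs[r.id] = to_rational(raw) / scale
        else:
            costs[r.id] = _ONE
    return CostVector(costs, rule, scale)


# GPR expression: id | expr 'and' expr | expr 'or' expr | '(' expr ')'
def _tokenize_gpr(text: str) -> list[str]:
    out = []
    for part in text.replace("(", " ( ").replace(")", " ) ").split():
        out.append(part)
    return out


def _parse_gpr(text: str):
    tokens = _tokenize_gpr(text)
    pos = 0

    def parse_or():
        nonlocal pos
        node = parse_and()
        terms = [node]
        while pos < len(tokens) and tokens[pos].lower() == "or":
            pos += 1
            terms.append(parse_and())
        return ("or", terms) if len(terms) > 1 else node

    def parse_and():
        nonlocal pos
        node = parse_atom()
        terms = [node]
        while pos < len(tokens) and tokens[pos].lower() == "and":
            pos += 1
            terms.append(parse_atom())
        return ("and", terms) if len(terms) > 1 else node

    def parse_atom():
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError(f"truncated GPR expression: {text!r}")
        tok = tokens[pos]
        if tok == "(":
            pos += 1
            node = parse_or()
            if pos >= len(tokens) or tokens[pos] != ")":
                raise ValueError(f"unbalanced parentheses in GPR: {text!r}")
            pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ValueError(f"malformed GPR expression: {text!r}")
        pos += 1
        return ("id", tok)

    node = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in GPR: {text!r}")
    return node


def _gpr_proteins(node) -> set[str]:
    kind, payload = node
    if kind == "id":
        return {payload}
    out: set[str] = set()
    for child in payload:
        out |= _gpr_proteins(child)
    return out


def _eval_gpr(node, lengths, rule) -> Fraction:
    kind, payload = node
    if kind == "id":
        return to_rational(lengths[payload])
    vals = [_eval_gpr(child, lengths, rule) for child in payload]
    if kind == "and":
        return sum(vals, _ZERO)
    if rule == "min":
        return min(vals)
    if rule == "max":
        return max(vals)
    return sum(vals, _ZERO) / len(vals)  # average


# ----------------------------------------------------------------------
# Secondary optimization
# ----------------------------------------------------------------------

def minimize_pathway_length(
    model: StoichModel,
    z_star: Fraction,
    space: Optional[OptimalSpace] = None,
    activity_cap: Fraction = DEFAULT_ACTIVITY_CAP,
) -> SecondaryResult:
    """MILP minimum of the active-reaction count at the fixed optimum.

    Activity bounds come from exact FVA at the optimum; directions the FVA
    reports unbounded (cycle directions) fall back to ``activity_cap``.
    The witness is exactly certified (see lp_core.solve_milp).  If an
    enumerated space is supplied, the number of its vertices attaining the
    minimum is counted exactly.
    """
    ranges = fva(model, z_star)
    indicator: dict[str, tuple[Bound, Bound]] = {}
    for rid in model.reaction_ids():
        lo, hi = ranges[rid]
        if lo is not None and hi is not None and lo == hi:
            continue  # fixed reaction: active count is constant, no binary
        scale = max(abs(x) for x in (lo, hi, _ONE) if x is not None)
        if lo is None:
            lo = -max(activity_cap, scale)
        if hi is None:
            hi = max(activity_cap, scale)
        indicator[rid] = (min(lo, _ZERO), max(hi, _ZERO))
    count_var, witness = solve_milp(model, indicator, z_star)
    fixed_active = sum(
        1 for rid in model.reaction_ids()
        if rid not in indicator and ranges[rid][0] != 0
    )
    value = Fraction(count_var + fixed_active)
    n_opt = None
    if space is not None:
        n_opt = sum(
            1 for _, v in iter_reconstructed_vertices(space)
            if pathway_length(v) == value
        )
    return SecondaryResult("P_L", value, witness, n_opt)


def minimize_linear_secondary(
    model: StoichModel,
    z_star: Fraction,
    costs: Optional[CostVector] = None,
    space: Optional[OptimalSpace] = None,
) -> SecondaryResult:
    """LP minimum of P_J (costs=None or equal) or P_C on a split model.

    Requires an all-irreversible (split) model, where |J_j| = J_j and the
    weighted absolute-flux sum is linear.
    """
    if any(r.reversible or r.lower_bound is None or r.lower_bound < 0
           for r in model.reactions):
        raise ValueError(
            "linear secondary objectives need a split (all-irreversible) "
            "model; apply split_reversible first"
        )
    name = "P_J" if costs is None or costs.rule == "equal" else "P_C"
    weights = {
        r.id: (costs.costs[r.id] if costs is not None else _ONE)
        for r in model.reactions
    }
    objective = {r.id: r.objective_coeff for r in model.reactions
                 if r.objective_coeff != 0}
    res = solve_model_lp(model, weights, sense="min",
                         equalities=[(objective, z_star)])
    if res.status != "optimal":
        raise ValueError(f"secondary LP not optimal: {res.status}")
    witness = FluxVector(dict(zip(model.reaction_ids(), res.x)))
    n_opt = None
    if space is not None:
        def score(v: FluxVector) -> Fraction:
            return sum((weights[rid] * abs(v[rid]) for rid in v.values), _ZERO)

        n_opt = sum(1 for _, v in iter_reconstructed_vertices(space)
                    if score(v) == res.objective)
    return SecondaryResult(name, res.objective, witness, n_opt)


# ----------------------------------------------------------------------
# Per-vertex statistics
# ----------------------------------------------------------------------

def vertex_statistics(
    space: OptimalSpace,
    costs: Optional[CostVector] = None,
    max_vertices: int = 100_000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """P_L, P_J (and P_C with costs) for every reconstructed vertex.

    If the vertex product exceeds ``max_vertices``, a seeded uniform sample
    of module-vertex combinations is scored instead.
    """
    from .polyhedra import count_vertices, reconstruct_vertex

    product, _ = count_vertices(space)
    rows = []
    if product <= max_vertices:
        iterator = iter_reconstructed_vertices(space)
    else:
        import random

        rng = random.Random(seed if seed is not None else 0)
        mids = [mid for mid, vs in space.module_vertices.items() if vs]

        def sampled():
            for _ in range(max_vertices):
                choice = {mid: rng.randrange(len(space.module_vertices[mid]))
                          for mid in mids}
                yield choice, reconstruct_vertex(space, choice)

        iterator = sampled()
    for choice, flux in iterator:
        row = {f"vertex[{mid}]": idx for mid, idx in choice.items()}
        row["P_L"] = pathway_length(flux)
        row["P_J"] = float(pathway_flux_sum(flux))
        if costs is not None:
            row["P_C"] = float(pathway_cost(flux, costs))
        rows.append(row)
    return pd.DataFrame(rows)
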