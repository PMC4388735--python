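"""Stoichiometric model types, fixtures, reversible splitting, and tabular I/O.

The central object is :class:`StoichModel`: species (with a boundary flag),
reactions with exact-rational stoichiometry, bounds, objective coefficients
and optional gene-protein-reaction (GPR) rules. Boundary species are not
balanced; the stoichiometric matrix ``N`` has one row per internal species.

Reversible-reaction splitting (:func:`split_reversible`) replaces every
reversible reaction by a forward and a backward irreversible reaction, which
makes the flux cone pointed and turns every non-decomposable optimal route
into a vertex of the optimal polyhedron.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator, Mapping, Optional, Sequence

from ._rational import Bound, format_rational, parse_bound, to_rational

__all__ = [
    "Species",
    "Reaction",
    "StoichModel",
    "SplitModel",
    "FluxVector",
    "build_toy_model",
    "generate_random_model",
    "split_reversible",
    "unsplit_flux",
    "read_model",
    "write_model",
    "ModelFormatError",
]


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed or violates an invariant."""


@dataclass(frozen=True)
class Species:
    id: str
    is_boundary: bool = False


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, Fraction]  # species id -> coefficient, <0 consumed
    reversible: bool = False
    lower_bound: Bound = Fraction(0)  # None = -inf
    upper_bound: Bound = None  # None = +inf
    objective_coeff: Fraction = Fraction(0)
    gpr: Optional[str] = None

    def validate(self) -> None:
        if not self.stoichiometry:
            raise ModelFormatError(f"reaction {self.id!r} has empty stoichiometry")
        lb, ub = self.lower_bound, self.upper_bound
        if lb is not None and ub is not None and lb > ub:
            raise ModelFormatError(
                f"reaction {self.id!r}: lower bound {lb} exceeds upper bound {ub}"
            )
        if not self.reversible and (lb is None or lb < 0):
            raise ModelFormatError(
                f"irreversible reaction {self.id!r} must have lower bound >= 0"
            )


@dataclass
class StoichModel:
    species: list[Species]
    reactions: list[Reaction]
    name: str = "model"

    def __post_init__(self) -> None:
        self._species_index = {s.id: s for s in self.species}
        self._reaction_index = {r.id: r for r in self.reactions}

    # -- lookups -------------------------------------------------------
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def internal_species_ids(self) -> list[str]:
        return [s.id for s in self.species if not s.is_boundary]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_species(self, sid: str) -> Species:
        return self._species_index[sid]

    def get_reaction(self, rid: str) -> Reaction:
        return self._reaction_index[rid]

    def objective_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.objective_coeff != 0]

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        sids = self.species_ids()
        if len(set(sids)) != len(sids):
            raise ModelFormatError("duplicate species ids")
        rids = self.reaction_ids()
        if len(set(rids)) != len(rids):
            raise ModelFormatError("duplicate reaction ids")
        for r in self.reactions:
            r.validate()
            for sid in r.stoichiometry:
                if sid not in self._species_index:
                    raise ModelFormatError(
                        f"reaction {r.id!r} references unknown species {sid!r}"
                    )

    # -- matrix view ---------------------------------------------------
    def stoich_matrix(self) -> tuple[list[str], list[str], list[list[Fraction]]]:
        """Return (internal species ids, reaction ids, dense rational N)."""
        rows = self.internal_species_ids()
        cols = self.reaction_ids()
        row_of = {s: i for i, s in enumerate(rows)}
        n = [[Fraction(0)] * len(cols) for _ in rows]
        for j, r in enumerate(self.reactions):
            for sid, coeff in r.stoichiometry.items():
                i = row_of.get(sid)
                if i is not None:
                    n[i][j] += coeff
        return rows, cols, n

    def copy(self) -> "StoichModel":
        return StoichModel(
            species=list(self.species),
            reactions=[
                Reaction(
                    id=r.id,
                    stoichiometry=dict(r.stoichiometry),
                    reversible=r.reversible,
                    lower_bound=r.lower_bound,
                    upper_bound=r.upper_bound,
                    objective_coeff=r.objective_coeff,
                    gpr=r.gpr,
                )
                for r in self.reactions
            ],
            name=self.name,
        )


@dataclass
class SplitModel:
    """An all-irreversible model plus the map back to the original reactions.

    ``split_map`` sends each original reaction id either to itself (was
    irreversible) or to its ``(forward id, backward id)`` pair.
    """

    model: StoichModel
    split_map: dict[str, tuple[str, str] | str]

    def forward_backward(self, rid: str) -> tuple[str, Optional[str]]:
        entry = self.split_map[rid]
        if isinstance(entry, str):
            return entry, None
        return entry


@dataclass
class FluxVector:
    """Exact-rational flux assignment, one value per reaction of its model."""

    values: dict[str, Fraction]

    def __getitem__(self, rid: str) -> Fraction:
        return self.values[rid]

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def support(self) -> frozenset[str]:
        return frozenset(rid for rid, v in self.values.items() if v != 0)

    def is_steady_state(self, model: StoichModel) -> bool:
        """Exact check that N.J = 0 over the internal species."""
        balance: dict[str, Fraction] = {}
        for r in model.reactions:
            v = self.values[r.id]
            if v == 0:
                continue
            for sid, coeff in r.stoichiometry.items():
                balance[sid] = balance.get(sid, Fraction(0)) + coeff * v
        internal = set(model.internal_species_ids())
        return all(val == 0 for sid, val in balance.items() if sid in internal)

    def within_bounds(self, model: StoichModel) -> bool:
        for r in model.reactions:
            v = self.values[r.id]
            if r.lower_bound is not None and v < r.lower_bound:
                return False
            if r.upper_bound is not None and v > r.upper_bound:
                return False
        return True

    def objective_value(self, model: StoichModel) -> Fraction:
        return sum(
            (r.objective_coeff * self.values[r.id] for r in model.reactions),
            Fraction(0),
        )


# ----------------------------------------------------------------------
# Reversible splitting
# ----------------------------------------------------------------------

def split_reversible(model: StoichModel) -> SplitModel:
    """Split each reversible reaction into forward and backward halves.

    The forward half keeps the original stoichiometry and objective
    coefficient; the backward half gets the negated stoichiometry and the
    negated objective coefficient, so the net objective contribution of any
    (forward, backward) pair equals that of the original net flux.
    Idempotent on an already-irreversible model.
    """
    reactions: list[Reaction] = []
    split_map: dict[str, tuple[str, str] | str] = {}
    existing = set(model.reaction_ids())
    for r in model.reactions:
        if not r.reversible:
            reactions.append(
                Reaction(r.id, dict(r.stoichiometry), False, r.lower_bound,
                         r.upper_bound, r.objective_coeff, r.gpr)
            )
            split_map[r.id] = r.id
            continue
        if r.lower_bound is not None and r.lower_bound > 0:
            raise ModelFormatError(
                f"reversible reaction {r.id!r} has positive lower bound; "
                "cannot be represented by a nonnegative forward/backward pair"
            )
        if r.upper_bound is not None and r.upper_bound < 0:
            raise ModelFormatError(
                f"reversible reaction {r.id!r} has negative upper bound; "
                "cannot be represented by a nonnegative forward/backward pair"
            )
        fid, bid = r.id + "_f", r.id + "_b"
        if fid in existing or bid in existing:
            raise ModelFormatError(f"split ids for {r.id!r} collide with existing ids")
        reactions.append(
            Reaction(fid, dict(r.stoichiometry), False, Fraction(0),
                     r.upper_bound, r.objective_coeff, r.gpr)
        )
        reactions.append(
            Reaction(bid, {s: -c for s, c in r.stoichiometry.items()}, False,
                     Fraction(0),
                     None if r.lower_bound is None else -r.lower_bound,
                     -r.objective_coeff, r.gpr)
        )
        split_map[r.id] = (fid, bid)
    split = StoichModel(list(model.species), reactions, name=model.name + "_split")
    split.validate()
    return SplitModel(model=split, split_map=split_map)


def unsplit_flux(split_flux: FluxVector, split_map: Mapping[str, tuple[str, str] | str]) -> FluxVector:
    """Map a split-model flux back: net flux = forward - backward."""
    values: dict[str, Fraction] = {}
    for rid, entry in split_map.items():
        if isinstance(entry, str):
            if entry not in split_flux.values:
                raise KeyError(f"reaction {entry!r} missing from split flux")
            values[rid] = split_flux.values[entry]
        else:
            fid, bid = entry
            if fid not in split_flux.values or bid not in split_flux.values:
                raise KeyError(f"split pair for {rid!r} missing from split flux")
            values[rid] = split_flux.values[fid] - split_flux.values[bid]
    return FluxVector(values)


# ----------------------------------------------------------------------
# Fixtures
# ----------------------------------------------------------------------

def build_toy_model() -> StoichModel:
    """The 18-species / 18-reaction toy network.

    Boundary source X and sink Y; ATP/ADP act as cofactors in two branches.
    The input reaction R1 (X -> A) is capped at 2 and the objective is
    maximization of the output flux J_18 (N -> Y), whose optimum is 1.
    Reactions R2, R3, R4, R13, R14 are reversible; everything else is
    irreversible.
    """
    one = Fraction(1)
    two = Fraction(2)

    def rxn(rid, stoich, reversible=False, ub=None, obj=0):
        return Reaction(
            id=rid,
            stoichiometry={s: to_rational(c) for s, c in stoich.items()},
            reversible=reversible,
            lower_bound=None if reversible else Fraction(0),
            upper_bound=ub,
            objective_coeff=to_rational(obj),
        )

    species = [Species("X", True), Species("Y", True)] + [
        Species(s) for s in
        ["A", "B", "C", "D", "E", "F", "G", "H", "I", "J", "K", "L", "M", "N",
         "ATP", "ADP"]
    ]
    reactions = [
        rxn("R1", {"X": -1, "A": 1}, ub=two),
        rxn("R2", {"A": -1, "B": 1}, reversible=True),
        rxn("R3", {"A": -1, "C": 1}, reversible=True),
        rxn("R4", {"C": -1, "B": 1}, reversible=True),
        rxn("R5", {"B": -1, "D": 1}),
        rxn("R6", {"D": -1, "E": 1}),
        rxn("R7", {"E": -1, "F": 1}),
        rxn("R8", {"F": -1, "ADP": -1, "H": 1, "ATP": 1}),
        rxn("R9", {"D": -1, "G": 1}),
        rxn("R10", {"G": -1, "ADP": -1, "H": 1, "ATP": 1}),
        rxn("R11", {"H": -1, "I": 1}),
        rxn("R12", {"I": -1, "J": 1}),
        rxn("R13", {"J": -1, "K": 1}, reversible=True),
        rxn("R14", {"K": -1, "L": 1}, reversible=True),
        rxn("R15", {"I": -1, "L": 1}),
        rxn("R16", {"J": -1, "L": -1, "M": 1}),
        rxn("R17", {"M": -1, "ATP": -2, "N": 1, "ADP": 2}),
        rxn("R18", {"N": -1, "Y": 1}, obj=one),
    ]
    model = StoichModel(species, reactions, name="toy")
    model.validate()
    return model


def generate_random_model(
    n_species: int,
    n_reactions: int,
    seed: int,
    p_reversible: float = 0.3,
    max_retries: int = 50,
) -> StoichModel:
    """Seeded random small network with one input and one output exchange.

    Internal species sit on a substrate-to-product backbone chain (which
    guarantees a nonzero steady-state route), decorated with random extra
    conversions with integer stoichiometric coefficients in {1, 2}. Intended
    for property tests against brute-force oracles, so keep sizes small.
    """
    if n_species < 1:
        raise ValueError("need at least one internal species")
    min_reactions = n_species + 1  # chain + input + output
    if n_reactions < min_reactions:
        raise ValueError(
            f"need at least {min_reactions} reactions for {n_species} species"
        )
    rng = _random.Random(seed)
    from . import lp_core  # deferred: lp_core imports netmodel types

    for _attempt in range(max_retries):
        model = _draw_random_model(n_species, n_reactions, rng, p_reversible)
        sol = lp_core.solve_fba(model, sense="max")
        if sol.status == "optimal" and sol.objective_value > 0:
            return model
        if sol.status == "unbounded":
            # input is capped at 1, so this cannot happen for a sound draw
            continue
    raise RuntimeError(
        f"no feasible random model found in {max_retries} draws (seed {seed})"
    )


def _draw_random_model(n_species, n_reactions, rng, p_reversible) -> StoichModel:
    internal = [f"S{i+1}" for i in range(n_species)]
    species = [Species("Xin", True), Species("Xout", True)] + [
        Species(s) for s in internal
    ]
    reactions = [
        Reaction("Rin", {"Xin": Fraction(-1), internal[0]: Fraction(1)},
                 False, Fraction(0), Fraction(1)),
        Reaction("Rout", {internal[-1]: Fraction(-1), "Xout": Fraction(1)},
                 False, Fraction(0), None, objective_coeff=Fraction(1)),
    ]
    idx = 1
    # backbone chain keeps every species reachable from the input
    for a, b in zip(internal[:-1], internal[1:]):
        rev = rng.random() < p_reversible
        reactions.append(
            Reaction(f"R{idx}", {a: Fraction(-1), b: Fraction(rng.choice([1, 1, 2]))},
                     rev, None if rev else Fraction(0), None)
        )
        idx += 1
    while len(reactions) < n_reactions:
        a, b = rng.sample(internal, 2) if n_species >= 2 else (internal[0], internal[0])
        if a == b:
            break
        rev = rng.random() < p_reversible
        reactions.append(
            Reaction(
                f"R{idx}",
                {a: Fraction(-rng.choice([1, 1, 2])), b: Fraction(rng.choice([1, 1, 2]))},
                rev, None if rev else Fraction(0), None,
            )
        )
        idx += 1
    model = StoichModel(species, reactions, name=f"random")
    model.validate()
    return model


# ----------------------------------------------------------------------
# Tabular dialect
# ----------------------------------------------------------------------
#
# One reaction per line:
#   id : 2 A + B <=> C ; lb, ub ; obj ; gpr
# "-->" marks irreversible, "<=>" reversible; bounds/obj/gpr groups are
# optional.  Boundary species are declared up front with "@boundary X Y".
# Rationals are serialized as "p/q".

def read_model(path: str, format: str = "tabular") -> StoichModel:
    """Read a model from ``path`` in the named format ({tabular, sbml})."""
    if format == "sbml":
        from .sbml import read_sbml

        return read_sbml(path)
    if format != "tabular":
        raise ValueError(f"unknown model format {format!r}")
    with open(path) as fh:
        text = fh.read()
    model = _parse_tabular(text, name=path)
    model.validate()
    if not model.objective_ids():
        import warnings

        warnings.warn(
            f"{path}: no objective coefficient set; supply one at solve time",
            stacklevel=2,
        )
    return model


def write_model(model: StoichModel, path: str, format: str = "tabular") -> None:
    if format == "sbml":
        from .sbml import write_sbml

        write_sbml(model, path)
        return
    if format != "tabular":
        raise ValueError(f"unknown model format {format!r}")
    with open(path, "w") as fh:
        fh.write(dumps_tabular(model))


def dumps_tabular(model: StoichModel) -> str:
    lines = [f"# {model.name}"]
    boundary = [s.id for s in model.species if s.is_boundary]
    if boundary:
        lines.append("@boundary " + " ".join(boundary))
    internal_only = [s.id for s in model.species if not s.is_boundary]
    if internal_only:
        lines.append("@species " + " ".join(internal_only))
    for r in model.reactions:
        lhs = []
        rhs = []
        for sid, coeff in r.stoichiometry.items():
            if coeff < 0:
                lhs.append(_term(-coeff, sid))
            elif coeff > 0:
                rhs.append(_term(coeff, sid))
        arrow = "<=>" if r.reversible else "-->"
        lb = format_rational(r.lower_bound, inf_sign="-")
        ub = format_rational(r.upper_bound, inf_sign="+")
        parts = [
            f"{r.id} : {' + '.join(lhs)} {arrow} {' + '.join(rhs)}",
            f"{lb}, {ub}",
            format_rational(r.objective_coeff),
        ]
        if r.gpr:
            parts.append(r.gpr)
        lines.append(" ; ".join(parts))
    return "\n".join(lines) + "\n"


def _term(coeff: Fraction, sid: str) -> str:
    return sid if coeff == 1 else f"{format_rational(coeff)} {sid}"


def _parse_tabular(text: str, name: str = "model") -> StoichModel:
    boundary: list[str] = []
    declared: list[str] = []
    reactions: list[Reaction] = []
    seen_species: dict[str, None] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@boundary"):
            boundary.extend(line.split()[1:])
            continue
        if line.startswith("@species"):
            declared.extend(line.split()[1:])
            continue
        try:
            reactions.append(_parse_reaction_line(line, seen_species))
        except ModelFormatError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise ModelFormatError(f"{name}:{lineno}: {exc}") from exc
    order: list[str] = []
    for sid in boundary + declared + list(seen_species):
        if sid not in order:
            order.append(sid)
    bset = set(boundary)
    species = [Species(sid, sid in bset) for sid in order]
    return StoichModel(species, reactions, name=name)


def _parse_reaction_line(line: str, seen_species: dict[str, None]) -> Reaction:
    head, _, rest = line.partition(":")
    rid = head.strip()
    if not rid or not rest:
        raise ModelFormatError(f"malformed reaction line {line!r}")
    groups = [g.strip() for g in rest.split(";")]
    eq = groups[0]
    if "<=>" in eq:
        reversible = True
        lhs_s, rhs_s = eq.split("<=>")
    elif "-->" in eq:
        reversible = False
        lhs_s, rhs_s = eq.split("-->")
    else:
        raise ModelFormatError(f"reaction {rid!r}: missing arrow ('-->' or '<=>')")
    stoich: dict[str, Fraction] = {}

    def add_side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            tokens = term.split()
            if not tokens:
                raise ModelFormatError(f"reaction {rid!r}: empty stoichiometry term")
            if len(tokens) == 1:
                coeff, sid = Fraction(1), tokens[0]
            elif len(tokens) == 2:
                coeff, sid = to_rational(tokens[0]), tokens[1]
            else:
                raise ModelFormatError(f"reaction {rid!r}: bad term {term.strip()!r}")
            stoich[sid] = stoich.get(sid, Fraction(0)) + sign * coeff
            seen_species.setdefault(sid, None)

    add_side(lhs_s, -1)
    add_side(rhs_s, +1)

    lb: Bound = None if reversible else Fraction(0)
    ub: Bound = None
    obj = Fraction(0)
    gpr = None
    if len(groups) > 1 and groups[1]:
        bounds = groups[1].split(",")
        if len(bounds) != 2:
            raise ModelFormatError(f"reaction {rid!r}: bounds must be 'lb, ub'")
        lb = parse_bound(bounds[0], lb)
        ub = parse_bound(bounds[1], ub)
    if len(groups) > 2 and groups[2]:
        obj = to_rational(groups[2])
    if len(groups) > 3 and groups[3]:
        gpr = groups[3]
    rxn = Reaction(rid, stoich, reversible, lb, ub, obj, gpr)
    rxn.validate()
    return rxn
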