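"""Secondary objectives: P_L, P_J, P_C, GPR costs, MILP/LP minimization."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

import fluxtope as ft
from fluxtope.objectives import (
    build_cost_vector,
    pathway_cost,
    pathway_flux_sum,
    pathway_length,
)
from fluxtope.polyhedra import iter_reconstructed_vertices

rational = st.fractions(min_value=-10, max_value=10)


class TestStatistics:
    @given(st.lists(rational, min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_length_counts_support(self, values):
        flux = ft.FluxVector({f"R{i}": v for i, v in enumerate(values)})
        assert pathway_length(flux) == sum(1 for v in values if v != 0)

    @given(st.lists(rational, min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_equal_cost_equals_flux_sum(self, values):
        flux = ft.FluxVector({f"R{i}": v for i, v in enumerate(values)})
        costs = ft.CostVector({f"R{i}": Fraction(1)
                               for i in range(len(values))}, "equal",
                              Fraction(1))
        assert pathway_cost(flux, costs) == pathway_flux_sum(flux)

    def test_flux_sum_is_absolute(self):
        flux = ft.FluxVector({"a": Fraction(1), "b": Fraction(-2),
                              "c": Fraction(0)})
        assert pathway_flux_sum(flux) == 3
        assert pathway_length(flux) == 2

    def test_weighted_cost(self):
        flux = ft.FluxVector({"a": Fraction(1), "b": Fraction(4)})
        costs = ft.CostVector({"a": Fraction(2), "b": Fraction(1)},
                              "average", Fraction(1))
        assert pathway_cost(flux, costs) == 6

    def test_missing_cost_entry(self):
        flux = ft.FluxVector({"a": Fraction(1)})
        costs = ft.CostVector({}, "average", Fraction(1))
        with pytest.raises(KeyError):
            pathway_cost(flux, costs)

    def test_float_threshold_mode(self):
        flux = ft.FluxVector({"a": Fraction(1, 10**12), "b": Fraction(1)})
        assert pathway_length(flux) == 2
        assert pathway_length(flux, zero_tol=1e-9) == 1


class TestCostVector:
    @pytest.fixture()
    def annotated(self, toy):
        model = toy.copy()
        model.get_reaction("R6").gpr = "p1 and p2"
        model.get_reaction("R7").gpr = "p1 or p2"
        return model

    lengths = {"p1": 100, "p2": 300}

    def test_and_rule_sums(self, annotated):
        cv = build_cost_vector(annotated, self.lengths, "min")
        assert cv["R6"] == 2  # (100+300)/200

    def test_or_rules(self, annotated):
        assert build_cost_vector(annotated, self.lengths, "min")["R7"] \
            == Fraction(1, 2)
        assert build_cost_vector(annotated, self.lengths, "max")["R7"] \
            == Fraction(3, 2)
        assert build_cost_vector(annotated, self.lengths, "average")["R7"] \
            == 1

    def test_unannotated_cost_one(self, annotated):
        cv = build_cost_vector(annotated, self.lengths, "average")
        assert cv["R1"] == 1

    def test_equal_rule_all_ones(self, annotated):
        cv = build_cost_vector(annotated, {}, "equal")
        assert all(c == 1 for c in cv.costs.values())

    def test_unknown_protein_listed(self, annotated):
        with pytest.raises(KeyError, match="p2"):
            build_cost_vector(annotated, {"p1": 100}, "min")

    def test_nested_expression(self, toy):
        model = toy.copy()
        model.get_reaction("R6").gpr = "(p1 and p2) or p3"
        cv = build_cost_vector(model, {"p1": 60, "p2": 60, "p3": 240}, "min")
        # corpus mean 120; min(60+60, 240) = 120 -> cost 1
        assert cv["R6"] == 1

    @given(st.lists(st.integers(min_value=1, max_value=1000),
                    min_size=2, max_size=2))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rule_ordering(self, toy, lens):
        model = toy.copy()
        model.get_reaction("R7").gpr = "p1 or p2"
        table = {"p1": lens[0], "p2": lens[1]}
        lo = build_cost_vector(model, table, "min")["R7"]
        mid = build_cost_vector(model, table, "average")["R7"]
        hi = build_cost_vector(model, table, "max")["R7"]
        assert lo <= mid <= hi


class TestPathwayLengthMinimization:
    def test_single_constraint_minimum_eleven(self, toy, z_star):
        result = ft.minimize_pathway_length(toy, z_star)
        assert result.optimal_value == 11
        assert len(result.witness_flux.support()) == 11
        assert result.witness_flux.is_steady_state(toy)

    def test_two_constraints_minimum_twelve(self, toy):
        model = toy.copy()
        model.get_reaction("R15").upper_bound = Fraction(1, 2)
        z = ft.solve_fba(model).objective_value
        assert z == 1
        result = ft.minimize_pathway_length(model, z)
        assert result.optimal_value == 12

    def test_extra_constraint_cannot_shorten(self, toy, z_star):
        base = ft.minimize_pathway_length(toy, z_star).optimal_value
        model = toy.copy()
        model.get_reaction("R15").upper_bound = Fraction(1, 2)
        tightened = ft.minimize_pathway_length(
            model, ft.solve_fba(model).objective_value).optimal_value
        assert tightened >= base

    def test_nonsplit_minimum_is_convex_combination(self, toy, z_star):
        """The shortest non-split optimal route is strictly shorter than
        every vertex: it mixes two vertices so opposed fluxes cancel."""
        space = ft.build_optimal_space(toy, z_star)
        result = ft.minimize_pathway_length(toy, z_star, space=space)
        vertex_lengths = [pathway_length(f)
                          for _, f in iter_reconstructed_vertices(space)]
        assert result.optimal_value == 11
        assert min(vertex_lengths) == 12
        assert result.n_optimal_vertices == 0
        from fluxtope.polyhedra import Decomposition, decompose_in_space

        res = decompose_in_space(space, result.witness_flux, toy, z_star)
        assert isinstance(res, Decomposition)
        assert sum(1 for a in res.alpha if a != 0) == 2
        assert all(g == 0 for g in res.gamma)

    def test_split_minimum_is_a_vertex(self, toy_split, z_star):
        sm = toy_split.model
        space = ft.build_optimal_space(sm, z_star)
        result = ft.minimize_pathway_length(sm, z_star, space=space)
        assert result.optimal_value == 11
        assert result.n_optimal_vertices >= 1

    @pytest.mark.parametrize("seed", [0, 3, 6, 9])
    def test_milp_matches_vertex_minimum_on_split_models(self, seed):
        """On split models the MILP minimum equals the brute-force minimum
        over enumerated vertices (support-minimal optima are vertices)."""
        model = ft.generate_random_model(3, 6, seed=seed)
        sm = ft.split_reversible(model).model
        z = ft.solve_fba(sm).objective_value
        space = ft.build_optimal_space(sm, z)
        result = ft.minimize_pathway_length(sm, z, space=space)
        vertex_min = min(pathway_length(f)
                         for _, f in iter_reconstructed_vertices(space))
        assert result.optimal_value == vertex_min


class TestLinearSecondary:
    def test_requires_split_model(self, toy, z_star):
        with pytest.raises(ValueError, match="split"):
            ft.minimize_linear_secondary(toy, z_star)

    def test_flux_sum_minimum_attained_by_vertex(self, toy_split, z_star):
        sm = toy_split.model
        space = ft.build_optimal_space(sm, z_star)
        result = ft.minimize_linear_secondary(sm, z_star, space=space)
        vertex_vals = [pathway_flux_sum(f)
                       for _, f in iter_reconstructed_vertices(space)]
        assert result.optimal_value == min(vertex_vals)
        assert result.n_optimal_vertices >= 1

    def test_generic_costs_single_minimizer(self, toy_split, z_star):
        sm = toy_split.model
        space = ft.build_optimal_space(sm, z_star)
        primes = [2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37,
                  41, 43, 47, 53, 59, 61, 67, 71, 73, 79, 83]
        costs = ft.CostVector(
            {rid: Fraction(p, 10) for rid, p in zip(sm.reaction_ids(), primes)},
            "average", Fraction(1))
        result = ft.minimize_linear_secondary(sm, z_star, costs, space)
        assert result.n_optimal_vertices == 1

    def test_zero_costs_trivial(self, toy_split, z_star):
        sm = toy_split.model
        costs = ft.CostVector({r: Fraction(0) for r in sm.reaction_ids()},
                              "average", Fraction(1))
        result = ft.minimize_linear_secondary(sm, z_star, costs)
        assert result.optimal_value == 0


class TestVertexStatistics:
    def test_toy_split_table(self, toy_split, z_star):
        sm = toy_split.model
        space = ft.build_optimal_space(sm, z_star)
        costs = build_cost_vector(sm, {}, "equal")
        table = ft.vertex_statistics(space, costs)
        assert len(table) == 12
        assert table["P_L"].min() == 11
        assert (table["P_C"] == table["P_J"]).all()

    def test_single_vertex_space(self):
        model = ft.generate_random_model(2, 3, seed=1)
        sol = ft.solve_fba(model)
        space = ft.build_optimal_space(model, sol.objective_value)
        table = ft.vertex_statistics(space)
        assert len(table) == max(ft.count_vertices(space)[0], 1)
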