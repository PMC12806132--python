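import numpy as np
import pandas as pd
import pytest

from omicflux.eflux import (
    MediumSpec,
    assign_eflux_bounds,
    evaluate_gpr_minsum,
    fluxome_for_cohort,
    solve_fba,
)
from omicflux.expression import ExpressionMatrix, normalize_reference_minmax
from omicflux.gsmm import make_irreversible, parse_gpr

from conftest import build_parallel_model, random_gpr


def oracle_minsum(ast, expr, missing_policy="skip"):
    """Independent brute-force evaluator: flatten to nested tuples, reduce."""

    def to_tuple(node):
        if node.kind == "GENE":
            return ("G", node.gene_id)
        return (node.kind, tuple(to_tuple(c) for c in node.children))

    def reduce(tup):
        tag = tup[0]
        if tag == "G":
            if tup[1] in expr:
                return float(expr[tup[1]])
            return 0.0 if missing_policy == "zero" else None
        vals = [reduce(c) for c in tup[1]]
        vals = [v for v in vals if v is not None]
        if not vals:
            return None
        return min(vals) if tag == "AND" else sum(vals)

    return reduce(to_tuple(ast))


class TestEvaluateGprMinsum:
    def test_and_is_min(self):
        ast = parse_gpr("g1 and g2")
        assert evaluate_gpr_minsum(ast, {"g1": 0.2, "g2": 0.7}) == pytest.approx(0.2)

    def test_or_is_sum(self):
        ast = parse_gpr("g1 or g2")
        assert evaluate_gpr_minsum(ast, {"g1": 0.2, "g2": 0.7}) == pytest.approx(0.9)

    def test_nested(self):
        ast = parse_gpr("(gA and gB) or (gC and gD)")
        expr = {"gA": 0.5, "gB": 0.3, "gC": 0.4, "gD": 0.1}
        expected = oracle_minsum(ast, expr)
        assert expected == pytest.approx(0.4)  # min(.5,.3) + min(.4,.1)
        assert evaluate_gpr_minsum(ast, expr) == pytest.approx(expected)

    def test_missing_skip_drops_gene(self):
        ast = parse_gpr("g1 and g2")
        assert evaluate_gpr_minsum(ast, {"g1": 0.4}, "skip") == pytest.approx(0.4)

    def test_missing_zero(self):
        ast = parse_gpr("g1 and g2")
        assert evaluate_gpr_minsum(ast, {"g1": 0.4}, "zero") == 0.0

    def test_all_absent_skip_is_none(self):
        ast = parse_gpr("g1 or g2")
        assert evaluate_gpr_minsum(ast, {}, "skip") is None

    def test_unknown_policy(self):
        with pytest.raises(ValueError, match="missing_policy"):
            evaluate_gpr_minsum(parse_gpr("g1"), {}, "whatever")

    @pytest.mark.parametrize("missing_policy", ["skip", "zero"])
    def test_oracle_agreement_random_asts(self, missing_policy):
        rng = np.random.default_rng(123)
        genes = [f"g{i}" for i in range(12)]
        for _ in range(1000):
            ast = random_gpr(rng, genes, max_depth=5)
            present = [g for g in genes if rng.random() < 0.7]
            expr = {g: float(rng.uniform(0, 1)) for g in present}
            got = evaluate_gpr_minsum(ast, expr, missing_policy)
            want = oracle_minsum(ast, expr, missing_policy)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-12)


class TestAssignEfluxBounds:
    def _expr(self, mapping):
        df = pd.DataFrame({"s": mapping})
        return ExpressionMatrix(values=df, layer="TX")

    def test_proportional_bound(self, chain_model):
        split, _ = make_irreversible(chain_model)
        expr = self._expr({"g1": 0.5, "g2": 0.8})
        constrained, n = assign_eflux_bounds(split, expr, "s", vmax=1000.0)
        assert constrained.get_reaction("A2B").upper_bound == pytest.approx(500.0)
        assert n == 1

    def test_or_sum_capped_at_vmax(self):
        from conftest import build_chain_model

        model = build_chain_model()
        model.get_reaction("A2B").gpr = parse_gpr("g1 or g2")
        expr = self._expr({"g1": 0.9, "g2": 0.8})
        constrained, _ = assign_eflux_bounds(model, expr, "s", vmax=1000.0)
        assert constrained.get_reaction("A2B").upper_bound == pytest.approx(1000.0)

    def test_zero_score_blocks_growth(self, chain_model):
        expr = self._expr({"g1": 0.0, "g2": 0.5})
        constrained, _ = assign_eflux_bounds(chain_model, expr, "s")
        res = solve_fba(constrained)
        assert res.optimal
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_requires_irreversible(self, chain_model):
        model = chain_model.copy()
        model.get_reaction("A2B").lower_bound = -5
        with pytest.raises(ValueError, match="irreversible"):
            assign_eflux_bounds(model, self._expr({"g1": 1.0}), "s")

    def test_constrained_count(self, toy_model, toy_cohort):
        split, _ = make_irreversible(toy_model)
        expr = normalize_reference_minmax(toy_cohort.tx, "PKM")
        with_gpr = sum(1 for r in split.reactions if r.gpr is not None)
        _, n = assign_eflux_bounds(split, expr, expr.sample_ids[0])
        assert n == with_gpr  # every model gene is present in the cohort

    def test_medium_closes_disallowed_uptake(self, toy_model):
        split, _ = make_irreversible(toy_model)
        expr = self._expr({g: 1.0 for g in toy_model.genes})
        medium = MediumSpec(allowed_uptake=frozenset(), uptake_limit=5.0)
        constrained, _ = assign_eflux_bounds(split, expr, "s", medium=medium)
        res = solve_fba(constrained)
        assert res.optimal
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_medium_opens_allowed_uptake(self, toy_model):
        split, _ = make_irreversible(toy_model)
        expr = self._expr({g: 1.0 for g in toy_model.genes})
        medium = MediumSpec(allowed_uptake=frozenset({"EX_glc"}), uptake_limit=5.0)
        constrained, _ = assign_eflux_bounds(split, expr, "s", medium=medium)
        res = solve_fba(constrained)
        assert res.optimal
        assert res.objective_value == pytest.approx(5.0)

    def test_uptake_limit_must_be_positive(self):
        with pytest.raises(ValueError, match="uptake_limit"):
            MediumSpec(allowed_uptake=frozenset(), uptake_limit=0.0)


class TestSolveFba:
    def test_bottleneck_chain(self, chain_model):
        res = solve_fba(chain_model)
        assert res.optimal
        assert res.objective_value == pytest.approx(5.0)

    def test_all_bounds_zero(self, chain_model):
        model = chain_model.copy()
        for rxn in model.reactions:
            rxn.lower_bound = rxn.upper_bound = 0.0
        res = solve_fba(model)
        assert res.optimal
        assert res.objective_value == pytest.approx(0.0)
        assert np.allclose(res.fluxes.to_numpy(), 0.0)

    def test_parallel_routes(self, parallel_model):
        res = solve_fba(parallel_model)
        assert res.optimal
        assert res.objective_value == pytest.approx(7.0)

    def test_infeasible_reported_not_silent(self, chain_model):
        model = chain_model.copy()
        # force net production of A with no outlet capacity
        model.get_reaction("EX_A").lower_bound = 8.0
        model.get_reaction("EX_A").upper_bound = 8.0
        model.get_reaction("A2B").upper_bound = 5.0
        model.get_reaction("A2B").lower_bound = 0.0
        res = solve_fba(model)
        assert not res.optimal
        assert res.status in ("infeasible", "error")
        assert len(res.fluxes) == 0

    def test_mass_balance_and_bounds(self, parallel_model):
        res = solve_fba(parallel_model)
        balance = {}
        for rid, v in res.fluxes.items():
            rxn = parallel_model.get_reaction(rid)
            assert rxn.lower_bound - 1e-9 <= v <= rxn.upper_bound + 1e-9
            for met, coeff in rxn.stoichiometry.items():
                balance[met] = balance.get(met, 0.0) + coeff * v
        assert max(abs(b) for b in balance.values()) <= 1e-6

    def test_monotone_in_upper_bound(self):
        objs = []
        for ub in (1.0, 2.0, 3.0, 5.0):
            model = build_parallel_model(ub1=ub, ub2=4.0)
            objs.append(solve_fba(model).objective_value)
        assert objs == sorted(objs)


class TestFluxomeForCohort:
    @pytest.fixture
    def cohort_inputs(self, toy_model, toy_cohort, toy_design):
        split, _ = make_irreversible(toy_model)
        expr = normalize_reference_minmax(toy_cohort.tx, "PKM")
        return split, expr, toy_design.medium()

    def test_identical_samples_identical_columns(self, toy_model, toy_design):
        split, _ = make_irreversible(toy_model)
        genes = sorted(toy_model.genes)
        df = pd.DataFrame(
            {"a": [0.5] * len(genes), "b": [0.5] * len(genes)}, index=genes
        )
        expr = ExpressionMatrix(values=df, layer="TX")
        flux = fluxome_for_cohort(split, expr, medium=toy_design.medium())
        np.testing.assert_array_equal(
            flux.values["a"].to_numpy(), flux.values["b"].to_numpy()
        )

    def test_cohort_all_optimal(self, cohort_inputs):
        split, expr, medium = cohort_inputs
        flux = fluxome_for_cohort(split, expr, medium=medium)
        assert flux.failed_samples == []
        assert flux.values.shape == (len(split.reactions), len(expr.sample_ids))

    def test_mass_balance_every_column(self, cohort_inputs):
        split, expr, medium = cohort_inputs
        flux = fluxome_for_cohort(split, expr, medium=medium)
        S = np.zeros((len(split.metabolites), len(split.reactions)))
        met_index = {m.id: i for i, m in enumerate(split.metabolites)}
        for j, rxn in enumerate(split.reactions):
            for met, coeff in rxn.stoichiometry.items():
                S[met_index[met], j] = coeff
        imbalance = np.abs(S @ flux.values.to_numpy())
        assert imbalance.max() <= 1e-6

    def test_downregulated_pathway_has_lower_flux(self, toy_model, toy_design):
        split, _ = make_irreversible(toy_model)
        genes = sorted(toy_model.genes)
        pwy2_genes = {
            g
            for r in toy_model.reactions
            if r.subsystem == "PWY2" and r.gpr
            for g in r.gpr.genes()
        }
        # keep total pathway capacity below the uptake limit so the
        # expression bounds (not the shared uptake) are binding
        high = {g: 0.1 for g in genes}
        low = {g: (0.02 if g in pwy2_genes else 0.1) for g in genes}
        expr = ExpressionMatrix(
            values=pd.DataFrame({"high": high, "low": low}), layer="TX"
        )
        flux = fluxome_for_cohort(split, expr, medium=toy_design.medium())
        pwy2_rxns = [r.id for r in split.reactions if r.subsystem == "PWY2"]
        total_high = flux.values.loc[pwy2_rxns, "high"].sum()
        total_low = flux.values.loc[pwy2_rxns, "low"].sum()
        assert total_low < total_high

    def test_expression_scaling_scales_objective(self, toy_model, toy_design):
        """Homogeneous LP: scaling all scores by k scales the optimum by k."""
        split, _ = make_irreversible(toy_model)
        genes = sorted(toy_model.genes)
        # below uptake saturation, the LP is homogeneous in the bounds
        base = {g: 0.2 for g in genes}
        objs = {}
        for k in (0.25, 0.5, 1.0):
            df = pd.DataFrame({"s": {g: v * k for g, v in base.items()}})
            expr = ExpressionMatrix(values=df, layer="TX")
            flux = fluxome_for_cohort(split, expr, medium=toy_design.medium())
            objs[k] = flux.objective_values["s"]
        assert objs[0.5] == pytest.approx(0.5 * objs[1.0], rel=1e-9)
        assert objs[0.25] == pytest.approx(0.25 * objs[1.0], rel=1e-9)

    def test_infeasible_sample_recorded_run_continues(self, chain_model):
        model = chain_model.copy()
        model.get_reaction("EX_A").lower_bound = 8.0
        model.get_reaction("EX_A").upper_bound = 8.0
        # sample "bad" blocks the only outlet -> infeasible; "ok" is fine
        df = pd.DataFrame(
            {"bad": {"g1": 0.0, "g2": 0.0}, "ok": {"g1": 1.0, "g2": 1.0}}
        )
        expr = ExpressionMatrix(values=df, layer="TX")
        flux = fluxome_for_cohort(model, expr)
        assert flux.failed_samples == ["bad"]
        assert flux.solver_status["ok"] == "optimal"
        assert flux.as_expression().sample_ids == ["ok"]
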