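import numpy as np
import pandas as pd
import pytest

from omicflux.expression import ExpressionMatrix
from omicflux.gsmm import MetabolicModel, Metabolite, Reaction, parse_gpr
from omicflux.synthetic import SyntheticDesign, make_cohort, make_toy_model


def build_chain_model():
    """EX -> A -> B -> biomass bottleneck chain (bounds 10 / 5 / 1000)."""
    mets = [Metabolite("A"), Metabolite("B")]
    reactions = [
        Reaction(id="EX_A", stoichiometry={"A": 1.0}, lower_bound=0, upper_bound=10),
        Reaction(
            id="A2B",
            stoichiometry={"A": -1.0, "B": 1.0},
            lower_bound=0,
            upper_bound=5,
            gpr=parse_gpr("g1 and g2"),
            subsystem="chain",
        ),
        Reaction(
            id="BIOMASS", stoichiometry={"B": -1.0}, lower_bound=0, upper_bound=1000
        ),
    ]
    return MetabolicModel(metabolites=mets, reactions=reactions, objective_id="BIOMASS")


def build_parallel_model(ub1=3.0, ub2=4.0):
    """Two parallel routes (ub1, ub2) feeding biomass."""
    mets = [Metabolite("A"), Metabolite("B")]
    reactions = [
        Reaction(id="EX_A", stoichiometry={"A": 1.0}, lower_bound=0, upper_bound=1000),
        Reaction(
            id="R1", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0, upper_bound=ub1
        ),
        Reaction(
            id="R2", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0, upper_bound=ub2
        ),
        Reaction(
            id="BIOMASS", stoichiometry={"B": -1.0}, lower_bound=0, upper_bound=1000
        ),
    ]
    return MetabolicModel(metabolites=mets, reactions=reactions, objective_id="BIOMASS")


@pytest.fixture
def chain_model():
    return build_chain_model()


@pytest.fixture
def parallel_model():
    return build_parallel_model()


@pytest.fixture(scope="session")
def toy_design():
    return SyntheticDesign(
        classes=(("N", 12), ("C", 12)),
        planted_effects=(("C", "PWY2", "down", 0.2),),
        seed=7,
    )


@pytest.fixture(scope="session")
def toy_model(toy_design):
    return make_toy_model(toy_design)


@pytest.fixture(scope="session")
def toy_cohort(toy_design, toy_model):
    return make_cohort(toy_design, toy_model)


@pytest.fixture
def small_expr():
    df = pd.DataFrame(
        {
            "s1": [10.0, 50.0, 100.0, 200.0],
            "s2": [5.0, 30.0, 80.0, 40.0],
        },
        index=["gA", "gB", "PKM", "gC"],
    )
    return ExpressionMatrix(values=df, layer="TX")


def random_gpr(rng, genes, depth=0, max_depth=4):
    """Random AST over the given gene pool (independent of parse_gpr)."""
    from omicflux.gsmm import GprAst

    if depth >= max_depth or rng.random() < 0.35:
        return GprAst("GENE", gene_id=str(rng.choice(genes)))
    kind = "AND" if rng.random() < 0.5 else "OR"
    n_children = int(rng.integers(2, 4))
    return GprAst(
        kind,
        children=tuple(
            random_gpr(rng, genes, depth + 1, max_depth) for _ in range(n_children)
        ),
    )
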