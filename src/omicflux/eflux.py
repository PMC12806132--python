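"""Expression-constrained flux balance analysis (E-flux with minSum GPR scores).

Normalized expression in [0, 1] is converted to per-reaction upper bounds:
the GPR score of a reaction takes the minimum over AND-connected genes
(enzyme complexes) and the sum over OR-connected genes (isozymes), capped at
1, and scales a global flux ceiling ``vmax``.  Growth is then maximized by
linear programming (HiGHS via scipy) per sample, yielding a reactions x
samples fluxome matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

from .expression import ExpressionMatrix
from .gsmm import GprAst, MetabolicModel

__all__ = [
    "MediumSpec",
    "FBAResult",
    "FluxMatrix",
    "evaluate_gpr_minsum",
    "assign_eflux_bounds",
    "solve_fba",
    "fluxome_for_cohort",
    "DEFAULT_VMAX",
]

logger = logging.getLogger(__name__)

DEFAULT_VMAX = 1000.0
DEFAULT_UPTAKE_LIMIT = 10.0

MASS_BALANCE_TOL = 1e-6


@dataclass(frozen=True)
class MediumSpec:
    """Exchange reactions whose uptake direction is open, and the cap.

    ``allowed_uptake`` holds exchange reaction ids of the *original*
    (pre-split) model; split uptake halves are matched through their parent
    id.  Uptake through every other exchange is closed; secretion is always
    left open.
    """

    allowed_uptake: frozenset[str]
    uptake_limit: float = DEFAULT_UPTAKE_LIMIT

    def __post_init__(self) -> None:
        if self.uptake_limit <= 0:
            raise ValueError(f"uptake_limit must be > 0, got {self.uptake_limit}")
        object.__setattr__(self, "allowed_uptake", frozenset(self.allowed_uptake))


def evaluate_gpr_minsum(
    gpr: GprAst,
    expr_for_sample: dict,
    missing_policy: str = "skip",
) -> Optional[float]:
    """minSum score of a GPR rule under one sample's expression.

    GENE leaves evaluate to their expression value; AND nodes to the minimum
    of their children; OR nodes to the sum.  Genes absent from the map are
    dropped from their parent's aggregation (``missing_policy="skip"``) or
    treated as 0 (``"zero"``).  Returns ``None`` when every leaf is absent
    under ``skip`` — i.e. no expression constraint applies.
    """
    if missing_policy not in ("skip", "zero"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if gpr.kind == "GENE":
        if gpr.gene_id in expr_for_sample:
            return float(expr_for_sample[gpr.gene_id])
        return 0.0 if missing_policy == "zero" else None
    scores = [
        evaluate_gpr_minsum(child, expr_for_sample, missing_policy)
        for child in gpr.children
    ]
    present = [s for s in scores if s is not None]
    if not present:
        return None
    if gpr.kind == "AND":
        return min(present)
    return sum(present)


def assign_eflux_bounds(
    model: MetabolicModel,
    expr: ExpressionMatrix,
    sample: str,
    vmax: float = DEFAULT_VMAX,
    medium: Optional[MediumSpec] = None,
    missing_policy: str = "skip",
) -> tuple[MetabolicModel, int]:
    """Per-sample expression-constrained copy of an irreversible model.

    Every GPR-carrying reaction with a defined minSum score ``a`` gets
    bounds ``[0, min(a, 1) * vmax]``; reactions without a GPR (or with all
    genes absent under ``skip``) keep their defaults.  When a medium is
    given, uptake-direction exchange halves are capped at ``uptake_limit``
    if their (parent) id is allowed and closed otherwise.

    Returns the constrained copy and the number of expression-constrained
    reactions.
    """
    if not model.is_irreversible:
        raise ValueError(
            "assign_eflux_bounds requires an irreversible model; call "
            "make_irreversible first"
        )
    expr_map = expr.sample(sample)
    out = model.copy()
    n_constrained = 0
    for rxn in out.reactions:
        if rxn.is_exchange and medium is not None:
            coeff = next(iter(rxn.stoichiometry.values()))
            if coeff > 0:  # produces its metabolite: uptake direction
                key = rxn.parent_id or rxn.id
                allowed = key in medium.allowed_uptake or rxn.id in medium.allowed_uptake
                rxn.lower_bound = 0.0
                rxn.upper_bound = medium.uptake_limit if allowed else 0.0
            continue
        if rxn.gpr is None:
            continue
        score = evaluate_gpr_minsum(rxn.gpr, expr_map, missing_policy)
        if score is None:
            continue
        rxn.lower_bound = 0.0
        rxn.upper_bound = min(score, 1.0) * vmax
        n_constrained += 1
    return out, n_constrained


@dataclass
class FBAResult:
    fluxes: pd.Series
    objective_value: float
    status: str
    message: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _build_lp(model: MetabolicModel):
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    n_mets, n_rxns = len(met_index), len(model.reactions)
    S = lil_matrix((n_mets, n_rxns))
    for j, rxn in enumerate(model.reactions):
        for met, coeff in rxn.stoichiometry.items():
            S[met_index[met], j] = coeff
    c = np.zeros(n_rxns)
    c[model.reaction_ids.index(model.objective_id)] = 1.0
    return S.tocsr(), c


def solve_fba(model: MetabolicModel) -> FBAResult:
    """Maximize the objective flux subject to S.v = 0 and bounds.

    Deterministic HiGHS dual simplex; mass balance of optimal solutions is
    verified to ``1e-6``.  Infeasible or failed solves return a result with
    ``status != "optimal"`` and no silent zero vector.
    """
    S, c = _build_lp(model)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res = linprog(
        -c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs-ds",
    )
    if not res.success:
        status = "infeasible" if res.status == 2 else "error"
        return FBAResult(
            fluxes=pd.Series(dtype=float),
            objective_value=float("nan"),
            status=status,
            message=res.message,
        )
    v = res.x
    imbalance = np.abs(S @ v).max() if S.shape[0] else 0.0
    if imbalance > MASS_BALANCE_TOL:
        return FBAResult(
            fluxes=pd.Series(dtype=float),
            objective_value=float("nan"),
            status="error",
            message=f"mass-balance violation {imbalance:.3e}",
        )
    return FBAResult(
        fluxes=pd.Series(v, index=model.reaction_ids),
        objective_value=float(c @ v),
        status="optimal",
        message=res.message,
    )


@dataclass
class FluxMatrix:
    """Reactions x samples optimal flux values with per-sample diagnostics."""

    values: pd.DataFrame
    objective_values: pd.Series
    solver_status: pd.Series
    n_constrained: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    @property
    def reaction_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def failed_samples(self) -> list[str]:
        return self.solver_status[self.solver_status != "optimal"].index.tolist()

    def as_expression(self) -> ExpressionMatrix:
        """The fluxome as an omic layer (JX) for downstream stages.

        Columns of failed samples are dropped.
        """
        keep = [s for s in self.sample_ids if s not in self.failed_samples]
        df = self.values[keep]
        return ExpressionMatrix(values=df, layer="JX")

    def to_tsv(self, path, sep: str = "\t") -> None:
        df = self.values.copy()
        df.index.name = "reaction_id"
        df.to_csv(path, sep=sep, lineterminator="\n")

    def metadata(self) -> dict:
        return {
            "objective_values": {
                s: (None if not np.isfinite(v) else float(v))
                for s, v in self.objective_values.items()
            },
            "solver_status": self.solver_status.to_dict(),
            "n_constrained": {k: int(v) for k, v in self.n_constrained.items()},
            "n_failed": len(self.failed_samples),
        }


def fluxome_for_cohort(
    model: MetabolicModel,
    expr: ExpressionMatrix,
    vmax: float = DEFAULT_VMAX,
    medium: Optional[MediumSpec] = None,
    samples: Optional[Sequence[str]] = None,
    missing_policy: str = "skip",
) -> FluxMatrix:
    """Per-sample expression-constrained FBA over a cohort.

    One optimal flux column per sample; infeasible samples are recorded and
    the run continues.  Deterministic for fixed inputs and solver.
    """
    if samples is None:
        samples = expr.sample_ids
    columns: dict[str, np.ndarray] = {}
    objectives: dict[str, float] = {}
    statuses: dict[str, str] = {}
    constrained: dict[str, int] = {}
    n_rxns = len(model.reactions)
    for sample in samples:
        constrained_model, n_con = assign_eflux_bounds(
            model, expr, sample, vmax=vmax, medium=medium, missing_policy=missing_policy
        )
        result = solve_fba(constrained_model)
        constrained[sample] = n_con
        statuses[sample] = result.status
        objectives[sample] = result.objective_value
        if result.optimal:
            columns[sample] = result.fluxes.to_numpy()
        else:
            logger.warning("sample %s: FBA %s (%s)", sample, result.status, result.message)
            columns[sample] = np.full(n_rxns, np.nan)
    values = pd.DataFrame(columns, index=model.reaction_ids)
    flux = FluxMatrix(
        values=values,
        objective_values=pd.Series(objectives),
        solver_status=pd.Series(statuses),
        n_constrained=pd.Series(constrained),
    )
    if flux.failed_samples:
        logger.warning(
            "%d of %d samples infeasible: %s",
            len(flux.failed_samples),
            len(samples),
            flux.failed_samples,
        )
    return flux
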