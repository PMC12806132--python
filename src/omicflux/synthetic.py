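"""Synthetic inputs with planted structure: toy metabolic model and cohorts.

Everything the pipeline consumes can be generated here: a small metabolic
network of parallel pathway chains (each a labeled subsystem with mixed
AND/OR gene rules), and multi-omic cohorts (TX/GX/PX plus metadata) in
which chosen pathways are up- or down-regulated in chosen classes.  All
randomness flows through one seeded generator, so outputs are bit-identical
for a fixed design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .eflux import MediumSpec, assign_eflux_bounds, solve_fba
from .expression import DEFAULT_REFERENCE_GENE, ExpressionMatrix
from .gsmm import (
    GprAst,
    MetabolicModel,
    Metabolite,
    Reaction,
    make_irreversible,
    parse_gpr,
)

__all__ = ["SyntheticDesign", "CohortBundle", "make_toy_model", "make_cohort"]

#: Raw expression level of the planted reference gene (well above the
#: log-normal baseline, so clipping after normalization is rare).
REFERENCE_LEVEL = 500.0

TX_MEANLOG = 3.0
TX_SDLOG = 0.8

NO_STAGE = "-"


@dataclass
class SyntheticDesign:
    """Knobs for the toy model and cohort generator."""

    n_pathways: int = 4
    reactions_per_pathway: int = 4
    genes_per_reaction: int = 3
    classes: tuple[tuple[str, int], ...] = (("N", 30), ("C", 30))
    planted_effects: tuple[tuple[str, str, str, float], ...] = ()
    noise_sd: float = 0.3
    imbalance: Optional[dict[str, float]] = None
    seed: int = 0
    n_nuisance_genes: int = 40
    n_silent_genes: int = 6
    n_gx_markers: int = 10
    px_fraction: float = 0.6
    stages: tuple[str, ...] = ("S1", "S2", "S3")
    uptake_limit: float = 1000.0
    reference_gene: str = DEFAULT_REFERENCE_GENE

    def __post_init__(self) -> None:
        if self.n_pathways < 1 or self.reactions_per_pathway < 1:
            raise ValueError("need at least one pathway with one reaction")
        if not 1 <= self.genes_per_reaction <= 3:
            raise ValueError("genes_per_reaction must be 1..3")
        labels = [lab for lab, _ in self.classes]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate class labels: {labels}")
        if self.imbalance is not None:
            total = sum(n for _, n in self.classes)
            self.classes = tuple(
                (lab, max(4, round(total * self.imbalance.get(lab, 0))))
                for lab, _ in self.classes
            )
        for lab, n in self.classes:
            if n < 4:
                raise ValueError(f"class {lab!r}: needs >= 4 samples, got {n}")
        pathway_names = {f"PWY{i + 1}" for i in range(self.n_pathways)}
        for cls, pwy, direction, mult in self.planted_effects:
            if cls not in labels:
                raise ValueError(f"planted effect targets unknown class {cls!r}")
            if pwy not in pathway_names:
                raise ValueError(f"planted effect targets unknown pathway {pwy!r}")
            if mult <= 0:
                raise ValueError(f"effect multiplier must be > 0, got {mult}")
            if direction == "down" and mult >= 1:
                raise ValueError(f"down effect needs multiplier < 1, got {mult}")
            if direction == "up" and mult <= 1:
                raise ValueError(f"up effect needs multiplier > 1, got {mult}")
            if direction not in ("up", "down"):
                raise ValueError(f"unknown effect direction {direction!r}")

    @property
    def pathway_names(self) -> list[str]:
        return [f"PWY{i + 1}" for i in range(self.n_pathways)]

    def medium(self) -> MediumSpec:
        return MediumSpec(
            allowed_uptake=frozenset({"EX_glc"}), uptake_limit=self.uptake_limit
        )

    def to_dict(self) -> dict:
        return {
            "n_pathways": self.n_pathways,
            "reactions_per_pathway": self.reactions_per_pathway,
            "genes_per_reaction": self.genes_per_reaction,
            "classes": [list(c) for c in self.classes],
            "planted_effects": [list(e) for e in self.planted_effects],
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "n_nuisance_genes": self.n_nuisance_genes,
            "n_silent_genes": self.n_silent_genes,
            "n_gx_markers": self.n_gx_markers,
            "px_fraction": self.px_fraction,
            "stages": list(self.stages),
            "uptake_limit": self.uptake_limit,
            "reference_gene": self.reference_gene,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheticDesign":
        kwargs = dict(doc)
        if "classes" in kwargs:
            kwargs["classes"] = tuple((str(l), int(n)) for l, n in kwargs["classes"])
        if "planted_effects" in kwargs:
            kwargs["planted_effects"] = tuple(
                (str(c), str(p), str(d), float(m))
                for c, p, d, m in kwargs["planted_effects"]
            )
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)


# GPR shapes cycled along each chain; index capped by genes_per_reaction.
_GPR_PATTERNS = (
    "{a}",
    "{a} and {b}",
    "{a} or {b}",
    "({a} and {b}) or {c}",
)


def _gpr_for(p: int, i: int, max_genes: int) -> GprAst:
    if max_genes == 1:
        pattern = _GPR_PATTERNS[0]
    elif max_genes == 2:
        pattern = _GPR_PATTERNS[(p + i) % 3]
    else:
        pattern = _GPR_PATTERNS[(p + i) % 4]
    names = {k: f"g{p + 1}_{i + 1}{k}" for k in ("a", "b", "c")}
    return parse_gpr(pattern.format(**names))


def make_toy_model(design: SyntheticDesign) -> MetabolicModel:
    """Parallel pathway chains from a glucose hub to a growth sink.

    Each pathway is a linear chain of GPR-carrying reactions forming one
    subsystem; all chains start from the uptake hub and feed the biomass
    precursor consumed by the growth (objective) reaction.  The glucose
    exchange is reversible (so irreversibilization is exercised) and the
    model is verified feasible with all-ones expression.
    """
    mets = [Metabolite("glc_c", name="hub carbon", compartment="c")]
    reactions: list[Reaction] = [
        Reaction(
            id="EX_glc",
            stoichiometry={"glc_c": -1.0},
            lower_bound=-1000.0,
            upper_bound=1000.0,
            subsystem="Exchange",
            name="glucose exchange",
        )
    ]
    mets.append(Metabolite("bm_c", name="biomass precursor", compartment="c"))
    for p in range(design.n_pathways):
        pwy = design.pathway_names[p]
        chain = design.reactions_per_pathway
        for i in range(chain):
            src = "glc_c" if i == 0 else f"m{p + 1}_{i}"
            dst = "bm_c" if i == chain - 1 else f"m{p + 1}_{i + 1}"
            if dst != "bm_c":
                mets.append(Metabolite(dst, compartment="c"))
            reactions.append(
                Reaction(
                    id=f"R{p + 1}_{i + 1}",
                    stoichiometry={src: -1.0, dst: 1.0},
                    lower_bound=0.0,
                    upper_bound=1000.0,
                    subsystem=pwy,
                    gpr=_gpr_for(p, i, design.genes_per_reaction),
                )
            )
    reactions.append(
        Reaction(
            id="GROWTH",
            stoichiometry={"bm_c": -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            subsystem="Growth",
            name="growth sink",
        )
    )
    model = MetabolicModel(
        metabolites=mets, reactions=reactions, objective_id="GROWTH", id="toy"
    )

    # feasibility guarantee: all-ones expression must support growth
    split, _ = make_irreversible(model)
    ones = ExpressionMatrix(
        values=pd.DataFrame(
            {"check": {g: 1.0 for g in sorted(model.genes)}}
        ),
        layer="TX",
    )
    constrained, _ = assign_eflux_bounds(
        split, ones, "check", vmax=1000.0, medium=design.medium()
    )
    result = solve_fba(constrained)
    if not result.optimal or result.objective_value <= 0:
        raise AssertionError(
            f"toy model infeasible under all-ones expression: {result.status}"
        )
    return model


def pathway_genes(model: MetabolicModel) -> dict[str, set[str]]:
    """Genes appearing in each subsystem's GPR rules."""
    out: dict[str, set[str]] = {}
    for rxn in model.reactions:
        if rxn.subsystem and rxn.gpr is not None:
            out.setdefault(rxn.subsystem, set()).update(rxn.gpr.genes())
    return out


@dataclass
class CohortBundle:
    tx: ExpressionMatrix
    gx: ExpressionMatrix
    px: ExpressionMatrix
    metadata: pd.DataFrame
    gx_marker_genes: list[str] = field(default_factory=list)
    pathway_gene_map: dict[str, set[str]] = field(default_factory=dict)


def _stage_grade(stage: str, stages: Sequence[str]) -> float:
    if stage == NO_STAGE or stage not in stages:
        return 1.0
    return (list(stages).index(stage) + 1) / len(stages)


def make_cohort(design: SyntheticDesign, model: MetabolicModel) -> CohortBundle:
    """Multi-omic cohort with planted class structure.

    TX is log-normal baseline expression with multiplicative noise, the
    reference gene pinned high and constant, and planted effects applied
    multiplicatively to pathway genes of the target class (graded by stage,
    first stage weakest).  GX is copy-number-like integers in {0..4} with a
    planted set of class-biased marker genes.  PX covers a subset of genes
    with TX-correlated abundances plus independent noise.
    """
    rng = np.random.default_rng(design.seed)
    model_genes = sorted(model.genes)
    nuisance = [f"nuis_{i + 1}" for i in range(design.n_nuisance_genes)]
    silent = [f"silent_{i + 1}" for i in range(design.n_silent_genes)]
    genes = model_genes + nuisance + silent + [design.reference_gene]

    samples: list[str] = []
    conditions: list[str] = []
    subtypes: list[str] = []
    stage_col: list[str] = []
    for label, n in design.classes:
        for i in range(n):
            samples.append(f"{label}{i + 1:03d}")
            conditions.append("N" if label == "N" else "C")
            subtypes.append(label)
            if label == "N":
                stage_col.append(NO_STAGE)
            else:
                stage_col.append(design.stages[i % len(design.stages)])
    metadata = pd.DataFrame(
        {
            "sample_id": samples,
            "condition": conditions,
            "subtype": subtypes,
            "stage": stage_col,
        }
    )

    n_genes, n_samples = len(genes), len(samples)
    base_mean = rng.lognormal(TX_MEANLOG, TX_SDLOG, size=n_genes)
    noise = rng.lognormal(0.0, design.noise_sd, size=(n_genes, n_samples))
    tx = base_mean[:, None] * noise
    tx_df = pd.DataFrame(tx, index=genes, columns=samples)
    tx_df.loc[design.reference_gene] = REFERENCE_LEVEL
    # unexpressed genes pin the per-sample minimum at zero, as FPKM-like
    # data does; without them planted effects would shift the minimum and
    # leak into every other gene's normalized value
    if silent:
        tx_df.loc[silent] = 0.0

    pwy_genes = pathway_genes(model)
    gene_pos = {g: k for k, g in enumerate(genes)}
    for cls, pwy, _direction, mult in design.planted_effects:
        targets = [gene_pos[g] for g in sorted(pwy_genes.get(pwy, ()))]
        for col, (sample, label, stage) in enumerate(
            zip(samples, subtypes, stage_col)
        ):
            if label != cls:
                continue
            eff = mult ** _stage_grade(stage, design.stages)
            tx_df.iloc[targets, col] *= eff

    # GX: copy-number-like integers with class-biased markers
    gx = rng.binomial(4, 0.5, size=(n_genes, n_samples)).astype(float)
    gx_df = pd.DataFrame(gx, index=genes, columns=samples)
    marker_pool = nuisance if nuisance else model_genes
    n_markers = min(design.n_gx_markers, len(marker_pool))
    markers = sorted(
        rng.choice(marker_pool, size=n_markers, replace=False).tolist()
    )
    cancer_cols = [s for s, c in zip(samples, conditions) if c == "C"]
    if markers and cancer_cols:
        biased = rng.binomial(4, 0.85, size=(len(markers), len(cancer_cols)))
        gx_df.loc[markers, cancer_cols] = biased.astype(float)

    # PX: TX-correlated subset with independent multiplicative noise
    n_px = max(2, round(design.px_fraction * len(model_genes)))
    px_genes = sorted(rng.choice(model_genes, size=n_px, replace=False).tolist())
    px_noise = rng.lognormal(0.0, design.noise_sd, size=(len(px_genes), n_samples))
    px_df = tx_df.loc[px_genes] * px_noise

    return CohortBundle(
        tx=ExpressionMatrix(values=tx_df, layer="TX"),
        gx=ExpressionMatrix(values=gx_df, layer="GX"),
        px=ExpressionMatrix(values=px_df, layer="PX"),
        metadata=metadata,
        gx_marker_genes=markers,
        pathway_gene_map=pwy_genes,
    )
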