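"""Metabolic model core: stoichiometric network, GPR rules, irreversible form.

The model representation is deliberately minimal: stoichiometry, bounds,
subsystem labels and gene associations are all that downstream stages
(expression integration, FBA, enrichment) consume.  COBRA-style JSON is the
native interchange format; SBML Level 3 (FBC) is read through cobrapy when
it is installed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence, Union

__all__ = [
    "GprAst",
    "GprParseError",
    "ModelValidationError",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "parse_gpr",
    "read_model",
    "write_model",
    "make_irreversible",
]

DEFAULT_UPPER = 1000.0
DEFAULT_LOWER_REVERSIBLE = -1000.0

FORWARD_SUFFIX = "_f"
BACKWARD_SUFFIX = "_b"


class GprParseError(ValueError):
    """Raised when a gene-protein-reaction rule string is malformed."""


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GprAst:
    """Node of a boolean gene-association tree.

    ``kind`` is one of ``"GENE"``, ``"AND"`` or ``"OR"``.  Leaves carry a
    ``gene_id``; interior nodes carry at least two ``children``.
    """

    kind: str
    gene_id: Optional[str] = None
    children: tuple["GprAst", ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "GENE":
            if not self.gene_id:
                raise ValueError("GENE node requires a gene_id")
            if self.children:
                raise ValueError("GENE node cannot have children")
        elif self.kind in ("AND", "OR"):
            if self.gene_id is not None:
                raise ValueError(f"{self.kind} node cannot carry a gene_id")
            if len(self.children) < 2:
                raise ValueError(f"{self.kind} node requires >= 2 children")
        else:
            raise ValueError(f"unknown node kind {self.kind!r}")

    def genes(self) -> set[str]:
        """All gene identifiers appearing in the rule."""
        if self.kind == "GENE":
            return {self.gene_id}  # type: ignore[arg-type]
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out

    def to_string(self) -> str:
        """Infix rendering; re-parsing it yields an equal AST."""
        if self.kind == "GENE":
            return self.gene_id  # type: ignore[return-value]
        op = " and " if self.kind == "AND" else " or "
        parts = []
        for child in self.children:
            text = child.to_string()
            # OR under AND needs parentheses; AND under OR does not, but we
            # parenthesize every non-leaf child for unambiguous round-trips.
            if child.kind != "GENE":
                text = f"({text})"
            parts.append(text)
        return op.join(parts)

    def __iter__(self) -> Iterator["GprAst"]:
        yield self
        for child in self.children:
            yield from child


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(text)]


def parse_gpr(rule_text: str) -> GprAst:
    """Parse a GPR rule string into an AST.

    ``and`` binds tighter than ``or``; both operators are case-insensitive
    and n-ary (``a and b and c`` becomes a single AND node with three
    children).  Gene identifiers are any whitespace-delimited tokens that
    are not operators or parentheses.

    Raises :class:`GprParseError` (with character position) on unbalanced
    parentheses, dangling operators or empty input.
    """
    tokens = _tokenize(rule_text)
    if not tokens:
        raise GprParseError("empty GPR rule")
    pos = 0

    def peek() -> Optional[tuple[str, int]]:
        return tokens[pos] if pos < len(tokens) else None

    def fail(message: str, at: Optional[int] = None) -> GprParseError:
        where = at if at is not None else (tokens[-1][1] + len(tokens[-1][0]))
        return GprParseError(f"{message} at position {where} in {rule_text!r}")

    def parse_or() -> GprAst:
        nonlocal pos
        children = [parse_and()]
        while True:
            tok = peek()
            if tok is None or tok[0].lower() != "or":
                break
            pos += 1
            children.append(parse_and())
        if len(children) == 1:
            return children[0]
        return GprAst("OR", children=tuple(children))

    def parse_and() -> GprAst:
        nonlocal pos
        children = [parse_atom()]
        while True:
            tok = peek()
            if tok is None or tok[0].lower() != "and":
                break
            pos += 1
            children.append(parse_atom())
        if len(children) == 1:
            return children[0]
        return GprAst("AND", children=tuple(children))

    def parse_atom() -> GprAst:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise fail("dangling operator: expected gene or '('")
        text, at = tok
        if text == "(":
            pos += 1
            node = parse_or()
            closing = peek()
            if closing is None or closing[0] != ")":
                raise fail("unbalanced parentheses: expected ')'", at)
            pos += 1
            return node
        if text == ")":
            raise fail("unexpected ')'", at)
        if text.lower() in ("and", "or"):
            raise fail(f"unexpected operator {text!r}", at)
        pos += 1
        return GprAst("GENE", gene_id=text)

    node = parse_or()
    trailing = peek()
    if trailing is not None:
        raise fail(f"unexpected token {trailing[0]!r}", trailing[1])
    return node


# ---------------------------------------------------------------------------
# Model types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be nonempty")


@dataclass
class Reaction:
    """A reaction column: stoichiometry, flux bounds, subsystem and GPR.

    ``parent_id`` tracks the originating reaction after irreversible
    splitting so that pathway counting can collapse ``_f``/``_b`` pairs.
    """

    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UPPER
    subsystem: str = ""
    gpr: Optional[GprAst] = None
    name: str = ""
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be nonempty")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        """Boundary reactions touch a single metabolite."""
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str
    id: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions:
            if rxn.gpr is not None:
                out |= rxn.gpr.genes()
        return out

    @property
    def subsystem_index(self) -> dict[str, set[str]]:
        index: dict[str, set[str]] = {}
        for rxn in self.reactions:
            if rxn.subsystem:
                index.setdefault(rxn.subsystem, set()).add(rxn.id)
        return index

    def get_reaction(self, reaction_id: str) -> Reaction:
        try:
            return self._reaction_map[reaction_id]
        except KeyError:
            raise KeyError(f"no reaction {reaction_id!r} in model {self.id!r}")

    @property
    def objective(self) -> Reaction:
        return self.get_reaction(self.objective_id)

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dupes}")
        met_set = set(met_ids)
        for rxn in self.reactions:
            unknown = set(rxn.stoichiometry) - met_set
            if unknown:
                raise ModelValidationError(
                    f"reaction {rxn.id} references unknown metabolites: "
                    f"{sorted(unknown)}"
                )
        if self.objective_id not in set(rxn_ids):
            raise ModelValidationError(
                f"objective reaction {self.objective_id!r} not in model"
            )
        self._reaction_map = {r.id: r for r in self.reactions}

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            objective_id=self.objective_id,
            id=self.id,
        )

    @property
    def is_irreversible(self) -> bool:
        return all(r.lower_bound >= 0 for r in self.reactions)

    def summary(self) -> dict[str, int]:
        return {
            "metabolites": len(self.metabolites),
            "reactions": len(self.reactions),
            "genes": len(self.genes),
        }


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _reaction_from_json(entry: Mapping) -> Reaction:
    rid = entry.get("id")
    if not rid:
        raise ModelValidationError(f"reaction entry without id: {entry!r}")
    rule = entry.get("gene_reaction_rule", "") or ""
    gpr = parse_gpr(rule) if rule.strip() else None
    lb = entry.get("lower_bound")
    ub = entry.get("upper_bound")
    if lb is None and ub is None:
        lb, ub = 0.0, DEFAULT_UPPER
    elif lb is None:
        lb = 0.0
    elif ub is None:
        ub = DEFAULT_UPPER
    return Reaction(
        id=rid,
        stoichiometry={k: float(v) for k, v in entry.get("metabolites", {}).items()},
        lower_bound=float(lb),
        upper_bound=float(ub),
        subsystem=entry.get("subsystem", "") or "",
        gpr=gpr,
        name=entry.get("name", "") or "",
    )


def read_model_json(path: Union[str, Path]) -> MetabolicModel:
    """Read a COBRA-style JSON model."""
    path = Path(path)
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelValidationError(f"{path}: not valid JSON ({exc})") from exc
    mets = [
        Metabolite(
            id=m["id"],
            name=m.get("name", "") or "",
            compartment=m.get("compartment", "") or "",
        )
        for m in doc.get("metabolites", [])
    ]
    rxns = [_reaction_from_json(entry) for entry in doc.get("reactions", [])]
    objective = [
        r["id"]
        for r in doc.get("reactions", [])
        if float(r.get("objective_coefficient", 0.0) or 0.0) != 0.0
    ]
    if not objective:
        raise ModelValidationError(
            f"{path}: no reaction carries a nonzero objective coefficient"
        )
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_id=objective[0],
        id=doc.get("id", path.stem),
    )


def read_model_sbml(path: Union[str, Path]) -> MetabolicModel:
    """Read an SBML Level 3 (FBC) model via cobrapy."""
    import cobra.io

    cb = cobra.io.read_sbml_model(str(path))
    return _from_cobra(cb)


def _from_cobra(cb) -> MetabolicModel:
    mets = [
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "")
        for m in cb.metabolites
    ]
    rxns = []
    for r in cb.reactions:
        rule = r.gene_reaction_rule or ""
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                subsystem=r.subsystem or "",
                gpr=parse_gpr(rule) if rule.strip() else None,
                name=r.name or "",
            )
        )
    objective = [r.id for r in cb.reactions if r.objective_coefficient]
    if not objective:
        raise ModelValidationError("SBML model has no objective reaction")
    return MetabolicModel(metabolites=mets, reactions=rxns, objective_id=objective[0], id=cb.id or "model")


def read_model(path: Union[str, Path], format: Optional[str] = None) -> MetabolicModel:
    """Read a model from COBRA-style JSON or SBML (auto-detected by suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "SBML" if path.suffix.lower() in (".xml", ".sbml") else "COBRA-JSON"
    fmt = format.upper().replace("_", "-")
    if fmt in ("SBML",):
        return read_model_sbml(path)
    if fmt in ("COBRA-JSON", "JSON"):
        return read_model_json(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path: Union[str, Path]) -> None:
    """Write the model as COBRA-style JSON."""
    doc = {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "gene_reaction_rule": r.gpr.to_string() if r.gpr else "",
                "objective_coefficient": 1.0 if r.id == model.objective_id else 0.0,
            }
            for r in model.reactions
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Irreversible canonical form
# ---------------------------------------------------------------------------


def make_irreversible(
    model: MetabolicModel,
) -> tuple[MetabolicModel, dict[str, list[str]]]:
    """Split every reversible reaction into forward/backward halves.

    Returns the split model (all lower bounds >= 0, split pairs adjacent and
    in input order) and a mapping original id -> list of ids in the split
    model.  Both halves inherit subsystem and GPR; the backward half carries
    negated stoichiometry.  Any feasible flux of the split model maps back
    via ``v_f - v_b`` to a feasible flux of the original with the same
    objective value.
    """
    reactions: list[Reaction] = []
    mapping: dict[str, list[str]] = {}
    for rxn in model.reactions:
        if not rxn.reversible:
            out = rxn.copy()
            out.parent_id = rxn.id
            reactions.append(out)
            mapping[rxn.id] = [rxn.id]
            continue
        fwd = Reaction(
            id=rxn.id + FORWARD_SUFFIX,
            stoichiometry=dict(rxn.stoichiometry),
            lower_bound=0.0,
            upper_bound=rxn.upper_bound,
            subsystem=rxn.subsystem,
            gpr=rxn.gpr,
            name=rxn.name,
            parent_id=rxn.id,
        )
        bwd = Reaction(
            id=rxn.id + BACKWARD_SUFFIX,
            stoichiometry={m: -c for m, c in rxn.stoichiometry.items()},
            lower_bound=0.0,
            upper_bound=-rxn.lower_bound,
            subsystem=rxn.subsystem,
            gpr=rxn.gpr,
            name=rxn.name,
            parent_id=rxn.id,
        )
        reactions.extend([fwd, bwd])
        mapping[rxn.id] = [fwd.id, bwd.id]

    objective_id = model.objective_id
    if objective_id not in {r.id for r in reactions}:
        objective_id = mapping[model.objective_id][0]
    split = MetabolicModel(
        metabolites=list(model.metabolites),
        reactions=reactions,
        objective_id=objective_id,
        id=model.id,
    )
    return split, mapping


def recombine_fluxes(
    fluxes: Mapping[str, float], mapping: Mapping[str, Sequence[str]]
) -> dict[str, float]:
    """Map a split-model flux vector back onto original reaction ids."""
    out: dict[str, float] = {}
    for orig, ids in mapping.items():
        if len(ids) == 1:
            out[orig] = fluxes[ids[0]]
        else:
            out[orig] = fluxes[ids[0]] - fluxes[ids[1]]
    return out
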