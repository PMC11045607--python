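"""Core data structures for constraint-based metabolic models.

A model is a stoichiometric network: metabolites, reactions with flux
bounds in mmol/(gDCW*h) (the biomass reaction carries 1/h), boolean
gene-protein-reaction (GPR) rules, and a growth objective.  Conventions
follow the COBRA standard: exchange reactions are single-metabolite
boundary reactions and uptake is a negative flux.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np

#: Default magnitude used for "unbounded" fluxes, mmol/(gDCW*h).
DEFAULT_BOUND = 1000.0

# Monoisotopic-free average atomic masses (g/mol) for formula arithmetic.
ATOMIC_MASSES = {
    "C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Na": 22.990, "K": 39.098, "Mg": 24.305, "Fe": 55.845,
    "Cl": 35.45, "Ca": 40.078, "Zn": 65.38, "Se": 78.971,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelError(ValueError):
    """Raised for structurally invalid models or references to missing ids."""


class GPRParseError(ValueError):
    """Raised when a GPR rule string cannot be parsed; carries the position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# Elemental formulas
# ---------------------------------------------------------------------------

def parse_formula(formula: str) -> Dict[str, int]:
    """Parse an elemental formula like ``C6H14N4O2`` into element counts.

    Raises ``ValueError`` on anything that is not a flat element/count
    sequence (no parentheses, no charges).
    """
    if formula is None:
        raise ValueError("formula is None")
    formula = formula.strip()
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"unparseable formula {formula!r} at position {pos}")
        element = match.group(1)
        counts[element] = counts.get(element, 0) + int(match.group(2) or 1)
        pos = match.end()
    if pos != len(formula):
        raise ValueError(f"unparseable formula {formula!r} at position {pos}")
    return counts


def formula_string(counts: Mapping[str, int]) -> str:
    """Render element counts in Hill order (C, H, then alphabetical)."""
    def key(el: str) -> Tuple[int, str]:
        return ({"C": 0, "H": 1}.get(el, 2), el)

    parts = []
    for el in sorted(counts, key=key):
        n = counts[el]
        if n:
            parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def molar_mass(formula: str) -> float:
    """Molar mass in g/mol of an elemental formula string."""
    counts = parse_formula(formula)
    try:
        return sum(ATOMIC_MASSES[el] * n for el, n in counts.items())
    except KeyError as exc:  # pragma: no cover - exotic elements
        raise ValueError(f"no atomic mass for element {exc}") from exc


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPRExpression:
    """Boolean expression tree over gene identifiers.

    ``kind`` is one of ``"empty"``, ``"gene"``, ``"and"``, ``"or"``.  The
    empty expression evaluates true under every deletion set: reactions
    without gene association cannot be knocked out.
    """

    kind: str
    gene: Optional[str] = None
    children: Tuple["GPRExpression", ...] = ()

    def evaluate(self, deleted_genes: Iterable[str] = ()) -> bool:
        deleted = set(deleted_genes)
        return self._eval(deleted)

    def _eval(self, deleted: set) -> bool:
        if self.kind == "empty":
            return True
        if self.kind == "gene":
            return self.gene not in deleted
        if self.kind == "and":
            return all(c._eval(deleted) for c in self.children)
        if self.kind == "or":
            return any(c._eval(deleted) for c in self.children)
        raise AssertionError(f"unknown GPR node kind {self.kind!r}")

    def genes(self) -> set:
        """All gene identifiers appearing in the expression."""
        if self.kind == "gene":
            return {self.gene}
        out: set = set()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        """Normalized string form; round-trips through :func:`parse_gpr`."""
        return self._render(top=True)

    def _render(self, top: bool = False) -> str:
        if self.kind == "empty":
            return ""
        if self.kind == "gene":
            return self.gene
        op = f" {self.kind} "
        inner = op.join(c._render() for c in self.children)
        if top:
            return inner
        return f"({inner})"

    def __str__(self) -> str:
        return self.to_string()


GPR_EMPTY = GPRExpression(kind="empty")

_GPR_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-]+)")


def _tokenize_gpr(text: str) -> List[Tuple[str, int]]:
    tokens: List[Tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        match = _GPR_TOKEN.match(text, pos)
        if match is None:
            raise GPRParseError(f"unexpected character {text[pos]!r}", pos)
        tokens.append((match.group(1), match.start(1)))
        pos = match.end()
    return tokens


class _GPRParser:
    """Recursive-descent parser: or-expr := and-expr ('or' and-expr)*."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize_gpr(text)
        self.index = 0

    def peek(self) -> Optional[Tuple[str, int]]:
        if self.index < len(self.tokens):
            return self.tokens[self.index]
        return None

    def next(self) -> Tuple[str, int]:
        token = self.peek()
        if token is None:
            raise GPRParseError("unexpected end of rule", len(self.text))
        self.index += 1
        return token

    def parse(self) -> GPRExpression:
        expr = self.parse_or()
        if self.peek() is not None:
            token, pos = self.peek()
            raise GPRParseError(f"unexpected token {token!r}", pos)
        return expr

    def parse_or(self) -> GPRExpression:
        parts = [self.parse_and()]
        while self.peek() is not None and self.peek()[0].lower() == "or":
            self.next()
            parts.append(self.parse_and())
        if len(parts) == 1:
            return parts[0]
        return GPRExpression(kind="or", children=tuple(parts))

    def parse_and(self) -> GPRExpression:
        parts = [self.parse_atom()]
        while self.peek() is not None and self.peek()[0].lower() == "and":
            self.next()
            parts.append(self.parse_atom())
        if len(parts) == 1:
            return parts[0]
        return GPRExpression(kind="and", children=tuple(parts))

    def parse_atom(self) -> GPRExpression:
        token, pos = self.next()
        if token == "(":
            expr = self.parse_or()
            closing = self.peek()
            if closing is None or closing[0] != ")":
                raise GPRParseError("unbalanced parenthesis", pos)
            self.next()
            return expr
        if token == ")":
            raise GPRParseError("unmatched closing parenthesis", pos)
        if token.lower() in ("and", "or"):
            raise GPRParseError(f"operator {token!r} without operand", pos)
        return GPRExpression(kind="gene", gene=token)


def parse_gpr(rule_text: str) -> GPRExpression:
    """Parse a GPR rule (``and``/``or``/parentheses, case-insensitive)."""
    if rule_text is None or not rule_text.strip():
        return GPR_EMPTY
    return _GPRParser(rule_text).parse()


def evaluate_gpr(expr: GPRExpression, deleted_genes: Iterable[str] = ()) -> bool:
    """True if the reaction remains catalyzed after deleting ``deleted_genes``."""
    return expr.evaluate(deleted_genes)


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str = ""
    charge: int = 0


@dataclass
class Reaction:
    """Reaction with stoichiometry (negative = consumed) and flux bounds."""

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: GPRExpression = GPR_EMPTY
    subsystem: str = ""
    name: str = ""

    def __post_init__(self):
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id}: empty stoichiometry")

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def bounds(self) -> Tuple[float, float]:
        return (self.lower_bound, self.upper_bound)


#: Medium: exchange-reaction id -> (lower_bound, upper_bound), mmol/(gDCW*h).
Medium = Dict[str, Tuple[float, float]]


@dataclass
class MetabolicModel:
    id: str
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    objective_reaction_id: str = ""
    ngam_reaction_id: Optional[str] = None

    def __post_init__(self):
        self._reindex()

    def _reindex(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise ModelError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelError("duplicate reaction ids")

    # -- lookups -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self.metabolites[self._met_index[met_id]]
        except KeyError:
            raise ModelError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise ModelError(f"unknown reaction {rxn_id!r}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    @property
    def genes(self) -> List[str]:
        out: set = set()
        for r in self.reactions:
            out |= r.gpr.genes()
        return sorted(out)

    # -- structure ---------------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S matrix, metabolites x reactions."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                S[self._met_index[met_id], j] = coeff
        return S

    def validate(self) -> None:
        """Check referential integrity and the objective; raise ``ModelError``."""
        if self.objective_reaction_id not in self._rxn_index:
            raise ModelError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )
        if self.ngam_reaction_id and self.ngam_reaction_id not in self._rxn_index:
            raise ModelError(f"NGAM reaction {self.ngam_reaction_id!r} not in model")
        for rxn in self.reactions:
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelError(
                        f"reaction {rxn.id} references unknown metabolite {met_id!r}"
                    )
            if not np.all(np.isfinite(list(rxn.stoichiometry.values()))):
                raise ModelError(f"reaction {rxn.id}: non-finite coefficient")
        for met in self.metabolites:
            if not met.compartment:
                raise ModelError(f"metabolite {met.id}: empty compartment")

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- editing -----------------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._met_index:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)
        self._met_index[met.id] = len(self.metabolites) - 1

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self._rxn_index:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        self.reactions.append(rxn)
        self._rxn_index[rxn.id] = len(self.reactions) - 1

    def set_bounds(self, rxn_id: str, lower: float, upper: float) -> None:
        rxn = self.reaction(rxn_id)
        if lower > upper:
            raise ModelError(f"{rxn_id}: lower bound {lower} > upper bound {upper}")
        rxn.lower_bound = lower
        rxn.upper_bound = upper

    def inactive_reactions(self, deleted_genes: Iterable[str]) -> List[str]:
        """Reactions whose GPR evaluates false under a gene deletion set."""
        deleted = set(deleted_genes)
        return [r.id for r in self.reactions if not r.gpr.evaluate(deleted)]


# ---------------------------------------------------------------------------
# Medium application
# ---------------------------------------------------------------------------

def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Return a copy with exchange bounds set from ``medium``.

    Exchanges listed in the medium get exactly the given (lb, ub).  Every
    other exchange is closed to uptake (lower bound raised to 0) while its
    secretion bound is retained, so products absent from the medium
    definition can still leave the cell.
    """
    exchange_ids = {r.id for r in model.exchanges}
    unknown = [rid for rid in medium if rid not in exchange_ids]
    if unknown:
        raise ModelError(
            "medium references non-exchange or missing reactions: "
            + ", ".join(sorted(unknown))
        )
    out = model.copy()
    for rxn in out.reactions:
        if not rxn.is_exchange:
            continue
        if rxn.id in medium:
            lb, ub = medium[rxn.id]
            out.set_bounds(rxn.id, lb, ub)
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
            rxn.upper_bound = max(rxn.upper_bound, rxn.lower_bound)
    return out


# ---------------------------------------------------------------------------
# PHB polymerization builder
# ---------------------------------------------------------------------------

def _scaled_formula(formula: str, factor: int) -> str:
    if not formula:
        return ""
    counts = parse_formula(formula)
    return formula_string({el: n * factor for el, n in counts.items()})


def add_polymer_reaction(
    model: MetabolicModel,
    residue_metabolite_id: str,
    residues_per_monomer: int,
    monomers_per_polymer: int,
    prefix: str = "PHB",
    add_exchange: bool = True,
) -> MetabolicModel:
    """Add monomer-synthesis and polymerization reactions for a polyester.

    ``residues_per_monomer`` residues condense into one short-chain monomer
    and ``monomers_per_polymer`` monomers into one polymer molecule, so the
    polymer molar mass is ``residues_per_monomer * monomers_per_polymer``
    times the residue mass.  Because the polymerization stoichiometry is a
    pure rescaling, the chain-length choice leaves any mass-based product
    yield unchanged.  Optionally adds secretion and exchange for the
    polymer.
    """
    if residues_per_monomer < 1 or monomers_per_polymer < 1:
        raise ValueError("residue and monomer counts must be >= 1")
    out = model.copy()
    residue = out.metabolite(residue_metabolite_id)  # raises if missing
    lowered = prefix.lower()
    monomer = Metabolite(
        id=f"{lowered}_mon_{residue.compartment}",
        name=f"{prefix} monomer ({residues_per_monomer} residues)",
        compartment=residue.compartment,
        formula=_scaled_formula(residue.formula, residues_per_monomer),
    )
    polymer = Metabolite(
        id=f"{lowered}_pol_{residue.compartment}",
        name=f"{prefix} polymer ({monomers_per_polymer} monomers)",
        compartment=residue.compartment,
        formula=_scaled_formula(
            residue.formula, residues_per_monomer * monomers_per_polymer
        ),
    )
    out.add_metabolite(monomer)
    out.add_metabolite(polymer)
    out.add_reaction(Reaction(
        id=f"{prefix}_MONOMER_SYN",
        stoichiometry={residue.id: -float(residues_per_monomer), monomer.id: 1.0},
        lower_bound=0.0, upper_bound=DEFAULT_BOUND,
        subsystem="polymer synthesis",
    ))
    out.add_reaction(Reaction(
        id=f"{prefix}_POLYMER_SYN",
        stoichiometry={monomer.id: -float(monomers_per_polymer), polymer.id: 1.0},
        lower_bound=0.0, upper_bound=DEFAULT_BOUND,
        subsystem="polymer synthesis",
    ))
    if add_exchange:
        polymer_e = Metabolite(
            id=f"{lowered}_pol_e",
            name=polymer.name + " (extracellular)",
            compartment="e",
            formula=polymer.formula,
        )
        out.add_metabolite(polymer_e)
        out.add_reaction(Reaction(
            id=f"{prefix}t",
            stoichiometry={polymer.id: -1.0, polymer_e.id: 1.0},
            lower_bound=0.0, upper_bound=DEFAULT_BOUND,
            subsystem="transport",
        ))
        out.add_reaction(Reaction(
            id=f"EX_{lowered}",
            stoichiometry={polymer_e.id: -1.0},
            lower_bound=0.0, upper_bound=DEFAULT_BOUND,
            subsystem="exchange",
        ))
    return out
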