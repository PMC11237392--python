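"""Core data model for constraint-based metabolic networks.

A :class:`Model` holds metabolites, reactions and genes keyed by id, with
one designated objective reaction (typically a biomass drain).  Reaction
bounds are fluxes in mmol·gDCW⁻¹·h⁻¹; the community convention applies
to exchange reactions: negative flux is uptake, positive is secretion.

Default bounds follow the usual genome-scale convention: reversible
reactions get [-1000, 1000], irreversible ones [0, 1000]; bounds are
always stored explicitly.
"""

from __future__ import annotations

import copy as _copy
import math
import re
from dataclasses import dataclass, field
from typing import Mapping

from .gpr import GPRNode, genes_of

__all__ = [
    "DEFAULT_UPPER_BOUND",
    "DEFAULT_LOWER_BOUND_REVERSIBLE",
    "Metabolite",
    "Gene",
    "Reaction",
    "Model",
    "MediumSpec",
    "BalanceReport",
    "ModelValidationError",
    "parse_formula",
    "format_formula",
    "check_balance",
    "apply_medium",
    "infer_origin",
]

DEFAULT_UPPER_BOUND = 1000.0
DEFAULT_LOWER_BOUND_REVERSIBLE = -1000.0

#: Origin labels for genes in a hybrid model.
ORIGINS = ("parentA", "parentB", "hybrid-specific", "template")

#: Canonical allele suffixes (case-sensitive): S. cerevisiae-like alleles
#: get "_Scer", S. eubayanus-like "_Seub", hybrid-specific "_Spast".
SUFFIX_TO_ORIGIN = {
    "_Scer": "parentA",
    "_Seub": "parentB",
    "_Spast": "hybrid-specific",
}


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse an elemental formula like ``C6H12O6`` into element counts."""
    if not text:
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Render element counts as a Hill-ordered formula string."""
    elements = sorted(counts)
    if "C" in counts:
        elements = ["C"] + (["H"] if "H" in counts else []) + [
            e for e in elements if e not in ("C", "H")
        ]
    return "".join(
        f"{e}{counts[e]}" if counts[e] != 1 else e for e in elements if counts[e]
    )


def infer_origin(gene_id: str) -> str:
    """Infer a gene's parental origin from its allele suffix."""
    for suffix, origin in SUFFIX_TO_ORIGIN.items():
        if gene_id.endswith(suffix):
            return origin
    return "template"


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, int] | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            self.formula = parse_formula(self.formula)
        if self.formula is not None and any(v < 0 for v in self.formula.values()):
            raise ValueError(f"negative element count in formula of {self.id!r}")


@dataclass
class Gene:
    id: str
    name: str = ""
    origin: str = "template"
    allele_partner: str | None = None

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(
                f"gene {self.id!r}: origin {self.origin!r} not in {ORIGINS}"
            )


@dataclass
class Reaction:
    """A (possibly gene-associated) stoichiometric conversion.

    ``stoichiometry`` maps metabolite ids to signed coefficients
    (negative = consumed).  ``gpr`` is a Boolean rule tree, or ``None``
    for spontaneous/exchange/pseudo reactions, or the ``UNSATISFIABLE``
    sentinel from :mod:`hybridgem.hybridize` for rules voided during
    hybridization (pruning removes those).
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UPPER_BOUND
    gpr: object | None = None
    sbo_term: str | None = None

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        """Whether flux may run backwards (a negative flux is permitted)."""
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        """Boundary reactions touch exactly one metabolite."""
        return len(self.stoichiometry) == 1

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    @bounds.setter
    def bounds(self, value: tuple[float, float]) -> None:
        lb, ub = value
        if lb > ub:
            raise ValueError(f"reaction {self.id!r}: bounds {value} inverted")
        self.lower_bound, self.upper_bound = float(lb), float(ub)


#: Medium specification: exchange reaction id -> (lower_bound, upper_bound).
MediumSpec = Mapping[str, tuple[float, float]]


@dataclass
class Model:
    id: str = "model"
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)
    objective_reaction_id: str | None = None
    #: free-form provenance notes keyed by entity id (curation audit trail)
    provenance: dict[str, str] = field(default_factory=dict)

    # -- construction helpers -------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        return met

    def add_gene(self, gene: Gene) -> Gene:
        if gene.id in self.genes:
            raise ValueError(f"duplicate gene id {gene.id!r}")
        self.genes[gene.id] = gene
        return gene

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn
        return rxn

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def copy(self) -> "Model":
        return _copy.deepcopy(self)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Check referential integrity; raises :class:`ModelValidationError`."""
        problems: list[str] = []
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    problems.append(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )
            if isinstance(rxn.gpr, GPRNode):
                missing = genes_of(rxn.gpr) - set(self.genes)
                if missing:
                    problems.append(
                        f"reaction {rxn.id!r} GPR references undeclared genes: "
                        f"{sorted(missing)}"
                    )
        if self.objective_reaction_id is not None and (
            self.objective_reaction_id not in self.reactions
        ):
            problems.append(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )
        for gene in self.genes.values():
            partner = gene.allele_partner
            if partner is not None:
                other = self.genes.get(partner)
                if other is None:
                    problems.append(
                        f"gene {gene.id!r} names missing allele partner {partner!r}"
                    )
                elif other.allele_partner != gene.id:
                    problems.append(
                        f"allele partnership {gene.id!r} <-> {partner!r} is not "
                        "symmetric"
                    )
        if problems:
            raise ModelValidationError("; ".join(problems))


# ---------------------------------------------------------------------------
# Mass/charge balance

@dataclass
class BalanceReport:
    """Per-element and charge imbalance of a reaction.

    ``element_delta`` holds net production minus consumption for each
    element; a balanced reaction has all zeros and zero net charge.
    Exchange reactions are single-sided by construction and reported as
    exempt; reactions touching a metabolite without a formula are
    indeterminate rather than failed.
    """

    reaction_id: str
    status: str  # "balanced" | "imbalanced" | "indeterminate" | "exempt"
    element_delta: dict[str, float] = field(default_factory=dict)
    charge_delta: float | None = None
    missing_formulas: list[str] = field(default_factory=list)

    @property
    def balanced(self) -> bool:
        return self.status == "balanced"


def check_balance(
    reaction: Reaction, metabolites: Mapping[str, Metabolite]
) -> BalanceReport:
    """Elemental/charge balance check of one reaction.

    The net count of each element is the stoichiometry-weighted sum of
    the participating metabolite formulas.
    """
    if reaction.is_exchange:
        return BalanceReport(reaction.id, "exempt")
    missing = [
        met_id
        for met_id in reaction.stoichiometry
        if metabolites[met_id].formula is None
    ]
    if missing:
        return BalanceReport(reaction.id, "indeterminate", missing_formulas=missing)
    delta: dict[str, float] = {}
    charge = 0.0
    charge_known = True
    for met_id, coeff in reaction.stoichiometry.items():
        met = metabolites[met_id]
        for element, count in (met.formula or {}).items():
            delta[element] = delta.get(element, 0.0) + coeff * count
        if met.charge is None:
            charge_known = False
        else:
            charge += coeff * met.charge
    delta = {e: v for e, v in delta.items() if abs(v) > 1e-9}
    charge_delta = charge if charge_known else None
    status = (
        "balanced"
        if not delta and (charge_delta is None or math.isclose(charge_delta, 0.0, abs_tol=1e-9))
        else "imbalanced"
    )
    return BalanceReport(reaction.id, status, delta, charge_delta)


# ---------------------------------------------------------------------------
# Medium application

def apply_medium(model: Model, medium: MediumSpec) -> Model:
    """Return a copy of ``model`` with exchange bounds set from ``medium``.

    Exchanges listed in the medium get exactly the given bounds
    (negative lower bound = permitted uptake).  Every *unlisted*
    exchange has its uptake closed (lower bound raised to 0) while its
    secretion direction is left as-is, so the medium fully determines
    what the cell may consume.

    Raises
    ------
    ValueError
        If a medium id is absent from the model or is not an exchange.
    """
    new = model.copy()
    for rxn_id, (lb, ub) in medium.items():
        rxn = new.reactions.get(rxn_id)
        if rxn is None:
            raise ValueError(f"medium references unknown reaction {rxn_id!r}")
        if not rxn.is_exchange:
            raise ValueError(f"medium reaction {rxn_id!r} is not an exchange")
        if lb > ub:
            raise ValueError(f"medium bounds for {rxn_id!r} inverted: {(lb, ub)}")
        rxn.bounds = (lb, ub)
    for rxn in new.reactions.values():
        if rxn.is_exchange and rxn.id not in medium and rxn.lower_bound < 0:
            rxn.lower_bound = 0.0
    return new
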