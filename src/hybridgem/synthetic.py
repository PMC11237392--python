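"""Deterministic generators for toy models, ortholog tables and
expression profiles.

The toy template is a set of parallel linear pathways, each fed by its
own substrate exchange (uptake bound 10 mmol·gDCW⁻¹·h⁻¹) and draining
into a single biomass precursor, so the FBA optimum is known
analytically: the sum of path uptake capacities.  GPRs span all census
categories (single gene, redundant ``or`` pairs, an ``and`` complex or
mixed rule, gene-less exchanges and biomass).  Everything is
reproducible from a single integer seed (numpy PCG64 generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .expression import ExpressionProfile, tpm_normalize
from .gpr import parse_gpr
from .hybridize import PARENT_A, PARENT_B, OrthologRecord
from .model import Gene, Metabolite, Model, Reaction

__all__ = [
    "ToyNetworkSpec",
    "SyntheticExpressionSpec",
    "make_template",
    "make_ortholog_tables",
    "make_expression",
    "UPTAKE_BOUND",
]

#: per-path substrate uptake bound of generated templates
UPTAKE_BOUND = 10.0

_SUGAR = {"C": 6, "H": 12, "O": 6}


@dataclass(frozen=True)
class ToyNetworkSpec:
    """Shape of a generated toy template network.

    ``fraction_redundant_genes`` is the probability that a reaction's
    catalyst exists as a redundant parental allele pair (an ``or`` rule
    with ``_Scer``/``_Seub`` suffixed genes) rather than a single gene;
    1.0 yields a fully allele-redundant hybrid toy, 0.0 a plain
    single-copy template.
    """

    n_internal_reactions: int = 6
    n_parallel_paths: int = 2
    fraction_redundant_genes: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_internal_reactions < 1:
            raise ValueError("need at least one internal reaction")
        if self.n_parallel_paths < 1:
            raise ValueError("need at least one path")
        if self.n_internal_reactions < self.n_parallel_paths:
            raise ValueError("need at least one internal reaction per path")
        if not 0.0 <= self.fraction_redundant_genes <= 1.0:
            raise ValueError("fraction_redundant_genes must be in [0, 1]")


def _gene_group(
    model: Model, index: int, redundant: bool
) -> tuple[str, list[str]]:
    """Create the gene(s) for one catalyst slot; returns (rule text, ids)."""
    base = f"G{index}"
    if redundant:
        a, b = f"{base}_Scer", f"{base}_Seub"
        model.add_gene(Gene(id=a, name=a, origin=PARENT_A, allele_partner=b))
        model.add_gene(Gene(id=b, name=b, origin=PARENT_B, allele_partner=a))
        return f"({a} or {b})", [a, b]
    model.add_gene(Gene(id=base, name=base, origin="template"))
    return base, [base]


def make_template(spec: ToyNetworkSpec) -> Model:
    """Generate a toy template model from ``spec`` (deterministic).

    The model grows on its default medium with FBA optimum equal to
    ``UPTAKE_BOUND * n_parallel_paths``.
    """
    rng = np.random.default_rng(spec.seed)
    model = Model(id=f"toy_seed{spec.seed}")
    precursor = model.add_metabolite(
        Metabolite("biomass_pre_c", "biomass precursor", "c", dict(_SUGAR))
    )

    per_path = spec.n_internal_reactions // spec.n_parallel_paths
    remainder = spec.n_internal_reactions % spec.n_parallel_paths
    gene_counter = 0
    internal: list[Reaction] = []

    for p in range(spec.n_parallel_paths):
        length = per_path + (1 if p < remainder else 0)
        substrate = model.add_metabolite(
            Metabolite(f"sub{p}_e", f"substrate {p}", "e", dict(_SUGAR))
        )
        model.add_reaction(
            Reaction(
                id=f"EX_sub{p}",
                name=f"substrate {p} exchange",
                stoichiometry={substrate.id: -1.0},
                lower_bound=-UPTAKE_BOUND,
                upper_bound=1000.0,
                sbo_term="SBO:0000627",
            )
        )
        prev = substrate.id
        for i in range(length):
            last = i == length - 1
            nxt = (
                precursor.id
                if last
                else model.add_metabolite(
                    Metabolite(f"m{p}_{i}_c", f"intermediate {p}.{i}", "c", dict(_SUGAR))
                ).id
            )
            rxn = model.add_reaction(
                Reaction(
                    id=f"R{p}_{i}",
                    name=f"path {p} step {i}",
                    stoichiometry={prev: -1.0, nxt: 1.0},
                    lower_bound=0.0,
                    upper_bound=1000.0,
                )
            )
            internal.append(rxn)
            prev = nxt

    # assign GPRs: last internal reaction is a two-subunit complex,
    # the rest single catalysts; redundancy drawn per catalyst slot
    for k, rxn in enumerate(internal):
        redundant = bool(rng.random() < spec.fraction_redundant_genes)
        if k == len(internal) - 1 and len(internal) >= 2:
            rule_a, _ = _gene_group(model, gene_counter, redundant)
            rule_b, _ = _gene_group(model, gene_counter + 1, redundant)
            gene_counter += 2
            rxn.gpr = parse_gpr(f"{rule_a} and {rule_b}")
        else:
            rule, _ = _gene_group(model, gene_counter, redundant)
            gene_counter += 1
            rxn.gpr = parse_gpr(rule)

    biomass = model.add_reaction(
        Reaction(
            id="BIOMASS",
            name="biomass drain",
            stoichiometry={precursor.id: -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            sbo_term="SBO:0000629",
        )
    )
    model.objective_reaction_id = biomass.id
    model.validate()
    return model


def make_ortholog_tables(
    template: Model,
    fraction_both: float = 0.6,
    fraction_Aonly: float = 0.1,
    fraction_Bonly: float = 0.3,
    seed: int = 0,
    identity_threshold: float = 70.0,
) -> list[OrthologRecord]:
    """Generate ortholog calls for the template's genes by seeded draw.

    Each gene is assigned both / parentA-only / parentB-only / unmapped
    with the given probabilities.  Mapped records draw identities above
    the threshold, unmapped genes get below-threshold records (so they
    are excluded by the mapping step rather than simply absent).
    """
    fractions = (fraction_both, fraction_Aonly, fraction_Bonly)
    if any(f < 0 for f in fractions) or sum(fractions) > 1.0 + 1e-12:
        raise ValueError(
            f"fractions must be non-negative and sum to <= 1, got {fractions}"
        )
    rng = np.random.default_rng(seed)
    records: list[OrthologRecord] = []

    def identity(mapped: bool) -> float:
        if mapped:
            return float(rng.uniform(identity_threshold + 0.5, 100.0))
        return float(rng.uniform(20.0, identity_threshold - 0.5))

    for gene_id in template.genes:
        u = rng.random()
        if u < fraction_both:
            parents = [(PARENT_A, True), (PARENT_B, True)]
        elif u < fraction_both + fraction_Aonly:
            parents = [(PARENT_A, True), (PARENT_B, False)]
        elif u < sum(fractions):
            parents = [(PARENT_A, False), (PARENT_B, True)]
        else:
            parents = [(PARENT_A, False), (PARENT_B, False)]
        for parent, mapped in parents:
            tag = "A" if parent == PARENT_A else "B"
            records.append(
                OrthologRecord(
                    hybrid_gene_id=f"SPH_{gene_id}_{tag}",
                    template_gene_id=gene_id,
                    parent=parent,
                    percent_identity=identity(mapped),
                    evidence="gene",
                )
            )
    return records


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Conditions emulating growth cultures at several temperatures.

    ``parentB_bias`` is the fraction of each allele pair's expression
    carried by the parentB allele; ``bias_by_condition`` optionally
    overrides it per condition (to emulate temperature-dependent allele
    usage shifts).  ``temperature_effect`` maps condition labels to a
    (low, high) uniform range for a per-gene-pair expression multiplier;
    multipliers apply to both alleles of a pair equally, so allele
    ratios are preserved within a condition.  ``noise_cv`` adds
    multiplicative log-normal noise per allele (0 = exact ratios).
    """

    parentB_bias: float = 0.5
    temperature_effect: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "SD_13C": (0.8, 1.0),
            "SD_22C": (1.0, 1.2),
            "SD_30C": (0.9, 1.1),
        }
    )
    noise_cv: float = 0.0
    seed: int = 0
    bias_by_condition: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.parentB_bias <= 1.0:
            raise ValueError("parentB_bias must be in [0, 1]")
        if self.bias_by_condition is not None and any(
            not 0.0 <= b <= 1.0 for b in self.bias_by_condition.values()
        ):
            raise ValueError("per-condition biases must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def make_expression(
    model: Model, spec: SyntheticExpressionSpec
) -> dict[str, ExpressionProfile]:
    """Generate one TPM-normalized expression profile per condition.

    Abundances are continuous pseudo-counts over 1 kb genes, normalized
    through :func:`hybridgem.expression.tpm_normalize`, so allele
    ratios survive normalization exactly at zero noise.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(model.genes.values())
    if not genes:
        raise ValueError("model has no genes to express")

    # group redundant allele pairs; singletons form their own group
    groups: list[list[Gene]] = []
    seen: set[str] = set()
    for gene in genes:
        if gene.id in seen:
            continue
        partner = model.genes.get(gene.allele_partner or "")
        if partner is not None and partner.id not in seen:
            groups.append(sorted([gene, partner], key=lambda g: g.origin))
            seen |= {gene.id, partner.id}
        else:
            groups.append([gene])
            seen.add(gene.id)

    base_totals = {
        tuple(x.id for x in group): float(rng.uniform(100.0, 1000.0))
        for group in groups
    }
    conditions = dict(spec.temperature_effect)
    profiles: dict[str, ExpressionProfile] = {}
    for condition, (lo, hi) in conditions.items():
        bias = (
            spec.bias_by_condition.get(condition, spec.parentB_bias)
            if spec.bias_by_condition
            else spec.parentB_bias
        )
        counts: dict[str, float] = {}
        for group in groups:
            key = tuple(x.id for x in group)
            total = base_totals[key] * float(rng.uniform(lo, hi))
            if len(group) == 2:
                split = {PARENT_A: 1.0 - bias, PARENT_B: bias}
                for gene in group:
                    counts[gene.id] = total * split[gene.origin]
            else:
                counts[group[0].id] = total
        if spec.noise_cv > 0:
            for gene_id in counts:
                counts[gene_id] *= float(rng.lognormal(0.0, spec.noise_cv))
        lengths = {g: 1.0 for g in counts}
        profiles[condition] = tpm_normalize(counts, lengths, library_id=condition)
    return profiles
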