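"""Build a hybrid-organism model from a template plus ortholog maps.

An interspecies hybrid (e.g. a lager yeast, *S. cerevisiae* ×
*S. eubayanus*) carries up to two parental alleles per template gene.
Starting from a curated template model, the pipeline is:

1. :func:`build_mapping` — decide, per template gene, which parental
   alleles exist in the hybrid, from gene-level and protein-level
   one-to-one ortholog calls above a percent-identity threshold
   (protein-level calls rescue genes missed at gene level, and win on
   conflict).
2. :func:`rewrite_gprs` — rewrite every GPR leaf: both alleles present
   becomes ``allele_Scer or allele_Seub`` (functional redundancy); one
   allele becomes a single renamed leaf; an absent gene is dropped from
   its ``or`` context or voids its ``and`` branch (a complex missing a
   subunit cannot form).
3. :func:`prune` — remove reactions whose rewritten GPR can no longer be
   satisfied, then genes left in no GPR.
4. :func:`apply_curation` — replay a manual curation list (re-integrated
   reactions, new reactions/genes, removals), idempotently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .gpr import AND, GPRNode, genes_of, parse_gpr
from .model import Gene, Metabolite, Model, Reaction, check_balance, infer_origin

__all__ = [
    "UNSATISFIABLE",
    "OrthologRecord",
    "HybridMapping",
    "CurationAction",
    "RemovalRecord",
    "VennCounts",
    "build_mapping",
    "venn_summary",
    "rewrite_gprs",
    "prune",
    "apply_curation",
    "load_curation_actions",
    "DEFAULT_SUFFIXES",
    "DEFAULT_IDENTITY_THRESHOLD",
]

PARENT_A = "parentA"
PARENT_B = "parentB"

#: Canonical allele-name suffixes per parent.
DEFAULT_SUFFIXES: dict[str, str] = {PARENT_A: "_Scer", PARENT_B: "_Seub"}

#: Ortholog calls at or below this percent identity are discarded
#: (strictly-greater-than comparison).
DEFAULT_IDENTITY_THRESHOLD = 70.0


class _Unsatisfiable:
    """Sentinel GPR for reactions whose rule can never be satisfied."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNSATISFIABLE"


UNSATISFIABLE = _Unsatisfiable()


@dataclass(frozen=True)
class OrthologRecord:
    """One hybrid-gene → template-gene one-to-one ortholog call."""

    hybrid_gene_id: str
    template_gene_id: str
    parent: str  # "parentA" | "parentB"
    percent_identity: float
    evidence: str = "gene"  # "gene" | "protein"

    def __post_init__(self) -> None:
        if self.parent not in (PARENT_A, PARENT_B):
            raise ValueError(f"unknown parent {self.parent!r}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )
        if self.evidence not in ("gene", "protein"):
            raise ValueError(f"unknown evidence level {self.evidence!r}")


@dataclass
class HybridMapping:
    """Resolved template-gene → hybrid-allele correspondence.

    ``alleles`` maps each mapped template gene to its supporting
    (hybrid_gene_id, parent, evidence) triples, at most one per parent.
    ``gene_level``/``protein_level`` keep the raw per-stratum calls so
    either accounting (before or after protein rescue) can be rebuilt.
    """

    alleles: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    unmapped_template_genes: set[str] = field(default_factory=set)
    conflicts: list[tuple[str, str, str]] = field(default_factory=list)
    ambiguous: list[tuple[str, str, str]] = field(default_factory=list)
    gene_level: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    protein_level: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def parents_of(self, template_gene_id: str) -> set[str]:
        return {p for _, p, _ in self.alleles.get(template_gene_id, [])}


@dataclass(frozen=True)
class VennCounts:
    both: int
    parentA_only: int
    parentB_only: int
    unmapped: int

    @property
    def total(self) -> int:
        return self.both + self.parentA_only + self.parentB_only + self.unmapped


def build_mapping(
    template: Model,
    orthologs: Iterable[OrthologRecord],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> HybridMapping:
    """Resolve which parental alleles support each template gene.

    Records at or below ``identity_threshold`` percent identity are
    excluded.  Within each (parent, evidence) stratum the calls must be
    one-to-one; duplicates raise with the offending ids.  Protein-level
    calls rescue template genes with no gene-level call, and on a
    disagreement about which template gene a hybrid gene corresponds
    to, the protein-level call wins and the conflict is logged.
    """
    records = [r for r in orthologs if r.percent_identity > identity_threshold]
    unknown = {r.template_gene_id for r in records} - set(template.genes)
    if unknown:
        raise ValueError(
            f"ortholog records reference genes absent from the template: "
            f"{sorted(unknown)}"
        )

    # 1:1 check per (parent, evidence) stratum, in both directions.
    for key_fn, label in (
        (lambda r: (r.parent, r.evidence, r.hybrid_gene_id), "hybrid gene"),
        (lambda r: (r.parent, r.evidence, r.template_gene_id), "template gene"),
    ):
        seen: dict[tuple, OrthologRecord] = {}
        offenders = []
        for rec in records:
            key = key_fn(rec)
            if key in seen and seen[key] != rec:
                offenders.append((seen[key], rec))
            seen[key] = rec
        if offenders:
            raise ValueError(
                f"duplicate one-to-one claims on {label} within a stratum: "
                + "; ".join(
                    f"{a.hybrid_gene_id}->{a.template_gene_id} vs "
                    f"{b.hybrid_gene_id}->{b.template_gene_id}"
                    for a, b in offenders
                )
            )

    mapping = HybridMapping()
    # raw per-stratum calls keyed by template gene
    for rec in records:
        stratum = mapping.gene_level if rec.evidence == "gene" else mapping.protein_level
        stratum.setdefault(rec.template_gene_id, []).append(
            (rec.hybrid_gene_id, rec.parent)
        )

    # Per (hybrid gene, parent), detect gene-vs-protein target disagreement.
    by_hybrid: dict[tuple[str, str], dict[str, str]] = {}
    for rec in records:
        by_hybrid.setdefault((rec.hybrid_gene_id, rec.parent), {})[
            rec.evidence
        ] = rec.template_gene_id
    overridden: set[tuple[str, str, str]] = set()
    for (hybrid_id, parent), calls in by_hybrid.items():
        if "gene" in calls and "protein" in calls and calls["gene"] != calls["protein"]:
            mapping.conflicts.append((hybrid_id, calls["gene"], calls["protein"]))
            overridden.add((hybrid_id, parent, calls["gene"]))

    # Resolve alleles: protein call wins where it disagrees with the gene call.
    resolved: dict[str, dict[str, tuple[str, str]]] = {}
    for rec in records:
        if rec.evidence == "gene" and (
            (rec.hybrid_gene_id, rec.parent, rec.template_gene_id) in overridden
        ):
            continue
        slot = resolved.setdefault(rec.template_gene_id, {})
        if rec.parent in slot:
            prev_hybrid, prev_evidence = slot[rec.parent]
            if prev_hybrid != rec.hybrid_gene_id:
                # two hybrid genes claim the same (template, parent) slot
                # across strata: paralogs indistinguishable at protein
                # level (e.g. 100%-identical duplicates) — keep the
                # gene-level call, flag the ambiguity.
                mapping.ambiguous.append(
                    (rec.template_gene_id, prev_hybrid, rec.hybrid_gene_id)
                )
                if prev_evidence == "protein" and rec.evidence == "gene":
                    slot[rec.parent] = (rec.hybrid_gene_id, rec.evidence)
            continue
        slot[rec.parent] = (rec.hybrid_gene_id, rec.evidence)

    for template_id, slot in resolved.items():
        mapping.alleles[template_id] = [
            (hybrid, parent, evidence)
            for parent, (hybrid, evidence) in sorted(slot.items())
        ]
    mapping.unmapped_template_genes = set(template.genes) - set(mapping.alleles)
    return mapping


def venn_summary(mapping: HybridMapping) -> VennCounts:
    """Count template genes with both / one / no parental alleles."""
    both = a_only = b_only = 0
    for parents in map(mapping.parents_of, mapping.alleles):
        if parents == {PARENT_A, PARENT_B}:
            both += 1
        elif parents == {PARENT_A}:
            a_only += 1
        elif parents == {PARENT_B}:
            b_only += 1
    return VennCounts(both, a_only, b_only, len(mapping.unmapped_template_genes))


# ---------------------------------------------------------------------------
# GPR rewriting

def _allele_gene_id(template_gene: Gene, suffix: str) -> str:
    base = template_gene.name or template_gene.id
    return f"{base}{suffix}"


def _rewrite_node(
    node: GPRNode,
    allele_leaves: Mapping[str, GPRNode | None],
) -> GPRNode | None | _Unsatisfiable:
    """Replace template leaves by allele leaves/OR-groups.

    Returns ``None`` when an unmapped leaf simply disappears from an
    ``or`` context that still has support, and ``UNSATISFIABLE`` when
    the (sub)rule can no longer be satisfied.
    """
    if node.kind == "leaf":
        replacement = allele_leaves.get(node.gene_id)
        return UNSATISFIABLE if replacement is None else replacement
    rewritten = [_rewrite_node(c, allele_leaves) for c in node.children]
    if node.kind == AND:
        if any(child is UNSATISFIABLE for child in rewritten):
            return UNSATISFIABLE
        kept = [c for c in rewritten if isinstance(c, GPRNode)]
        if len(kept) == 1:
            return kept[0]
        return GPRNode(AND, children=tuple(kept))
    # OR: drop unsatisfiable operands
    kept = [c for c in rewritten if isinstance(c, GPRNode)]
    if not kept:
        return UNSATISFIABLE
    if len(kept) == 1:
        return kept[0]
    return GPRNode("or", children=tuple(kept))


def rewrite_gprs(
    template: Model,
    mapping: HybridMapping,
    suffixes: Mapping[str, str] | None = None,
) -> Model:
    """Rewrite all GPRs of ``template`` in terms of hybrid alleles.

    Allele genes are named ``<template common name><suffix>`` (e.g.
    ``PGI1_Scer``); the hybrid organism's own ORF id is kept as the
    gene's ``name``.  Stoichiometry and bounds are untouched.  Reactions
    whose rule loses all support carry the ``UNSATISFIABLE`` sentinel
    until :func:`prune` removes them.
    """
    suffixes = dict(DEFAULT_SUFFIXES if suffixes is None else suffixes)
    if len(set(suffixes.values())) != len(suffixes):
        raise ValueError(f"suffix collision: {suffixes}")

    new = template.copy()
    new.genes = {}
    allele_leaves: dict[str, GPRNode | None] = {}
    new_gene_ids: dict[str, str] = {}

    for gene_id, template_gene in template.genes.items():
        triples = mapping.alleles.get(gene_id)
        if not triples:
            allele_leaves[gene_id] = None
            continue
        leaves = []
        allele_ids: dict[str, str] = {}
        for hybrid_id, parent, _evidence in triples:
            allele_id = _allele_gene_id(template_gene, suffixes[parent])
            if allele_id in new.genes:
                raise ValueError(
                    f"suffix collision: allele id {allele_id!r} produced twice"
                )
            new.genes[allele_id] = Gene(
                id=allele_id, name=hybrid_id, origin=parent
            )
            allele_ids[parent] = allele_id
            leaves.append(GPRNode("leaf", gene_id=allele_id))
        if len(allele_ids) == 2:
            a, b = allele_ids[PARENT_A], allele_ids[PARENT_B]
            new.genes[a].allele_partner = b
            new.genes[b].allele_partner = a
        allele_leaves[gene_id] = (
            leaves[0] if len(leaves) == 1 else GPRNode("or", children=tuple(leaves))
        )
        new_gene_ids[gene_id] = ",".join(sorted(allele_ids.values()))

    for rxn in new.reactions.values():
        if isinstance(rxn.gpr, GPRNode):
            rxn.gpr = _rewrite_node(rxn.gpr, allele_leaves)
            if rxn.gpr is None:  # pragma: no cover - defensive
                rxn.gpr = UNSATISFIABLE
    return new


@dataclass(frozen=True)
class RemovalRecord:
    entity_id: str
    kind: str  # "reaction" | "gene"
    reason: str


def prune(model: Model) -> tuple[Model, list[RemovalRecord]]:
    """Drop unsatisfiable reactions, then genes left in no GPR.

    A reaction is removed iff its GPR cannot be satisfied even with
    every remaining gene present (i.e. it carries the ``UNSATISFIABLE``
    sentinel after rewriting).  Reactions without a GPR (exchanges,
    spontaneous, biomass) are never pruned.  Gene removal runs second,
    so genes orphaned by reaction removal are also dropped.
    """
    new = model.copy()
    report: list[RemovalRecord] = []
    for rxn_id in [r.id for r in new.reactions.values() if r.gpr is UNSATISFIABLE]:
        del new.reactions[rxn_id]
        report.append(
            RemovalRecord(rxn_id, "reaction", "GPR unsatisfiable: no supporting genes")
        )
    used: set[str] = set()
    for rxn in new.reactions.values():
        if isinstance(rxn.gpr, GPRNode):
            used |= genes_of(rxn.gpr)
    for gene_id in sorted(set(new.genes) - used):
        del new.genes[gene_id]
        report.append(RemovalRecord(gene_id, "gene", "not associated to any reaction"))
    return new, report


# ---------------------------------------------------------------------------
# Manual curation

_CURATION_KINDS = (
    "reintegrate_reaction",
    "add_reaction",
    "add_gene",
    "remove_gene",
    "remove_reaction",
)


@dataclass(frozen=True)
class CurationAction:
    """One manual curation step, replayable and idempotent.

    ``payload`` for reaction kinds: ``stoichiometry`` (metabolite id →
    coefficient), optional ``lower_bound``/``upper_bound``/``name``/
    ``gpr`` (rule string)/``sbo``/``new_metabolites``; for ``add_gene``:
    ``name``/``origin``/``allele_partner``.  New reactions must balance
    elementally unless ``balance_waiver`` is set.
    """

    kind: str
    target_id: str
    payload: Mapping | None = None
    note: str = ""
    balance_waiver: bool = False
    amend: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _CURATION_KINDS:
            raise ValueError(f"unknown curation kind {self.kind!r}")
        if self.kind in ("reintegrate_reaction", "add_reaction", "add_gene") and (
            self.payload is None
        ):
            raise ValueError(f"curation {self.kind}:{self.target_id} needs a payload")


def _reaction_from_payload(target_id: str, payload: Mapping) -> Reaction:
    gpr_text = payload.get("gpr")
    stoich = {k: float(v) for k, v in dict(payload["stoichiometry"]).items()}
    reversible = bool(payload.get("reversible", False))
    return Reaction(
        id=target_id,
        name=payload.get("name", ""),
        stoichiometry=stoich,
        lower_bound=float(
            payload.get("lower_bound", -1000.0 if reversible else 0.0)
        ),
        upper_bound=float(payload.get("upper_bound", 1000.0)),
        gpr=parse_gpr(gpr_text) if gpr_text else None,
        sbo_term=payload.get("sbo"),
    )


def _same_reaction(a: Reaction, b: Reaction) -> bool:
    return (
        a.stoichiometry == b.stoichiometry
        and a.bounds == b.bounds
        and repr(a.gpr) == repr(b.gpr)
    )


def apply_curation(model: Model, actions: Sequence[CurationAction]) -> Model:
    """Apply curation actions in order; replaying the list is a no-op.

    Adding an entity that already exists is an error unless the existing
    entity is identical to the payload (idempotent replay) or the action
    carries ``amend=True``.  Removing an already-absent entity is a
    no-op, so remove→add sequences replay cleanly.
    """
    new = model.copy()
    for action in actions:
        if action.kind in ("add_reaction", "reintegrate_reaction"):
            payload = action.payload or {}
            for met in payload.get("new_metabolites", []):
                if met["id"] not in new.metabolites:
                    new.add_metabolite(Metabolite(**met))
            rxn = _reaction_from_payload(action.target_id, payload)
            existing = new.reactions.get(action.target_id)
            if existing is not None:
                if action.amend or _same_reaction(existing, rxn):
                    new.reactions[action.target_id] = rxn
                else:
                    raise ValueError(
                        f"reaction {action.target_id!r} already exists with a "
                        "different definition (set amend to overwrite)"
                    )
            else:
                new.add_reaction(rxn)
            if isinstance(rxn.gpr, GPRNode):
                for gene_id in genes_of(rxn.gpr):
                    if gene_id not in new.genes:
                        new.add_gene(Gene(id=gene_id, origin=infer_origin(gene_id)))
            if not action.balance_waiver and not rxn.is_exchange:
                report = check_balance(rxn, new.metabolites)
                if report.status == "imbalanced":
                    raise ValueError(
                        f"curated reaction {rxn.id!r} is not balanced: "
                        f"{report.element_delta} (set balance_waiver to accept)"
                    )
        elif action.kind == "add_gene":
            payload = dict(action.payload or {})
            existing_gene = new.genes.get(action.target_id)
            gene = Gene(id=action.target_id, **payload)
            if existing_gene is not None and existing_gene != gene and not action.amend:
                raise ValueError(
                    f"gene {action.target_id!r} already exists with different fields"
                )
            new.genes[action.target_id] = gene
        elif action.kind == "remove_reaction":
            new.reactions.pop(action.target_id, None)
        elif action.kind == "remove_gene":
            new.genes.pop(action.target_id, None)
        if action.note:
            new.provenance[action.target_id] = action.note
        else:
            new.provenance.setdefault(action.target_id, f"curation:{action.kind}")
    return new


def load_ortholog_table(path: str | Path) -> list[OrthologRecord]:
    """Read an ortholog table TSV with columns ``hybrid_gene_id,
    template_gene_id, parent, percent_identity, evidence`` (evidence
    defaults to ``gene``)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    needed = {"hybrid_gene_id", "template_gene_id", "parent", "percent_identity"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"ortholog table missing column(s): {sorted(missing)}")
    return [
        OrthologRecord(
            hybrid_gene_id=row["hybrid_gene_id"],
            template_gene_id=row["template_gene_id"],
            parent=row["parent"],
            percent_identity=float(row["percent_identity"]),
            evidence=row.get("evidence", "gene") if "evidence" in df.columns else "gene",
        )
        for _, row in df.iterrows()
    ]


def write_removal_report(report: Sequence[RemovalRecord], path: str | Path) -> None:
    """Write a prune report as a TSV (entity, kind, reason)."""
    import pandas as pd

    pd.DataFrame(
        [{"entity": r.entity_id, "kind": r.kind, "reason": r.reason} for r in report]
    ).to_csv(path, sep="\t", index=False)


def load_curation_actions(path: str | Path) -> list[CurationAction]:
    """Load a curation list from a YAML or JSON file."""
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, list):
        raise ValueError("curation file must contain a list of actions")
    return [CurationAction(**entry) for entry in raw]
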