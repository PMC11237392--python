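"""Parental-allele attribution of reaction activity.

In a hybrid, a reaction supported by redundant parental alleles can be
carried by either sub-genome; expression data reveal which parent's
copies actually do the work in a given condition.  For a group of
alternative catalysts (a pure ``or`` rule) each parent's share is its
alleles' fraction of the group's total TPM.  For a complex (``and`` of
groups) the reaction share is the unweighted mean of the per-group
shares — each subunit slot counts equally.  Shares from conditions at
different temperatures can then be compared to detect shifts of
parental allele usage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .gpr import AND, GPRNode, aggregate_expression, genes_of
from .model import Model, infer_origin

__all__ = [
    "AlleleShare",
    "attribute_reaction",
    "attribute_model",
    "detect_shift",
    "round_share",
]

logger = logging.getLogger(__name__)

PARENT_A = "parentA"
PARENT_B = "parentB"

#: Total supporting TPM at or below this makes a share inconclusive.
DEFAULT_THRESHOLD = 10.0
DEFAULT_SHIFT_DELTA = 0.10


@dataclass(frozen=True)
class AlleleShare:
    """Parental proportions supporting one reaction in one condition.

    For a conclusive share ``prop_parentA + prop_parentB == 1``; an
    inconclusive share (supporting expression at or below threshold)
    carries NaN proportions.
    """

    reaction_id: str
    prop_parentA: float
    prop_parentB: float
    status: str  # "conclusive" | "inconclusive"
    condition: str = ""

    @property
    def conclusive(self) -> bool:
        return self.status == "conclusive"


def _origin_share(
    node: GPRNode,
    tpm: Mapping[str, float],
    origin: Mapping[str, str],
) -> tuple[float, float]:
    """Recursive (parentA share, weight) of a GPR subtree.

    The weight is the subtree's aggregate expression; an ``or`` node
    averages child shares weighted by child capacity, an ``and`` node
    takes the unweighted mean of child shares.  Shares are NaN when the
    subtree has no supporting expression.
    """
    if node.kind == "leaf":
        gene = node.gene_id
        parent = origin.get(gene)
        if parent is None:
            raise KeyError(f"gene {gene!r} has no parental origin")
        if parent not in (PARENT_A, PARENT_B):
            raise ValueError(
                f"gene {gene!r} has origin {parent!r}; parental attribution "
                "requires parentA or parentB"
            )
        weight = float(tpm.get(gene, 0.0))
        share = (1.0 if parent == PARENT_A else 0.0) if weight > 0 else math.nan
        return share, weight
    child = [_origin_share(c, tpm, origin) for c in node.children]
    if node.kind == AND:
        shares = [s for s, _ in child]
        mean = (
            math.nan
            if any(math.isnan(s) for s in shares)
            else sum(shares) / len(shares)
        )
        weight = min(w for _, w in child)
        return mean, weight
    # OR: capacity-weighted mixture of alternatives
    total = sum(w for _, w in child)
    if total <= 0:
        return math.nan, 0.0
    share = sum(s * w for s, w in child if w > 0) / total
    return share, total


def attribute_reaction(
    gpr: GPRNode,
    tpm: Mapping[str, float],
    origin: Mapping[str, str],
    threshold: float = DEFAULT_THRESHOLD,
    reaction_id: str = "",
    condition: str = "",
) -> AlleleShare:
    """Attribute one reaction's supporting expression to the two parents.

    ``origin`` maps each leaf gene to ``parentA``/``parentB``; a missing
    or non-parental origin is a hard error.  The share is inconclusive
    when total supporting TPM over all leaves is at or below
    ``threshold``.
    """
    total_tpm = sum(float(tpm.get(g, 0.0)) for g in genes_of(gpr))
    share, _weight = _origin_share(gpr, tpm, origin)
    if total_tpm <= threshold or math.isnan(share):
        return AlleleShare(reaction_id, math.nan, math.nan, "inconclusive", condition)
    return AlleleShare(reaction_id, share, 1.0 - share, "conclusive", condition)


def attribute_model(
    model: Model,
    profiles: Mapping[str, "ExpressionProfile"],
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Attribute every gene-associated reaction across conditions.

    ``profiles`` maps condition labels to expression profiles.  Gene
    origins come from the model's gene table, falling back to allele
    suffixes.  Reactions with genes missing from a condition's profile
    are inconclusive for that condition (logged).  Returns a tidy frame
    with one row per (reaction, condition).
    """
    origin = {
        g.id: (g.origin if g.origin != "template" else infer_origin(g.id))
        for g in model.genes.values()
    }
    rows = []
    for condition, profile in profiles.items():
        tpm = profile.tpm
        for rxn in model.reactions.values():
            if not isinstance(rxn.gpr, GPRNode):
                continue
            leaves = genes_of(rxn.gpr)
            missing = leaves - set(tpm)
            if missing:
                logger.warning(
                    "condition %s: reaction %s inconclusive, genes not "
                    "measured: %s",
                    condition,
                    rxn.id,
                    sorted(missing),
                )
                share = AlleleShare(
                    rxn.id, math.nan, math.nan, "inconclusive", condition
                )
            else:
                share = attribute_reaction(
                    rxn.gpr, tpm, origin, threshold, rxn.id, condition
                )
            rows.append(
                {
                    "reaction_id": share.reaction_id,
                    "condition": share.condition,
                    "prop_parentA": share.prop_parentA,
                    "prop_parentB": share.prop_parentB,
                    "status": share.status,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["reaction_id", "condition", "prop_parentA", "prop_parentB", "status"],
    )


def detect_shift(
    shares: Sequence[AlleleShare],
    delta: float = DEFAULT_SHIFT_DELTA,
) -> str:
    """Classify allele usage across ordered conditions.

    Returns ``"shifted"`` when the parentA proportion differs by at
    least ``delta`` between any two conclusive conditions, ``"stable"``
    otherwise, and ``"indeterminate"`` with fewer than two conclusive
    conditions.
    """
    props = [s.prop_parentA for s in shares if s.conclusive]
    if len(props) < 2:
        return "indeterminate"
    spread = max(props) - min(props)
    return "shifted" if spread >= delta else "stable"


def round_share(value: float, granularity: float = 0.05) -> float:
    """Round a proportion to report granularity (default 5%)."""
    if math.isnan(value):
        return value
    return round(value / granularity) * granularity
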