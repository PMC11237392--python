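"""TPM normalization and transcriptome-to-flux-bound mapping.

Raw RNA-seq counts are normalized to transcripts per million (TPM):
RPK = count / gene length in kb; the per-million scaling factor is
ΣRPK / 1e6; TPM = RPK / factor.  Every library then sums to exactly
1e6, so genes are comparable across libraries.

TPM values are mapped onto reaction bounds through the GPR rules: the
capacity of a reaction is the recursive aggregate of its gene levels
(``or`` = sum of alternative catalysts, ``and`` = min over complex
subunits).  A reaction is constrained only when *all* genes in its GPR
are expressed above a noise threshold (default 10 TPM).  Irreversible
reactions have their upper bound capped at the aggregate; reversible
reactions are capped symmetrically at ±aggregate.  TPM magnitudes are
used directly as flux-bound magnitudes (mmol·gDCW⁻¹·h⁻¹) — a heuristic
unit convention, with bounds only ever tightened, never widened.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .gpr import GPRNode, aggregate_expression, evaluate_boolean, genes_of
from .model import Model

__all__ = [
    "ExpressionProfile",
    "ConstraintConfig",
    "tpm_normalize",
    "map_transcriptome_data",
    "count_constrained",
    "read_expression_tsv",
]


@dataclass
class ExpressionProfile:
    """Per-gene raw counts, lengths, RPK and TPM for one library."""

    library_id: str
    data: pd.DataFrame  # index gene_id; columns raw_count, length_kb, rpk, tpm

    @property
    def tpm(self) -> dict[str, float]:
        return self.data["tpm"].to_dict()

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


def tpm_normalize(
    counts: Mapping[str, float],
    lengths_kb: Mapping[str, float],
    library_id: str = "library",
) -> ExpressionProfile:
    """Normalize raw counts to TPM.

    Counts are non-negative (fractional pseudo-counts are accepted, e.g.
    from synthetic generators); lengths are in kilobases and must be
    positive.  The returned library sums to 1e6 by construction.
    """
    if not counts:
        raise ValueError("empty library: no genes to normalize")
    missing = set(counts) - set(lengths_kb)
    if missing:
        raise ValueError(f"genes without a length: {sorted(missing)[:5]}")
    rows = []
    for gene, count in counts.items():
        length = float(lengths_kb[gene])
        if length <= 0:
            raise ValueError(f"gene {gene!r} has non-positive length {length}")
        if count < 0:
            raise ValueError(f"gene {gene!r} has negative count {count}")
        rows.append((gene, float(count), length, float(count) / length))
    df = pd.DataFrame(
        rows, columns=["gene", "raw_count", "length_kb", "rpk"]
    ).set_index("gene")
    total_rpk = df["rpk"].sum()
    if total_rpk <= 0:
        raise ValueError("library has zero total RPK; cannot scale to TPM")
    df["tpm"] = df["rpk"] / (total_rpk / 1e6)
    return ExpressionProfile(library_id, df)


def read_expression_tsv(path: str, library_id: str | None = None) -> ExpressionProfile:
    """Read an expression TSV: ``gene_id, raw_count, length_bp`` (lengths
    converted to kb) or a precomputed ``tpm`` column."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError("expression TSV needs a 'gene_id' column")
    lib = library_id or str(path)
    if "tpm" in df.columns:
        data = pd.DataFrame(
            {
                "raw_count": float("nan"),
                "length_kb": float("nan"),
                "rpk": float("nan"),
                "tpm": df["tpm"].astype(float).values,
            },
            index=df["gene_id"],
        )
        return ExpressionProfile(lib, data)
    if not {"raw_count", "length_bp"} <= set(df.columns):
        raise ValueError(
            "expression TSV needs either a 'tpm' column or both "
            "'raw_count' and 'length_bp'"
        )
    counts = dict(zip(df["gene_id"], df["raw_count"].astype(float)))
    lengths = dict(zip(df["gene_id"], df["length_bp"].astype(float) / 1000.0))
    return tpm_normalize(counts, lengths, lib)


@dataclass(frozen=True)
class ConstraintConfig:
    """Settings for expression-constrained bounds.

    ``threshold_abundance``: a gene counts as expressed only strictly
    above this TPM (default 10, above typical noise).  ``max_bound``:
    the unconstrained bound magnitude of the model (default 1000);
    aggregates are clipped to it.  ``gate``: ``"all"`` requires every
    gene in the GPR above threshold (default); ``"any_branch"`` only
    requires that some Boolean branch of expressed genes can satisfy
    the rule.
    """

    threshold_abundance: float = 10.0
    max_bound: float = 1000.0
    gate: str = "all"

    def __post_init__(self) -> None:
        if self.threshold_abundance <= 0 or self.max_bound <= 0:
            raise ValueError("threshold_abundance and max_bound must be positive")
        if self.gate not in ("all", "any_branch"):
            raise ValueError(f"unknown gate mode {self.gate!r}")


def map_transcriptome_data(
    model: Model,
    tpm: Mapping[str, float],
    config: ConstraintConfig = ConstraintConfig(),
) -> tuple[Model, int]:
    """Constrain reaction bounds from a TPM profile via the GPR rules.

    Returns the constrained copy of the model and the number of
    reactions whose bounds actually changed.  Reactions without a GPR
    are skipped; bounds are only ever tightened (clipped against the
    current bounds), so irreversibility is never relaxed.
    """
    new = model.copy()
    n_constrained = 0
    threshold = config.threshold_abundance
    for rxn in new.reactions.values():
        gpr = rxn.gpr
        if not isinstance(gpr, GPRNode):
            continue
        leaves = genes_of(gpr)
        if config.gate == "all":
            if not all(float(tpm.get(g, 0.0)) > threshold for g in leaves):
                continue
        else:  # any_branch: some fully-expressed branch satisfies the rule
            silent = {g for g in leaves if float(tpm.get(g, 0.0)) <= threshold}
            if not evaluate_boolean(gpr, silent):
                continue
        capacity = min(aggregate_expression(gpr, tpm), config.max_bound)
        old = rxn.bounds
        if rxn.lower_bound >= 0:  # irreversible
            rxn.upper_bound = min(rxn.upper_bound, capacity)
        else:  # reversible: symmetric cap
            rxn.upper_bound = min(rxn.upper_bound, capacity)
            rxn.lower_bound = max(rxn.lower_bound, -capacity)
        if rxn.bounds != old:
            n_constrained += 1
    return new, n_constrained


def count_constrained(model_before: Model, model_after: Model) -> int:
    """Number of reactions whose bounds differ between two models."""
    if set(model_before.reactions) != set(model_after.reactions):
        raise ValueError("models do not share the same reaction set")
    return sum(
        1
        for rxn_id, before in model_before.reactions.items()
        if before.bounds != model_after.reactions[rxn_id].bounds
    )
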