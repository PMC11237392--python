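"""Plain-text tabular model dialect and medium files.

Three TSVs describe a model:

* ``reactions.tsv`` — columns ``id, name, equation, lb, ub, gpr, sbo``
  plus an optional ``objective`` flag (1 marks the objective reaction);
  the equation uses ``2 A + B -> C`` syntax with ``->`` for irreversible
  and ``<=>`` for reversible reactions.  Omitted bounds default to
  [0, 1000] (irreversible) or [-1000, 1000] (reversible).
* ``metabolites.tsv`` — ``id, name, compartment, formula, charge``.
* ``genes.tsv`` — ``id, name, origin, allele_partner`` (optional file;
  genes referenced only in GPRs are created with suffix-inferred origin).

Media are a TSV with columns ``exchange_id, lb, ub`` or a JSON object
``{"EX_glc": [-20, 1000], ...}``.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path

import pandas as pd

from .gpr import format_gpr, genes_of, parse_gpr
from .model import (
    DEFAULT_LOWER_BOUND_REVERSIBLE,
    DEFAULT_UPPER_BOUND,
    Gene,
    Metabolite,
    Model,
    Reaction,
    format_formula,
    infer_origin,
)

__all__ = [
    "read_tabular_model",
    "write_tabular_model",
    "read_medium",
    "parse_equation",
    "format_equation",
]

_TERM = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def _parse_side(text: str, sign: float, stoich: dict[str, float]) -> None:
    text = text.strip()
    if not text:
        return
    for term in text.split(" + "):
        term = term.strip()
        match = _TERM.match(term)
        if not match:
            raise ValueError(f"cannot parse equation term {term!r}")
        coeff_text, met_id = match.groups()
        coeff = float(coeff_text) if coeff_text else 1.0
        stoich[met_id] = stoich.get(met_id, 0.0) + sign * coeff


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``2 A + B -> C`` into (stoichiometry, reversible)."""
    if "<=>" in text:
        left, right = text.split("<=>", 1)
        reversible = True
    elif "->" in text:
        left, right = text.split("->", 1)
        reversible = False
    else:
        raise ValueError(f"equation {text!r} lacks an arrow ('->' or '<=>')")
    stoich: dict[str, float] = {}
    _parse_side(left, -1.0, stoich)
    _parse_side(right, +1.0, stoich)
    return {k: v for k, v in stoich.items() if v != 0.0}, reversible


def format_equation(stoich: dict[str, float], reversible: bool) -> str:
    def side(items: list[tuple[str, float]]) -> str:
        parts = []
        for met_id, coeff in items:
            coeff = abs(coeff)
            parts.append(met_id if coeff == 1 else f"{coeff:g} {met_id}")
        return " + ".join(parts)

    left = side(sorted((m, c) for m, c in stoich.items() if c < 0))
    right = side(sorted((m, c) for m, c in stoich.items() if c > 0))
    arrow = "<=>" if reversible else "->"
    return f"{left} {arrow} {right}"


def _require_columns(df: pd.DataFrame, needed: list[str], what: str) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def _opt(row, column, default=None):
    if column not in row or row[column] is None:
        return default
    value = row[column]
    if isinstance(value, float) and math.isnan(value):
        return default
    if isinstance(value, str) and not value.strip():
        return default
    return value


def read_tabular_model(
    reactions_tsv: str | Path,
    metabolites_tsv: str | Path,
    genes_tsv: str | Path | None = None,
    model_id: str = "model",
) -> Model:
    """Assemble a model from the TSV dialect (see module docstring)."""
    model = Model(id=model_id)

    mets = pd.read_csv(metabolites_tsv, sep="\t", dtype=str)
    _require_columns(mets, ["id"], "metabolites.tsv")
    for _, row in mets.iterrows():
        charge = _opt(row, "charge")
        model.add_metabolite(
            Metabolite(
                id=row["id"],
                name=_opt(row, "name", "") or "",
                compartment=_opt(row, "compartment", "c") or "c",
                formula=_opt(row, "formula"),
                charge=int(charge) if charge is not None else None,
            )
        )

    if genes_tsv is not None:
        genes = pd.read_csv(genes_tsv, sep="\t", dtype=str)
        _require_columns(genes, ["id"], "genes.tsv")
        for _, row in genes.iterrows():
            model.add_gene(
                Gene(
                    id=row["id"],
                    name=_opt(row, "name", "") or "",
                    origin=_opt(row, "origin") or infer_origin(row["id"]),
                    allele_partner=_opt(row, "allele_partner"),
                )
            )

    rxns = pd.read_csv(reactions_tsv, sep="\t", dtype=str)
    _require_columns(rxns, ["id", "equation"], "reactions.tsv")
    for _, row in rxns.iterrows():
        stoich, reversible = parse_equation(row["equation"])
        lb = _opt(row, "lb")
        ub = _opt(row, "ub")
        lower = float(lb) if lb is not None else (
            DEFAULT_LOWER_BOUND_REVERSIBLE if reversible else 0.0
        )
        upper = float(ub) if ub is not None else DEFAULT_UPPER_BOUND
        gpr_text = _opt(row, "gpr")
        gpr = parse_gpr(gpr_text) if gpr_text else None
        rxn = Reaction(
            id=row["id"],
            name=_opt(row, "name", "") or "",
            stoichiometry=stoich,
            lower_bound=lower,
            upper_bound=upper,
            gpr=gpr,
            sbo_term=_opt(row, "sbo"),
        )
        model.add_reaction(rxn)
        objective_flag = _opt(row, "objective")
        if objective_flag is not None and str(objective_flag).strip() not in ("0", "false", "False"):
            model.objective_reaction_id = rxn.id
        if gpr is not None:
            for gene_id in genes_of(gpr):
                if gene_id not in model.genes:
                    model.add_gene(Gene(id=gene_id, origin=infer_origin(gene_id)))

    model.validate()
    return model


def write_tabular_model(model: Model, out_dir: str | Path) -> dict[str, Path]:
    """Write the three-TSV representation of ``model`` into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reactions": out / "reactions.tsv",
        "metabolites": out / "metabolites.tsv",
        "genes": out / "genes.tsv",
    }
    pd.DataFrame(
        [
            {
                "id": r.id,
                "name": r.name,
                "equation": format_equation(r.stoichiometry, r.reversible),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": format_gpr(r.gpr) if r.gpr is not None else "",
                "sbo": r.sbo_term or "",
                "objective": 1 if r.id == model.objective_reaction_id else "",
            }
            for r in model.reactions.values()
        ]
    ).to_csv(paths["reactions"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": format_formula(m.formula) if m.formula else "",
                "charge": "" if m.charge is None else m.charge,
            }
            for m in model.metabolites.values()
        ]
    ).to_csv(paths["metabolites"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "id": g.id,
                "name": g.name,
                "origin": g.origin,
                "allele_partner": g.allele_partner or "",
            }
            for g in model.genes.values()
        ]
    ).to_csv(paths["genes"], sep="\t", index=False)
    return paths


def read_medium(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read a medium spec from TSV (exchange_id, lb, ub) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return {k: (float(v[0]), float(v[1])) for k, v in data.items()}
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["exchange_id", "lb", "ub"], "medium TSV")
    return {
        row["exchange_id"]: (float(row["lb"]), float(row["ub"]))
        for _, row in df.iterrows()
    }
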