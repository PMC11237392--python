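"""Flux balance analysis and derived simulations.

FBA solves the linear program

    max  cᵀ·v   s.t.   S·v = 0,   v_l ≤ v ≤ v_u

over the m×n stoichiometric matrix S (metabolites × reactions); the
objective is usually the biomass pseudo-reaction.  FVA then minimizes
and maximizes each flux of interest under the extra constraint
wᵀ·v ≥ γ·Z₀, holding the network at a fraction γ of the FBA optimum Z₀
(2 LPs per reaction).  Gene knockouts close every reaction whose GPR is
Boolean-false with the deleted genes absent; an entity is called
essential when its removal drops growth below a fraction of wild type.

LPs are solved with scipy's HiGHS interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .gpr import AND, OR, GPRNode, evaluate_boolean, genes_of
from .model import MediumSpec, Model, apply_medium

__all__ = [
    "LPProblem",
    "FluxResult",
    "FVAResult",
    "EssentialityReport",
    "GPRCensus",
    "build_lp",
    "run_fba",
    "run_fva",
    "knockout",
    "essentiality_scan",
    "gpr_census",
]

#: |S·v| above this is treated as a solver failure, not rounding noise.
MASS_BALANCE_TOL = 1e-6
#: slack allowed when asserting bound feasibility of a returned vertex
BOUND_TOL = 1e-7
DEFAULT_ESSENTIALITY_THRESHOLD = 0.01


@dataclass
class LPProblem:
    S: sparse.csr_matrix
    c: np.ndarray
    v_l: np.ndarray
    v_u: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]

    def __post_init__(self) -> None:
        m, n = self.S.shape
        if not (len(self.c) == len(self.v_l) == len(self.v_u) == n):
            raise ValueError("LP dimensions inconsistent")
        if len(self.metabolite_ids) != m or len(self.reaction_ids) != n:
            raise ValueError("LP id lists inconsistent with S")
        if np.any(self.v_l > self.v_u):
            raise ValueError("lower bounds exceed upper bounds")


@dataclass
class FluxResult:
    fluxes: dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible" | "unbounded"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


@dataclass
class FVAResult:
    ranges: dict[str, tuple[float, float]]
    gamma: float
    objective_reaction_id: str
    objective_value: float


@dataclass
class EssentialityReport:
    mode: str  # "gene" | "reaction"
    classification: dict[str, str]  # id -> "essential" | "non-essential"
    wild_type_growth: float
    threshold_fraction: float
    medium_id: str = ""

    @property
    def essential(self) -> list[str]:
        return sorted(
            k for k, v in self.classification.items() if v == "essential"
        )

    @property
    def n_essential(self) -> int:
        return len(self.essential)


def build_lp(model: Model) -> LPProblem:
    """Assemble the stoichiometric LP: column j is reaction j's stoichiometry,
    c the indicator of the objective reaction."""
    met_ids = list(model.metabolites)
    rxn_ids = list(model.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    for j, rxn_id in enumerate(rxn_ids):
        for met_id, coeff in model.reactions[rxn_id].stoichiometry.items():
            rows.append(met_index[met_id])
            cols.append(j)
            vals.append(coeff)
    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
    )
    c = np.zeros(len(rxn_ids))
    if model.objective_reaction_id is not None:
        c[rxn_ids.index(model.objective_reaction_id)] = 1.0
    v_l = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    v_u = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    return LPProblem(S, c, v_l, v_u, rxn_ids, met_ids)


def _solve(
    lp: LPProblem,
    c: np.ndarray,
    maximize: bool,
    extra_A_ub: np.ndarray | None = None,
    extra_b_ub: np.ndarray | None = None,
):
    res = linprog(
        -c if maximize else c,
        A_eq=lp.S,
        b_eq=np.zeros(lp.S.shape[0]),
        A_ub=extra_A_ub,
        b_ub=extra_b_ub,
        bounds=np.column_stack([lp.v_l, lp.v_u]),
        method="highs",
    )
    return res


def _status_of(res) -> str:
    if res.status == 0:
        return "optimal"
    if res.status == 2:
        return "infeasible"
    if res.status == 3:
        return "unbounded"
    return f"solver-error({res.status})"


def run_fba(model: Model, lp: LPProblem | None = None) -> FluxResult:
    """Maximize the objective flux; returns the optimum and one optimal
    flux vector (degenerate optima mean the vector is not unique).

    Non-optimal solver statuses are propagated in ``status``, never
    silently reported as zero growth.
    """
    if model.objective_reaction_id is None:
        raise ValueError("model has no objective reaction")
    lp = lp or build_lp(model)
    res = _solve(lp, lp.c, maximize=True)
    status = _status_of(res)
    if status != "optimal":
        return FluxResult({}, float("nan"), status)
    v = res.x
    imbalance = np.abs(lp.S @ v).max() if lp.S.shape[0] else 0.0
    if imbalance > MASS_BALANCE_TOL:
        raise RuntimeError(f"steady-state violation |S·v|∞ = {imbalance:g}")
    if np.any(v < lp.v_l - BOUND_TOL) or np.any(v > lp.v_u + BOUND_TOL):
        raise RuntimeError("solver returned a bound-infeasible vertex")
    return FluxResult(dict(zip(lp.reaction_ids, v)), float(-res.fun), "optimal")


def run_fva(
    model: Model,
    reactions: Iterable[str] | None = None,
    gamma: float = 1.0,
) -> FVAResult:
    """Per-reaction flux min/max at a fraction ``gamma`` of the optimum.

    Solves 2 LPs per reaction of interest under wᵀ·v ≥ γ·Z₀, where w is
    the FBA objective and Z₀ its optimum.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    lp = build_lp(model)
    wild = run_fba(model, lp)
    if wild.status != "optimal":
        raise ValueError(f"FBA on the input model is {wild.status}")
    z0 = wild.objective_value
    # w^T v >= gamma * z0  as  -w^T v <= -gamma * z0
    A_ub = -lp.c.reshape(1, -1)
    b_ub = np.array([-gamma * z0])
    targets = list(reactions) if reactions is not None else list(lp.reaction_ids)
    unknown = set(targets) - set(lp.reaction_ids)
    if unknown:
        raise ValueError(f"unknown reactions for FVA: {sorted(unknown)}")
    ranges: dict[str, tuple[float, float]] = {}
    e = np.zeros(len(lp.reaction_ids))
    for rxn_id in targets:
        j = lp.reaction_ids.index(rxn_id)
        e[:] = 0.0
        e[j] = 1.0
        lo = _solve(lp, e, maximize=False, extra_A_ub=A_ub, extra_b_ub=b_ub)
        hi = _solve(lp, e, maximize=True, extra_A_ub=A_ub, extra_b_ub=b_ub)
        if lo.status != 0 or hi.status != 0:
            ranges[rxn_id] = (float("nan"), float("nan"))
        else:
            ranges[rxn_id] = (float(lo.fun), float(-hi.fun))
    return FVAResult(ranges, gamma, model.objective_reaction_id or "", z0)


def knockout(model: Model, genes: Iterable[str]) -> Model:
    """Delete ``genes``: reactions whose GPR is unsatisfied get bounds
    (0, 0); reactions without a GPR are untouched.  Order-independent."""
    absent = set(genes)
    unknown = absent - set(model.genes)
    if unknown:
        raise KeyError(f"unknown gene(s): {sorted(unknown)}")
    new = model.copy()
    for rxn in new.reactions.values():
        if isinstance(rxn.gpr, GPRNode) and not evaluate_boolean(rxn.gpr, absent):
            rxn.bounds = (0.0, 0.0)
    return new


def essentiality_scan(
    model: Model,
    medium: MediumSpec | None = None,
    mode: str = "gene",
    threshold_fraction: float = DEFAULT_ESSENTIALITY_THRESHOLD,
    medium_id: str = "",
) -> EssentialityReport:
    """Single-deletion scan: an entity is essential iff the knockout
    optimum falls below ``threshold_fraction`` × wild-type optimum.

    Gene mode closes all reactions whose GPR fails without the gene
    (one LP per gene, skipped when no reaction is affected); reaction
    mode zeroes each reaction's bounds in turn.
    """
    if mode not in ("gene", "reaction"):
        raise ValueError(f"mode must be 'gene' or 'reaction', got {mode!r}")
    work = apply_medium(model, medium) if medium is not None else model
    lp = build_lp(work)
    wild = run_fba(work, lp)
    if wild.status != "optimal" or wild.objective_value <= 0:
        raise ValueError(
            "wild-type growth is zero or infeasible; the medium cannot "
            "support growth"
        )
    cutoff = threshold_fraction * wild.objective_value
    classification: dict[str, str] = {}

    if mode == "gene":
        gene_to_rxn_cols: dict[str, list[int]] = {g: [] for g in work.genes}
        for j, rxn_id in enumerate(lp.reaction_ids):
            gpr = work.reactions[rxn_id].gpr
            if isinstance(gpr, GPRNode):
                for g in genes_of(gpr):
                    gene_to_rxn_cols.setdefault(g, []).append(j)
        for gene_id in work.genes:
            closed = [
                j
                for j in gene_to_rxn_cols.get(gene_id, [])
                if not evaluate_boolean(
                    work.reactions[lp.reaction_ids[j]].gpr, {gene_id}
                )
            ]
            if not closed:
                classification[gene_id] = "non-essential"
                continue
            v_l, v_u = lp.v_l.copy(), lp.v_u.copy()
            v_l[closed] = 0.0
            v_u[closed] = 0.0
            sub = LPProblem(lp.S, lp.c, v_l, v_u, lp.reaction_ids, lp.metabolite_ids)
            res = _solve(sub, sub.c, maximize=True)
            growth = -res.fun if res.status == 0 else 0.0
            classification[gene_id] = (
                "essential" if growth < cutoff else "non-essential"
            )
    else:
        for j, rxn_id in enumerate(lp.reaction_ids):
            v_l, v_u = lp.v_l.copy(), lp.v_u.copy()
            v_l[j] = 0.0
            v_u[j] = 0.0
            sub = LPProblem(lp.S, lp.c, v_l, v_u, lp.reaction_ids, lp.metabolite_ids)
            res = _solve(sub, sub.c, maximize=True)
            growth = -res.fun if res.status == 0 else 0.0
            classification[rxn_id] = (
                "essential" if growth < cutoff else "non-essential"
            )

    return EssentialityReport(
        mode, classification, wild.objective_value, threshold_fraction, medium_id
    )


# ---------------------------------------------------------------------------
# Census

@dataclass(frozen=True)
class GPRCensus:
    """Reaction counts by GPR structure; the six disjoint categories
    cover every reaction in the model."""

    single_gene: int
    or_only: int
    and_only: int
    mixed: int
    no_gene: int
    no_gene_exchange: int

    @property
    def total(self) -> int:
        return (
            self.single_gene
            + self.or_only
            + self.and_only
            + self.mixed
            + self.no_gene
            + self.no_gene_exchange
        )

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        return (
            self.single_gene,
            self.or_only,
            self.and_only,
            self.mixed,
            self.no_gene,
            self.no_gene_exchange,
        )


def _operators_of(node: GPRNode) -> set[str]:
    if node.kind == "leaf":
        return set()
    ops = {node.kind}
    for child in node.children:
        ops |= _operators_of(child)
    return ops


def gpr_census(model: Model) -> GPRCensus:
    """Classify each reaction by its GPR structure: single gene, pure
    ``or`` (redundant catalysts), pure ``and`` (one complex), mixed,
    or no gene association (exchanges counted separately)."""
    single = or_only = and_only = mixed = none = none_exch = 0
    for rxn in model.reactions.values():
        gpr = rxn.gpr
        if not isinstance(gpr, GPRNode):
            if rxn.is_exchange:
                none_exch += 1
            else:
                none += 1
            continue
        ops = _operators_of(gpr)
        if not ops:
            single += 1
        elif ops == {OR}:
            or_only += 1
        elif ops == {AND}:
            and_only += 1
        else:
            mixed += 1
    return GPRCensus(single, or_only, and_only, mixed, none, none_exch)
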