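"""Shared fixtures and oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from hybridgem.model import Gene, Metabolite, Model, Reaction
from hybridgem.gpr import parse_gpr


def make_chain_model(uptake: float = 10.0, with_gprs: bool = True) -> Model:
    """EX_A (uptake) -> A -> B -> biomass; optimum equals the uptake bound."""
    m = Model(id="chain")
    m.add_metabolite(Metabolite("A_e", "A external", "e", {"C": 1}))
    m.add_metabolite(Metabolite("A_c", "A internal", "c", {"C": 1}))
    m.add_reaction(
        Reaction("EX_A", "A exchange", {"A_e": -1.0}, -uptake, 1000.0)
    )
    m.add_reaction(
        Reaction(
            "T_A",
            "A transport",
            {"A_e": -1.0, "A_c": 1.0},
            0.0,
            1000.0,
            gpr=parse_gpr("GT") if with_gprs else None,
        )
    )
    m.add_reaction(Reaction("BIOMASS", "biomass", {"A_c": -1.0}, 0.0, 1000.0))
    if with_gprs:
        m.add_gene(Gene("GT", origin="template"))
    m.objective_reaction_id = "BIOMASS"
    m.validate()
    return m


def random_lp_model(seed: int, max_reactions: int = 12) -> Model:
    """Random small feasible-ish network for solver cross-checks.

    A few exchanges with random uptake bounds, random +-1/2 internal
    conversions (some reversible) and one drain objective.  Feasibility
    is not guaranteed; callers compare solver statuses too.
    """
    rng = np.random.default_rng(seed)
    n_mets = int(rng.integers(3, 6))
    model = Model(id=f"rand{seed}")
    met_ids = [f"M{i}" for i in range(n_mets)]
    for met_id in met_ids:
        model.add_metabolite(Metabolite(met_id, compartment="c"))
    n_exchanges = int(rng.integers(1, min(3, n_mets) + 1))
    for i in range(n_exchanges):
        uptake = float(rng.uniform(1.0, 20.0))
        model.add_reaction(
            Reaction(f"EX_{i}", "", {met_ids[i]: -1.0}, -uptake, 1000.0)
        )
    n_internal = int(rng.integers(2, max_reactions - n_exchanges - 1))
    for j in range(n_internal):
        subs, prods = rng.choice(n_mets, size=2, replace=False)
        stoich = {
            met_ids[subs]: -float(rng.integers(1, 3)),
            met_ids[prods]: float(rng.integers(1, 3)),
        }
        reversible = bool(rng.random() < 0.3)
        model.add_reaction(
            Reaction(
                f"R{j}", "", stoich, -1000.0 if reversible else 0.0, 1000.0
            )
        )
    target = met_ids[int(rng.integers(0, n_mets))]
    model.add_reaction(Reaction("DRAIN", "", {target: -1.0}, 0.0, 1000.0))
    model.objective_reaction_id = "DRAIN"
    model.validate()
    return model


def to_cobra(model: Model):
    """Convert to a cobrapy model (GLPK backend) as an independent oracle."""
    import cobra

    cm = cobra.Model(model.id)
    cm.add_metabolites(
        [cobra.Metabolite(m.id, compartment=m.compartment or "c")
         for m in model.metabolites.values()]
    )
    rxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id)
        cr.bounds = (r.lower_bound, r.upper_bound)
        rxns.append((cr, r.stoichiometry))
    cm.add_reactions([cr for cr, _ in rxns])
    for cr, stoich in rxns:
        cr.add_metabolites({cm.metabolites.get_by_id(k): v for k, v in stoich.items()})
    cm.objective = model.objective_reaction_id
    return cm


@pytest.fixture
def chain_model() -> Model:
    return make_chain_model()
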