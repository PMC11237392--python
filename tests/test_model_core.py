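"""Model types, tabular/SBML I/O, mass balance and media application."""

from __future__ import annotations

import textwrap

import pytest

from hybridgem.fba import gpr_census, run_fba
from hybridgem.gpr import format_gpr, parse_gpr
from hybridgem.model import (
    Metabolite,
    Model,
    ModelValidationError,
    Reaction,
    apply_medium,
    check_balance,
    format_formula,
    parse_formula,
)
from hybridgem.sbml_io import SBMLReadError, read_sbml, write_sbml
from hybridgem.tabular_io import (
    parse_equation,
    read_medium,
    read_tabular_model,
    write_tabular_model,
)

from conftest import make_chain_model


# ---------------------------------------------------------------------------
# formulas


@pytest.mark.parametrize(
    "text,counts",
    [
        ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
        ("H2O", {"H": 2, "O": 1}),
        ("NaCl", {"Na": 1, "Cl": 1}),
        ("C12H22O11", {"C": 12, "H": 22, "O": 11}),
    ],
)
def test_formula_round_trip(text, counts):
    assert parse_formula(text) == counts
    assert parse_formula(format_formula(counts)) == counts


def test_formula_rejects_garbage():
    with pytest.raises(ValueError):
        parse_formula("C6H12O6!")


# ---------------------------------------------------------------------------
# tabular dialect


def _write_tsvs(tmp_path, reactions, metabolites, genes=None):
    rp = tmp_path / "reactions.tsv"
    mp = tmp_path / "metabolites.tsv"
    rp.write_text(textwrap.dedent(reactions))
    mp.write_text(textwrap.dedent(metabolites))
    gp = None
    if genes is not None:
        gp = tmp_path / "genes.tsv"
        gp.write_text(textwrap.dedent(genes))
    return rp, mp, gp


def test_read_minimal_chain_network(tmp_path):
    rp, mp, _ = _write_tsvs(
        tmp_path,
        """\
        id\tname\tequation\tlb\tub\tgpr\tsbo
        EX_A\tA exchange\tA_e ->\t-10\t1000\t\t
        T_A\ttransport\tA_e -> A_c\t\t\tG1\t
        CONV\tconversion\tA_c <=> B_c\t\t\tG2 or G3\t
        BIO\tbiomass\tB_c ->\t\t\t\t
        """,
        """\
        id\tname\tcompartment\tformula\tcharge
        A_e\tA\te\tC6H12O6\t0
        A_c\tA\tc\tC6H12O6\t0
        B_c\tB\tc\tC6H12O6\t0
        """,
    )
    model = read_tabular_model(rp, mp)
    assert len(model.reactions) == 4
    assert model.reactions["T_A"].bounds == (0.0, 1000.0)  # irreversible default
    assert model.reactions["CONV"].bounds == (-1000.0, 1000.0)  # reversible default
    assert model.reactions["EX_A"].is_exchange
    assert format_gpr(model.reactions["CONV"].gpr) == "G2 or G3"
    assert set(model.genes) == {"G1", "G2", "G3"}


def test_missing_required_column_raises(tmp_path):
    rp, mp, _ = _write_tsvs(
        tmp_path,
        "id\tname\nR1\tno equation column\n",
        "id\nA_c\n",
    )
    with pytest.raises(ValueError, match="equation"):
        read_tabular_model(rp, mp)


def test_dangling_metabolite_id_raises(tmp_path):
    rp, mp, _ = _write_tsvs(
        tmp_path,
        "id\tequation\nR1\tA_c -> B_c\n",
        "id\nA_c\n",
    )
    with pytest.raises(ModelValidationError, match="B_c"):
        read_tabular_model(rp, mp)


def test_equation_parser_coefficients():
    stoich, reversible = parse_equation("2 A + B -> C")
    assert stoich == {"A": -2.0, "B": -1.0, "C": 1.0}
    assert not reversible
    assert parse_equation("A <=> B")[1] is True


def test_tabular_round_trip(tmp_path):
    model = make_chain_model()
    paths = write_tabular_model(model, tmp_path / "out")
    back = read_tabular_model(
        paths["reactions"], paths["metabolites"], paths["genes"]
    )
    assert set(back.reactions) == set(model.reactions)
    assert set(back.genes) == set(model.genes)
    for rxn_id, rxn in model.reactions.items():
        assert back.reactions[rxn_id].stoichiometry == rxn.stoichiometry
        assert back.reactions[rxn_id].bounds == rxn.bounds


# ---------------------------------------------------------------------------
# mass balance


def _mets(**formulas):
    return {
        met_id: Metabolite(met_id, formula=formula)
        for met_id, formula in formulas.items()
    }


def test_melibiose_hydrolysis_is_balanced():
    # melibiose + water -> glucose + galactose
    mets = _mets(
        melibiose="C12H22O11", water="H2O", glucose="C6H12O6", galactose="C6H12O6"
    )
    rxn = Reaction(
        "MELIBIASE",
        stoichiometry={"melibiose": -1, "water": -1, "glucose": 1, "galactose": 1},
    )
    report = check_balance(rxn, mets)
    assert report.balanced
    assert report.element_delta == {}


def test_carbon_imbalance_detected():
    mets = _mets(A="C", B="C2")
    report = check_balance(Reaction("R", stoichiometry={"A": -1, "B": 1}), mets)
    assert report.status == "imbalanced"
    assert report.element_delta == {"C": 1.0}


def test_exchange_is_exempt_and_missing_formula_indeterminate():
    mets = {"A": Metabolite("A", formula="C"), "X": Metabolite("X")}
    assert check_balance(Reaction("EX", stoichiometry={"A": -1}), mets).status == "exempt"
    rep = check_balance(Reaction("R", stoichiometry={"A": -1, "X": 1}), mets)
    assert rep.status == "indeterminate"
    assert rep.missing_formulas == ["X"]


def test_balance_equals_stoichiometric_dot_product():
    # oracle: naive summation over a random-ish reaction
    mets = _mets(A="C2H6O", B="CH4", C="C3H8O2")
    rxn = Reaction("R", stoichiometry={"A": -2, "B": 1, "C": 1})
    report = check_balance(rxn, mets)
    for element in ("C", "H", "O"):
        expected = sum(
            coeff * mets[met].formula.get(element, 0)
            for met, coeff in rxn.stoichiometry.items()
        )
        assert report.element_delta.get(element, 0.0) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# medium application


def test_glucose_uptake_twenty_sets_lower_bound(chain_model):
    fed = apply_medium(chain_model, {"EX_A": (-20.0, 1000.0)})
    assert fed.reactions["EX_A"].lower_bound == -20.0


def test_empty_medium_closes_all_uptakes(chain_model):
    starved = apply_medium(chain_model, {})
    assert starved.reactions["EX_A"].lower_bound == 0.0
    assert run_fba(starved).objective_value == pytest.approx(0.0)


def test_medium_on_non_exchange_raises(chain_model):
    with pytest.raises(ValueError, match="T_A"):
        apply_medium(chain_model, {"T_A": (-5.0, 5.0)})


def test_medium_file_formats(tmp_path):
    tsv = tmp_path / "m.tsv"
    tsv.write_text("exchange_id\tlb\tub\nEX_A\t-20\t1000\n")
    assert read_medium(tsv) == {"EX_A": (-20.0, 1000.0)}
    js = tmp_path / "m.json"
    js.write_text('{"EX_A": [-20, 1000]}')
    assert read_medium(js) == {"EX_A": (-20.0, 1000.0)}


# ---------------------------------------------------------------------------
# SBML round trip


def test_sbml_round_trip_census_identical(tmp_path, chain_model):
    path = tmp_path / "chain.xml"
    write_sbml(chain_model, path)
    back = read_sbml(path)
    assert gpr_census(back).as_tuple() == gpr_census(chain_model).as_tuple()
    assert set(back.reactions) == set(chain_model.reactions)
    assert set(back.genes) == set(chain_model.genes)
    assert back.objective_reaction_id == chain_model.objective_reaction_id
    for rxn_id, rxn in chain_model.reactions.items():
        assert back.reactions[rxn_id].bounds == rxn.bounds
        assert back.reactions[rxn_id].stoichiometry == rxn.stoichiometry
    assert sum(r.is_exchange for r in back.reactions.values()) == sum(
        r.is_exchange for r in chain_model.reactions.values()
    )


def test_sbml_preserves_boolean_structure(tmp_path):
    model = make_chain_model()
    model.reactions["T_A"].gpr = parse_gpr("(G2 or G3) and GT")
    for gid in ("G2", "G3"):
        from hybridgem.model import Gene

        model.add_gene(Gene(gid))
    path = tmp_path / "m.xml"
    write_sbml(model, path)
    back = read_sbml(path)
    assert format_gpr(back.reactions["T_A"].gpr) == "(G2 or G3) and GT"


def test_sbml_or_rule_reads_as_or_node(tmp_path, chain_model):
    chain_model.reactions["T_A"].gpr = parse_gpr("G1x or G2x")
    from hybridgem.model import Gene

    chain_model.add_gene(Gene("G1x"))
    chain_model.add_gene(Gene("G2x"))
    path = tmp_path / "m.xml"
    write_sbml(chain_model, path)
    node = read_sbml(path).reactions["T_A"].gpr
    assert node.kind == "or"
    assert {c.gene_id for c in node.children} == {"G1x", "G2x"}


def test_sbml_empty_gpr_emits_no_association(tmp_path, chain_model):
    path = tmp_path / "m.xml"
    write_sbml(chain_model, path)
    text = path.read_text()
    # only T_A carries a rule; exactly one association element is emitted
    assert text.count("geneProductAssociation") == 2  # open+close tags
    assert read_sbml(path).reactions["BIOMASS"].gpr is None


def test_sbml_rejects_level_2(tmp_path):
    bad = tmp_path / "l2.xml"
    bad.write_text(
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        '<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" '
        'version="4"><model id="m"/></sbml>\n'
    )
    with pytest.raises(SBMLReadError, match="Level"):
        read_sbml(bad)


def test_sbml_infers_origin_and_partners(tmp_path):
    model = Model(id="h")
    model.add_metabolite(Metabolite("A_c"))
    from hybridgem.model import Gene

    model.add_gene(Gene("PGI1_Scer", origin="parentA", allele_partner="PGI1_Seub"))
    model.add_gene(Gene("PGI1_Seub", origin="parentB", allele_partner="PGI1_Scer"))
    model.add_reaction(
        Reaction("R", stoichiometry={"A_c": -1.0}, gpr=parse_gpr("PGI1_Scer or PGI1_Seub"))
    )
    path = tmp_path / "h.xml"
    write_sbml(model, path)
    back = read_sbml(path)
    assert back.genes["PGI1_Scer"].origin == "parentA"
    assert back.genes["PGI1_Seub"].origin == "parentB"
    assert back.genes["PGI1_Scer"].allele_partner == "PGI1_Seub"
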