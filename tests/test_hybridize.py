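"""Hybrid model construction: mapping, GPR rewriting, pruning, curation."""

from __future__ import annotations

import pytest

from hybridgem.fba import knockout, run_fba
from hybridgem.gpr import GPRNode, evaluate_boolean, format_gpr, genes_of, parse_gpr
from hybridgem.hybridize import (
    UNSATISFIABLE,
    CurationAction,
    OrthologRecord,
    apply_curation,
    build_mapping,
    load_ortholog_table,
    prune,
    rewrite_gprs,
    venn_summary,
)
from hybridgem.model import Gene, Metabolite, Model, Reaction
from hybridgem.synthetic import ToyNetworkSpec, make_ortholog_tables, make_template


def _template(gene_ids):
    m = Model(id="tpl")
    m.add_metabolite(Metabolite("X_c"))
    for gid in gene_ids:
        m.add_gene(Gene(gid, name=gid))
    return m


def _rec(hybrid, template, parent, pid=95.0, evidence="gene"):
    return OrthologRecord(hybrid, template, parent, pid, evidence)


# ---------------------------------------------------------------------------
# mapping


def test_both_parents_mapped_as_two_alleles():
    tpl = _template(["PGI1"])
    mapping = build_mapping(
        tpl, [_rec("SP1", "PGI1", "parentA"), _rec("SP2", "PGI1", "parentB")]
    )
    assert mapping.parents_of("PGI1") == {"parentA", "parentB"}
    assert venn_summary(mapping).both == 1


def test_identity_threshold_is_strict():
    tpl = _template(["G1", "G2"])
    mapping = build_mapping(
        tpl,
        [
            _rec("SP1", "G1", "parentA", pid=70.0),  # exactly at threshold: out
            _rec("SP2", "G2", "parentA", pid=70.1),
        ],
        identity_threshold=70.0,
    )
    assert "G1" in mapping.unmapped_template_genes
    assert mapping.parents_of("G2") == {"parentA"}


def test_protein_evidence_rescues_gene_level_unmapped():
    tpl = _template(["G1"])
    mapping = build_mapping(
        tpl, [_rec("SP1", "G1", "parentB", evidence="protein")]
    )
    assert mapping.parents_of("G1") == {"parentB"}
    assert mapping.alleles["G1"][0][2] == "protein"


def test_gene_protein_conflict_logged_and_protein_wins():
    tpl = _template(["RPL12A", "RPL12B"])
    mapping = build_mapping(
        tpl,
        [
            _rec("SPX", "RPL12A", "parentA", evidence="gene"),
            _rec("SPX", "RPL12B", "parentA", evidence="protein"),
        ],
    )
    assert ("SPX", "RPL12A", "RPL12B") in mapping.conflicts
    assert mapping.parents_of("RPL12B") == {"parentA"}
    assert "RPL12A" in mapping.unmapped_template_genes


def test_duplicate_one_to_one_claims_raise():
    tpl = _template(["G1", "G2"])
    with pytest.raises(ValueError, match="duplicate"):
        build_mapping(
            tpl,
            [_rec("SP1", "G1", "parentA"), _rec("SP1", "G2", "parentA")],
        )


def test_venn_summary_constructed_counts():
    tpl = _template([f"G{i}" for i in range(10)])
    records = []
    for i in range(4):  # both
        records += [_rec(f"A{i}", f"G{i}", "parentA"), _rec(f"B{i}", f"G{i}", "parentB")]
    for i in range(4, 7):  # A only
        records.append(_rec(f"A{i}", f"G{i}", "parentA"))
    for i in range(7, 9):  # B only
        records.append(_rec(f"B{i}", f"G{i}", "parentB"))
    counts = venn_summary(build_mapping(tpl, records))
    assert (counts.both, counts.parentA_only, counts.parentB_only, counts.unmapped) == (
        4, 3, 2, 1
    )
    assert counts.total == 10


def test_venn_all_unmapped():
    tpl = _template(["G1", "G2", "G3"])
    counts = venn_summary(build_mapping(tpl, []))
    assert (counts.both, counts.parentA_only, counts.parentB_only, counts.unmapped) == (
        0, 0, 0, 3
    )


@pytest.mark.parametrize("seed", range(5))
def test_venn_categories_partition_template_genes(seed):
    tpl = make_template(ToyNetworkSpec(8, 2, 0.0, seed=seed))
    records = make_ortholog_tables(tpl, 0.4, 0.2, 0.2, seed=seed)
    counts = venn_summary(build_mapping(tpl, records))
    assert counts.total == len(tpl.genes)


def test_ortholog_table_tsv_round_trip(tmp_path):
    import pandas as pd

    records = [_rec("SP1", "G1", "parentA", 88.5), _rec("SP2", "G1", "parentB", 91.0)]
    path = tmp_path / "orth.tsv"
    pd.DataFrame(
        [
            {
                "hybrid_gene_id": r.hybrid_gene_id,
                "template_gene_id": r.template_gene_id,
                "parent": r.parent,
                "percent_identity": r.percent_identity,
                "evidence": r.evidence,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
    assert load_ortholog_table(path) == records


# ---------------------------------------------------------------------------
# GPR rewriting


def _rewrite_fixture():
    tpl = _template(["PGI1", "TAL1", "U", "V", "W"])
    tpl.add_reaction(
        Reaction("R1", stoichiometry={"X_c": -1.0}, gpr=parse_gpr("PGI1"))
    )
    tpl.add_reaction(
        Reaction("R2", stoichiometry={"X_c": -1.0}, gpr=parse_gpr("TAL1"))
    )
    tpl.add_reaction(
        Reaction("R3", stoichiometry={"X_c": -1.0}, gpr=parse_gpr("U and V"))
    )
    tpl.add_reaction(
        Reaction("R4", stoichiometry={"X_c": -1.0}, gpr=parse_gpr("W or U"))
    )
    records = [
        _rec("SP_PGI1_A", "PGI1", "parentA"),
        _rec("SP_PGI1_B", "PGI1", "parentB"),
        _rec("SP_TAL1_B", "TAL1", "parentB"),
        _rec("SP_V_A", "V", "parentA"),
        _rec("SP_W_A", "W", "parentA"),
    ]  # U unmapped
    return tpl, build_mapping(tpl, records)


def test_both_alleles_become_or_pair():
    tpl, mapping = _rewrite_fixture()
    hybrid = rewrite_gprs(tpl, mapping)
    assert format_gpr(hybrid.reactions["R1"].gpr) == "PGI1_Scer or PGI1_Seub"
    assert hybrid.genes["PGI1_Scer"].allele_partner == "PGI1_Seub"
    assert hybrid.genes["PGI1_Scer"].name == "SP_PGI1_A"  # hybrid ORF kept


def test_single_allele_becomes_single_leaf():
    tpl, mapping = _rewrite_fixture()
    hybrid = rewrite_gprs(tpl, mapping)
    assert format_gpr(hybrid.reactions["R2"].gpr) == "TAL1_Seub"
    assert hybrid.genes["TAL1_Seub"].origin == "parentB"


def test_complex_with_unmapped_subunit_is_unsatisfiable():
    tpl, mapping = _rewrite_fixture()
    hybrid = rewrite_gprs(tpl, mapping)
    assert hybrid.reactions["R3"].gpr is UNSATISFIABLE


def test_or_with_unmapped_operand_keeps_mapped_leaf():
    tpl, mapping = _rewrite_fixture()
    hybrid = rewrite_gprs(tpl, mapping)
    assert format_gpr(hybrid.reactions["R4"].gpr) == "W_Scer"


def test_rewrite_touches_only_gprs_and_genes():
    tpl, mapping = _rewrite_fixture()
    hybrid = rewrite_gprs(tpl, mapping)
    for rxn_id, rxn in tpl.reactions.items():
        assert hybrid.reactions[rxn_id].stoichiometry == rxn.stoichiometry
        assert hybrid.reactions[rxn_id].bounds == rxn.bounds


# ---------------------------------------------------------------------------
# pruning


def test_prune_removes_unsatisfiable_and_orphan_genes():
    tpl, mapping = _rewrite_fixture()
    hybrid = rewrite_gprs(tpl, mapping)
    pruned, report = prune(hybrid)
    assert "R3" not in pruned.reactions
    reasons = {(r.entity_id, r.kind) for r in report}
    assert ("R3", "reaction") in reasons
    # V was mapped but only supported R3: orphaned by the reaction removal
    assert ("V_Scer", "gene") in reasons
    assert "V_Scer" not in pruned.genes
    pruned.validate()


def test_prune_matches_boolean_satisfiability():
    tpl, mapping = _rewrite_fixture()
    hybrid = rewrite_gprs(tpl, mapping)
    pruned, _ = prune(hybrid)
    for rxn in pruned.reactions.values():
        if isinstance(rxn.gpr, GPRNode):
            assert evaluate_boolean(rxn.gpr, frozenset())


def test_prune_never_touches_gprless_reactions():
    model = Model(id="m")
    model.add_metabolite(Metabolite("A_c"))
    model.add_reaction(Reaction("EX", stoichiometry={"A_c": -1.0}))
    pruned, report = prune(model)
    assert "EX" in pruned.reactions and not report


# ---------------------------------------------------------------------------
# curation


def _melibiase_action():
    return CurationAction(
        kind="add_reaction",
        target_id="r_4711",
        payload={
            "name": "alpha-galactosidase (melibiase)",
            "stoichiometry": {
                "melibiose_c": -1,
                "water_c": -1,
                "glucose_c": 1,
                "galactose_c": 1,
            },
            "gpr": "MEL1_Seub",
            "new_metabolites": [
                {"id": "melibiose_c", "formula": "C12H22O11"},
                {"id": "water_c", "formula": "H2O"},
                {"id": "glucose_c", "formula": "C6H12O6"},
                {"id": "galactose_c", "formula": "C6H12O6"},
            ],
        },
        note="melibiose utilization inherited from the parentB sub-genome",
    )


def test_add_melibiase_gains_one_reaction_one_gene():
    model = Model(id="m")
    before = (len(model.reactions), len(model.genes))
    curated = apply_curation(model, [_melibiase_action()])
    assert len(curated.reactions) == before[0] + 1
    assert len(curated.genes) == before[1] + 1
    assert curated.genes["MEL1_Seub"].origin == "parentB"
    assert curated.provenance["r_4711"].startswith("melibiose")


def test_curation_rejects_imbalanced_reaction():
    action = CurationAction(
        kind="add_reaction",
        target_id="BAD",
        payload={
            "stoichiometry": {"a_c": -1, "b_c": 1},
            "new_metabolites": [
                {"id": "a_c", "formula": "C"},
                {"id": "b_c", "formula": "C2"},
            ],
        },
    )
    with pytest.raises(ValueError, match="not balanced"):
        apply_curation(Model(id="m"), [action])
    waived = CurationAction(
        kind="add_reaction",
        target_id="BAD",
        payload=action.payload,
        balance_waiver=True,
    )
    assert "BAD" in apply_curation(Model(id="m"), [waived]).reactions


def test_reintegration_with_existing_isoform_gene():
    model = Model(id="m")
    model.add_metabolite(Metabolite("hexose_c"))
    model.add_gene(Gene("HXT10_Seub", origin="parentB"))
    curated = apply_curation(
        model,
        [
            CurationAction(
                kind="reintegrate_reaction",
                target_id="HXT_TRANSPORT",
                payload={
                    "stoichiometry": {"hexose_c": 1},
                    "gpr": "HXT10_Seub",
                },
                balance_waiver=True,
            )
        ],
    )
    assert "HXT_TRANSPORT" in curated.reactions
    assert genes_of(curated.reactions["HXT_TRANSPORT"].gpr) == {"HXT10_Seub"}
    assert len(curated.genes) == 1  # no new gene created


def test_curation_list_is_idempotent():
    actions = [
        _melibiase_action(),
        CurationAction(kind="remove_reaction", target_id="r_4711"),
        _melibiase_action(),
    ]
    once = apply_curation(Model(id="m"), actions)
    twice = apply_curation(once, actions)
    assert set(once.reactions) == set(twice.reactions) == {"r_4711"}
    assert set(once.genes) == set(twice.genes)


def test_readding_different_definition_raises():
    first = _melibiase_action()
    conflicting = CurationAction(
        kind="add_reaction",
        target_id="r_4711",
        payload={"stoichiometry": {"water_c": -1}},
        balance_waiver=True,
    )
    with pytest.raises(ValueError, match="already exists"):
        apply_curation(Model(id="m"), [first, conflicting])


# ---------------------------------------------------------------------------
# end-to-end redundancy property


def test_fully_redundant_hybrid_survives_any_single_allele_loss():
    tpl = make_template(ToyNetworkSpec(6, 2, 0.0, seed=7))
    records = make_ortholog_tables(tpl, fraction_both=1.0, fraction_Aonly=0.0,
                                   fraction_Bonly=0.0, seed=7)
    hybrid, report = prune(rewrite_gprs(tpl, build_mapping(tpl, records)))
    assert not report  # nothing to prune when every gene has both alleles
    wild = run_fba(hybrid).objective_value
    assert wild > 0
    for gene_id in hybrid.genes:
        mutant = knockout(hybrid, {gene_id})
        for rxn in mutant.reactions.values():
            if isinstance(rxn.gpr, GPRNode):
                assert evaluate_boolean(rxn.gpr, {gene_id})
        assert run_fba(mutant).objective_value == pytest.approx(wild)
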