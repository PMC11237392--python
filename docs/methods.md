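# Methods

## Constraint-based model and solver

A model is a stoichiometric system: metabolites × reactions matrix S,
flux bounds v_l ≤ v ≤ v_u, and one objective reaction (a biomass
drain). FBA maximizes the objective flux subject to steady state
(S·v = 0) and the bounds; FVA minimizes/maximizes each flux of interest
under the additional constraint wᵀ·v ≥ γ·Z₀ (w = objective vector,
Z₀ = FBA optimum, γ the fraction of optimum), i.e. two LPs per
reaction. LPs are solved with scipy's HiGHS interface on a sparse S.

Numerical policy: every optimal solve is checked for ‖S·v‖∞ ≤ 1e-6 and
bound feasibility to 1e-7; violations raise rather than return. FBA
returns one optimal vertex; under degenerate alternate optima the flux
*vector* is not unique, so all scalar results reported by the toolkit
are objective values or FVA interval ends, which are well defined.
Infeasible/unbounded statuses are propagated explicitly, never
converted to zero growth.

Default bounds are ±1000 mmol·gDCW⁻¹·h⁻¹ for reversible and [0, 1000]
for irreversible reactions, stored explicitly on every reaction.
Exchange reactions (single-metabolite boundary reactions) follow the
community sign convention: negative flux is uptake. Applying a medium
sets the listed exchange bounds verbatim and closes uptake (lower
bound 0) on every unlisted exchange, leaving secretion open. The
objective value is reported unit-agnostically: biomass pseudo-reactions
are conventionally read as growth rate (h⁻¹), but the LP itself carries
flux units, and published hybrid-yeast tables print biomass in
mmol·gDCW⁻¹·h⁻¹; the toolkit does not attempt to resolve that
ambiguity.

## GPR rules

GPR rules are Boolean expressions over gene ids; `and` binds tighter
than `or`, keywords are case-insensitive, gene ids (including allele
suffixes `_Scer`/`_Seub`/`_Spast`) are case-sensitive, and
parenthesized groups are preserved as written. Three semantics share
one tree:

- **Satisfaction** (knockouts): leaf true iff the gene is not deleted;
  `and` = conjunction, `or` = disjunction.
- **Aggregation** (expression → capacity): `or` = sum of children
  (alternative catalysts add), `and` = min of children (a complex is
  limited by its scarcest subunit), applied recursively for mixed
  rules. Note that `or` over two alleles each expressed at x yields
  2x — the sum rule is applied literally, with no saturation; duplicate
  leaf occurrences aggregate independently. A leaf missing from the
  expression mapping contributes 0.
- **Attribution** (parental shares): see below.

## Hybridization pipeline

Ortholog records (hybrid gene → template gene, parent, percent
identity, gene- or protein-level evidence) are filtered at strictly
greater than 70 % identity (configurable) and must be one-to-one within
each (parent, evidence) stratum. Protein-level calls rescue template
genes unmapped at gene level; when gene- and protein-level calls
disagree about a hybrid gene's template target the protein call wins
and the conflict is logged. Both raw strata are retained on the mapping
so either accounting (before/after protein rescue) can be rebuilt.
Paralogs indistinguishable at the protein level (two hybrid genes
claiming one template slot across strata) keep the gene-level call and
are flagged ambiguous.

GPR rewriting renames alleles `<template name><suffix>` (canonical
suffixes `_Scer` for parentA, `_Seub` for parentB), links redundant
pairs, and keeps the hybrid organism's own ORF id as the gene name.
An unmapped leaf is dropped from an `or` that retains other support;
inside an `and` it voids the branch. The GPR node kinds are fixed at
LEAF/AND/OR, so a fully voided rule is represented by a module-level
`UNSATISFIABLE` sentinel on the reaction rather than a fourth node
kind; `prune()` consumes the sentinel. Pruning removes unsatisfiable
reactions first and then genes appearing in no GPR, so genes orphaned
by reaction removal are also dropped; reactions without any GPR
(exchanges, spontaneous, biomass) are never pruned. Rewriting never
touches stoichiometry or bounds.

Manual curation is a replayable action list (add/reintegrate/remove
reaction or gene). Added reactions must pass elemental balance against
their metabolite formulas unless explicitly waived (mitochondrially
encoded complex re-integrations are expressed as such actions rather
than inferred). Removing an absent entity is a no-op and re-adding an
identical definition is a no-op, so applying a curation list twice
equals applying it once; re-adding a *different* definition without an
amend flag is an error. Provenance notes are stored per touched entity.

## Essentiality

An entity is essential when its single deletion drops the FBA optimum
below 1 % of wild type (threshold configurable; cutoffs between roughly
1 % and 10 % give identical classifications on the toy networks since
knockouts there either leave growth intact or zero it). Gene mode
closes every reaction whose rule fails without the gene and skips the
LP entirely when no reaction is affected; reaction mode zeroes each
reaction's bounds in turn. A medium that cannot support wild-type
growth is an error, not an all-essential report.

## Expression integration

TPM: RPK = count / length-in-kb; scaling factor = ΣRPK / 10⁶;
TPM = RPK / factor, so each library sums to exactly 10⁶. Fractional
pseudo-counts are accepted (the synthetic generator uses them);
non-positive lengths and all-zero libraries are errors.

Bound mapping: a reaction with a GPR is constrained only when **all**
its genes are strictly above the threshold (default 10 TPM, a
conventional noise floor) — the conservative reading; an optional
`any_branch` gate (off by default) instead requires only that some
Boolean branch of expressed genes satisfies the rule. The aggregate
capacity, clipped at `max_bound` (default 1000), caps the upper bound
of irreversible reactions and both bounds (±capacity) of reversible
ones. Bounds are only ever tightened — clipped against current bounds,
never widened, never relaxing irreversibility. TPM magnitudes are used
directly as flux-bound magnitudes; this unit identification is a
heuristic convention, adopted deliberately and documented here rather
than hidden behind a rescaling constant. Constrained-reaction counts
report how many reactions' bounds actually changed.

## Parental attribution

Recursive share rule: a leaf is 100 % its parent's; an `or` node mixes
child shares weighted by child aggregate capacity (for a pure `or`
group this reduces to the parent's fraction of total TPM); an `and`
node takes the unweighted mean of child shares — each subunit slot
counts equally regardless of its expression level. The mean-of-groups
choice for complexes is one defensible convention among several (e.g.
min-group-weighted); it is isolated in a single function so an
alternative can be swapped in. A share is *inconclusive* when total
supporting TPM is at or below the threshold (default 10) — one
plausible operationalization of the inconclusive labels seen in
published allele-usage tables, which never define them. Conclusive
shares sum to 1 and are invariant under uniform TPM scaling. Genes
whose origin is neither parentA nor parentB (including
hybrid-specific genes) raise a hard error rather than being silently
excluded. A usage *shift* across ordered conditions is declared when
the parentA share differs by ≥0.10 between any two conclusive
conditions; reports round shares to 5 % granularity while machine
output keeps full precision.

## Synthetic data

`make_template` builds P parallel linear pathways, each fed by its own
exchange at uptake 10 mmol·gDCW⁻¹·h⁻¹ and ending in a common biomass
precursor drained by the objective, so the optimum is exactly 10·P.
All metabolites share one hexose formula, making every internal step
elementally balanced. Each catalyst slot is a redundant `_Scer`/`_Seub`
allele pair with probability `fraction_redundant_genes`, else a single
gene; the last internal reaction is a two-subunit complex (an `and` of
slots), so generated models cover all GPR census categories. The
biomass drain is a single-metabolite pseudo-reaction — the simplest
structure that makes essentiality meaningful.

`make_ortholog_tables` assigns each template gene
both/A-only/B-only/unmapped by seeded draw; unmapped genes still emit
records, at below-threshold identity, so threshold filtering (not mere
absence) is exercised. `make_expression` emulates cultures at three
temperatures (SD medium at 13/22/30 °C): each allele pair (or
singleton) draws a base abundance uniform in [100, 1000] pseudo-counts
over 1 kb genes, the parentB allele receives `parentB_bias` of the
pair total (optionally per-condition, to engineer usage shifts),
per-condition multipliers are drawn per *pair* so within-condition
allele ratios are preserved, and optional log-normal noise is applied
per allele. Profiles are TPM-normalized, which preserves ratios, so at
zero noise attribution recovers the engineered bias exactly.
Continuous pseudo-counts (not integer reads) are used precisely so that
this recovery is exact; real RNA-seq adds counting noise, library
composition effects and multi-mapping artifacts that the generator
does not emulate — passing tests demonstrate correctness of the
*mapping and attribution rules*, not robustness to real sequencing
noise. All generators are driven by one integer seed through numpy's
PCG64; identical seeds reproduce identical artifacts.

Problem sizes used in the test suite and the reproduction script —
toy networks of 4–12 reactions, 50 random networks for the solver
cross-check, 200 random trees for aggregation, 100 seeded replicates
for attribution recovery — were chosen as the smallest sizes at which
each property is non-trivially exercised.

## Interfaces and I/O

SBML L3V1 + fbc v2 is the primary exchange format (other levels are
rejected with a clear message); GPRs are serialized as fbc
gene-product associations, with no association element emitted for
rule-less reactions. Gene origin and allele partnership have no
standard fbc representation: origins are re-inferred from allele
suffixes on read and `_Scer`/`_Seub` pairs re-linked, so round trips
are census- and structure-identical rather than field-identical. A
plain-text tabular dialect (reactions/metabolites/genes TSVs with an
`2 A + B -> C` equation syntax) covers the same content for
version-controllable fixtures; media are TSV or JSON exchange-bound
maps. Compartments are opaque strings and balancing is not
compartment-aware.

## Known limitations

- No parsimonious FBA, MOMA, dynamic FBA or loopless FVA.
- No kcat- or proteomics-aware capacity aggregation; the TPM→flux unit
  identification is heuristic.
- Presence/absence allele modeling only: aneuploid copy-number dosage
  is not represented beyond the expression data itself.
- Ortholog detection (sequence alignment) is out of scope; the toolkit
  consumes ortholog tables produced elsewhere.
- Genome-scale external models (e.g. a deposited hybrid-yeast SBML) are
  read through the same code paths but are not bundled; all bundled
  verification is desk-scale on generated networks.
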