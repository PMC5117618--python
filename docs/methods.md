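# Methods

This note documents the models and procedures implemented by the
package, the parameters that matter, the numerical choices, and what
the synthetic fixtures do and do not establish.

## Balance model

A reaction is *balanced* when every element other than hydrogen and the
total electron count are conserved. Hydrogen and charge are folded into
a single electron ledger: each species contributes
`Σ(atomic number × atom count) − charge` electrons, so a bare proton
contributes nothing and proton bookkeeping can never unbalance a
reaction. This is the convention that makes charge-inconsistent source
databases usable without per-reaction proton curation. All balance
arithmetic uses exact rationals (`fractions.Fraction`); floating point
appears only at SBML serialization. Formulas containing generic groups
("R", "\*") are classified unresolvable and excluded from balance
decisions rather than guessed.

**Repair.** An imbalanced reaction may be repaired by (i) rescaling
each coefficient by a rational p/q with p, q ≤ `max_coeff` (default 6)
and (ii) adding water to either side. Water is never searched: once
multipliers are fixed, oxygen conservation dictates the signed water
amount and the electron ledger must agree with it (10 electrons per
water), so each multiplier assignment is feasible or not in O(1). Among
feasible repairs the one minimizing total coefficient change is
returned; ties break on fewest water molecules added, then
lexicographically. Minimal-change is this package's objective — the
choice of objective among feasible rebalancings is genuinely open, and
minimal perturbation of curated stoichiometry is the conservative
option. The search is branch-and-bound over per-metabolite multipliers
and is exhaustive at the problem sizes the database stage encounters.

## Database assembly

Sources are ranked: the *S. cerevisiae* community model first, then the
other curated whole-genome models, then KEGG, then MetaCyc. Duplicate
detection uses the unordered pair of participating-metabolite sets with
protons removed and coefficients ignored, so a reaction and its reverse
collide. When set-equal members disagree on stoichiometry, the
higher-priority source's coefficients are kept and a merge warning
logged (the resolution rule is this package's choice). Protons are
stored in equations but excluded from keys. Directions are harvested
from whole-genome-model members only; conflicts and public-database-only
reactions become bidirectional. Curation overrides (close / flip) apply
last from a TSV, supporting the iterative reconstruct–simulate–refine
loop. Lipid-tagged reactions survive only from the designated
gold-standard sources. Cluster identifiers for novel compounds are
minted from a sorted-name hash, so rebuilds are reproducible.

## Scoring

Evidence is consumed as pre-calibrated probabilities per species and
E.C. number; the phylogeny-aware probabilistic scoring that produces
those probabilities is out of scope here. The combination rule is the
maximum of the BLAST and GTG channels (a mean rule suppresses enzymes
whose closest GTG match is phylogenetically distant), and a reaction
takes the maximum over its E.C. annotations. Reactions with gene
evidence but no real E.C. class receive deterministic pseudo-E.C. ids
in the reserved `7.a.b.c` format. An optional linear parent–child score
blending along a species tree is provided for fixture experiments only
and is not part of the production path.

## Reconstruction

Parameters: `alpha` (acceptance threshold on the probability scale,
default 0.5 — the value selected by biomass-component production among
0.3/0.4/0.5), `beta` (gap budget, default 2), `sources` (compound ids
assumed available). Candidates with score ≥ α are processed in
descending score order, ties broken lexicographically on reaction id,
which makes drafts bit-reproducible.

Connectivity is simple directed reachability over a compound graph.
Compound mode draws substrate→product edges for each *permitted*
direction and excludes a configurable currency list (water, proton,
ATP/ADP/AMP, NAD(H), NADP(H), CO₂, phosphate) — a crude surrogate for
atom maps. Atom mode draws an edge only where a carbon atom is mapped
from substrate to product; maps are supplied per reaction through a
pluggable interface, since computing them from structure files is out
of scope.

Gap-filling seeks the cheapest reaction set (cost `1 − score`)
rendering all of a candidate's substrates reachable. `beta` is by
default a *count* of sub-threshold reactions per episode; a variant
capping the episode's total cost is available via `beta_mode="cost"`,
since both budget semantics are defensible. While the candidate pool is
small (≤ 14 reactions) the search enumerates subsets in ascending cost
order and is exact — the regime all shipped fixtures and tests operate
in; larger pools fall back to a per-substrate uniform-cost search over
(compound, budget-used) states, exact for single-substrate gaps.
Candidates that cannot be connected are kept as *orphans*: they carry
their database direction bounds in the final model, are flagged in
reaction notes, and never extend reachability for later candidates.

Dead-end metrics are structural: a metabolite is dead-end when no
permitted reaction orientation (or exchange) produces it, or none
consumes it; a reaction is dead-end when it touches a dead-end
metabolite.

## Biomass equation

Coefficients are mmol per gram cell dry weight, consumption negative.
For a polymerized component measured at w % w/w the monomer coefficient
is `(w/100) / (M_monomer − M_water) × 1000`. Molar masses come from
standard atomic weights via formulas. Specifics:

- **Protein:** twenty amino-acid weight fractions (summing to the
  protein total within 0.1 %), each over its peptide-residue mass.
- **DNA:** Chargaff fractions from genome GC content (0.52);
  total residue moles from the weighted mean dNMP-residue mass.
- **RNA:** measured base molar fractions (A 0.247, C 0.237, G 0.279,
  U 0.237, from the ribosomal pre-rRNA region) with NMP residues.
- **Carbohydrate:** chitin (7.82 % w/w, an input already corrected for
  ash) as N-acetylglucosamine residues; the remaining carbohydrate as
  glucose (glucan) residues. The package follows this computation even
  where a published coefficient table appears to swap the two rows.
- **Lipids:** per-fatty-acid coefficients from summed esterified + free
  masses over the free-acid molar mass. Lipid-class amounts are solved
  from the TAG:PE:PC weight ratio (0.52:0.16:0.32) and the ester mole
  balance `3·TAG + 2·PE + 2·PC = ester pool`; class molecular weights
  derive from the mean ester molar mass with one water per ester or
  phosphoester bond. The measured pool (0.0995 mmol/g, mean MW
  274.2 g/mol) is configuration, with a computed-from-composition
  fallback; the headgroup demand counts one glycerol 3-phosphate per
  glycerolipid of any class plus one phosphoethanolamine or
  phosphocholine per phospholipid — the only reading numerically
  consistent with the glycerol-3-P coefficient (≈0.040).
- **Maintenance & trace:** ATP/ADP/water/phosphate, sulfate and
  riboflavin coefficients are copied from the reference yeast biomass
  equation; ubiquitous cofactors enter at a trace 1e-6 mmol/g so the
  model must be able to synthesize them. Both live in a JSON config,
  not code. Ash is excluded.

Category mass closure (Σ |coef| × residue mass per category equals the
measured fraction) holds to 1e-6 relative by construction and is
asserted in tests. Two published rows are rounding-boundary cases the
builder reproduces to ±0.001 rather than exactly (valine, whose
computed 0.2545 rounds differently under slightly different
atomic-weight tables, and phosphocholine, whose value is sensitive to
the phospholipid molar-mass convention); all other coefficient rows
reproduce exactly at 3 decimals.

## FBA

LPs run through COBRApy on GLPK with feasibility tolerance 1e-9; every
optimal solution is independently re-verified (steady state `‖S·v‖∞`
and bounds) before being reported. The default minimal medium bounds
the carbon source and leaves ammonia, phosphate, sulfate, water, oxygen
and iron unlimited. Production is always measured through a dedicated
export-only demand sink, so a compound whose only boundary is its own
uptake exchange still shows its true production. The carbon audit flags
any compound whose maximal production carries more carbon than the
medium's bounded uptakes supply (tolerance 1e-6); production exactly at
the bound is plausible, not a violation. P/O coupling augments the
terminal oxidase with `ratio × 2` phosphorylation events per O₂ (the
phosphorylation half is a condensation, hence balance-preserving).
Growth rates are reported in 1/h via the biomass equation's gram basis;
production rates in mmol/g CDW/h, with integer rounding available as a
reporting convention.

## SBML

Models serialize as SBML Level 3 with FBC bounds and objectives through
COBRApy, which applies reversible SId escaping to composite identifiers
(hyphens in `r0226-YCM606-R00086` survive a round trip). Models are
uncompartmentalized (single cytosol) — compartment-duplicated source
reactions were already collapsed at the database stage. Inclusion
status (scored / gap-fill / orphan) travels in reaction notes, so the
validation report is recomputable from the artifact alone.

## Synthetic fixtures

The generators define the test conditions:

- **Toy universes** (seeded): compounds with random formulas over
  C/H/N/O/P/S; "adduct" compounds defined as elementwise formula sums
  so condensation reactions balance by construction; planted imbalances
  (doubled product coefficient) and planted sub-threshold scores in
  stated exact fractions, all recorded in a manifest. Same seed,
  byte-identical files.
- **Valine network:** glycolysis surrogate
  (glucose → 2 pyruvate + 2 H₂), aminating valine synthase, a
  CO₂-refixing carboxylase and a redox shuttle, all element- and
  electron-balanced, with exchanges for glucose/NH₃/O₂/H₂O/CO₂/valine.
  Glucose is the only carbon input, so the LP optimum for valine export
  at uptake 10 equals the carbon bound 10 × 6/5 = 12 exactly.
- **Gap fixtures:** isomer chains where a high-scoring target is
  reachable only through n planted sub-threshold bridges, optionally
  with an irreversible wrong-way detour whose written equation would
  connect the target in one step but whose permitted direction runs
  away from it.

What the fixtures do **not** emulate: genome-scale topology (thousands
of reactions, hub metabolites), compartmentalization, noisy or
conflicting evidence distributions, and real atom maps. Passing tests
establish correctness of the algorithms under their stated contracts,
not predictive accuracy on a real organism.

## Problem sizes

The shipped test suite and the acceptance script run networks of 4–30
reactions and exhaustive oracles up to 2^10 subsets / ~10^5 repair
candidates; these sizes make every oracle comparison exact while the
full suite completes in well under a minute.

## Known limitations

- The phylogenetic probability model that produces evidence scores is
  consumed, not implemented.
- Atom maps must be supplied; the compound-mode currency list is a
  heuristic stand-in.
- The gap search's large-pool fallback is heuristic for multi-substrate
  targets (exact within the tested regime).
- Published genome-scale counts (database sizes, per-species model
  statistics) require the original source dumps and are out of scope;
  the package validates the procedures on fixtures with analytically
  known answers instead.
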