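# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind each stage of the pipeline, in the order the stages run.

## Model representation and chemistry

A model is a set of compartments, metabolites, reactions and genes with an
objective. Metabolite ids follow the BiGG dialect (base id + `_` +
compartment token; tokens c, m, x, e, r, n, g, v, l). Formulas are element
-> count maps serialized in Hill order; the pseudo-elements `R` and `X`
(lumped acyl chains, unspecified groups) take part in balance arithmetic
like ordinary elements so lumped lipid species remain auditable. The
balance audit declares a reaction balanced only at exactly zero net for
all-integer stoichiometries, and within 1e-6 when any coefficient is
fractional (biomass-style equations); exchange, demand, sink and biomass
reactions are exempt because they cross the system boundary by design.
Reactions whose metabolites lack formula or charge are reported
"unauditable" rather than skipped.

GPR rules are boolean trees over gene ids with case-insensitive infix
`and`/`or`, `and` binding tighter. The empty rule is always satisfied.
Disjunctive normal form (with subsumed branches dropped) is the working
representation for the isozyme/complex resolution rule, making "branch" a
well-defined notion for arbitrarily nested rules.

## Draft assembly

A donor reaction transfers iff at least one GPR gene maps through the
ortholog groups to a target gene. One-to-many ortholog expansion always
uses OR: ortholog groups mix orthologs and recent paralogs, which are
treated as isozymes, never as complex partners. Unmapped donor genes stay
behind as `organism::gene` leaves until resolution: a branch containing an
unmapped gene is pruned when a fully mapped branch survives; when every
branch needs the absent gene (a required complex subunit with no isozyme)
the reaction is removed. Reactions with empty donor GPRs (spontaneous,
orphan) are never transferred automatically; they are logged as candidates
for manual opt-in. Duplicate reactions across donors collapse onto the
first donor's copy (deterministic first-donor-wins metadata, OR-unioned
GPRs) keyed by the canonical stoichiometry signature described below.

Compartment assignment applies explicit relocation rules first (selector =
reaction id, subsystem or `*`), then gene-localization evidence, and
removes reactions stranded in compartments the target organism lacks.
Relocations that recreate an existing reaction collapse onto it.

## Curation

The reaction signature sorts participants by metabolite id and rescales
coefficients so the lexicographically smallest participant has coefficient
-1 (+1 when the reaction only produces). This makes the signature invariant
to insertion order, to scalar multiples, and to writing a reversible
reaction in either direction. Deduplication keeps the smallest id, unions
GPRs with OR and takes the hull of the bound intervals after mapping each
duplicate's bounds through its scale factor; the hull preserves per-route
capacity (and the flux cone whenever the duplicates were alternative
writings of one capability) but deliberately does not *sum* capacities —
duplicate entries are treated as redundant bookkeeping, not as parallel
enzymes. Metabolite duplicate candidates come from exact
(formula, charge, compartment) keys, then a user alias table, then
normalized name tokens; name tokens only rank candidates and never
auto-merge, and differing protonation states never auto-merge because
charge is part of the key. Dead ends are classified from the matrix
sparsity pattern with reversibility honored (only-produced, only-consumed,
disconnected).

## Biomass

Monomer coefficients are `mass_fraction * mol_fraction / residue_mass`
(mmol/gDW), with optional carrier release (CoA returned when acetyl-CoA
carbon enters biomass); assembly errors out unless the total assembled
mass is 1 g/gDW within 1e-4. Growth-associated maintenance defaults to
30 mmol ATP/gDW. Trace elements can enter as a configurable
small-coefficient pool (default none in the demo fixture, which has no
cofactor biosynthesis).

### Segmented fatty-acid regression

Because samples report compositions, `x = sum_k y_k` holds exactly, which
forces `sum m_k = 1` and `sum b_k = x0` in the generating model. The fit:

1. grid-search `x0` over `[0, min(x)]` (default step 0.05 wt%); at each
   candidate every fatty acid gets a nonnegativity-constrained least
   squares line on `x - x0`; the candidate minimizing joint RSS wins.
   The per-species line is shift-invariant wherever no constraint binds,
   so the RSS profile has a plateau; ties resolve to the **largest**
   RSS-minimal `x0`. This attributes the maximum content to lean mass and
   is the consistent choice: with data only at `x >= x0` the smallest
   observed total converges to the true breakpoint from above, while a
   smallest-`x0` tie-break does not converge at all.
2. classify increasing species: unconstrained slope above 0.02 *and* slope
   t-statistic above 2 (both configurable; an exact fit counts as t = inf);
3. pin non-increasing slopes to 0 (`b_k` = mean content), project
   increasing slopes to sum to 1, refit intercepts at the chosen slopes,
   clip at 0 and rescale so `sum b_k = x0` exactly.

The lean composition is `b / sum b`, the lipid-body composition is `m`
restricted to the increasing set. A per-species-breakpoint variant exists
behind `FitConfig(shared_breakpoint=False)` for exploration; the shared
breakpoint is the default because the lean-to-accumulating transition is a
property of the cell state, not of individual species. Data below the
chosen breakpoint cannot occur by construction of the grid. Known
limitation: the breakpoint estimate inherits an upward bias of order
(x-range)/(n+1) from using the smallest observed total; at the packaged
noise level (sigma = 0.5 wt%, n = 12 over a 35 wt% span) this contributes
most of the intercept error (mean absolute error ~0.9 wt%), while slopes
are unaffected.

Lipid-droplet wiring: irreversible demand reactions consume droplet acyl
species weighted by the lipid-body composition (3 acyl equivalents per
triacylglycerol, 1 per sterol ester); matching sink reactions for
mobilization are created closed and opened by the user. In the demo
fixture, which has no sterol chemistry, the two demands are deliberately
signature-identical pseudo-reactions.

## Simulation

FBA uses `scipy.optimize.linprog` (HiGHS). Shadow prices are the duals of
the mass-balance rows, sign convention: positive means allowing net
accumulation of that metabolite would raise the objective. Assertions in
tests target objective values, duals on non-degenerate toys, and set
membership — never full flux vectors, which are not unique. Gene deletions
zero the bounds of reactions whose GPR evaluates false; a gene is called
essential when the growth ratio drops below 0.1 (configurable), with a
growth-call floor of 1e-6 flux units. Default carbon uptake is
10 mmol·gDW⁻¹·h⁻¹.

Precursor diagnosis maximizes a temporary whole-molecule demand per
consumed biomass precursor. In models without de-novo cofactor
biosynthesis (like the demo fixture) precursors carrying a conserved
moiety (ATP, acetyl-CoA) are reported non-producible by this probe even
though the moiety-balanced biomass is feasible — the probe is a diagnosis
aid for real reconstructions, where those pathways exist.

EGC detection closes every boundary reaction, relaxes forced lower bounds
(a maintenance floor would otherwise make the closed system infeasible and
mask cycles), and maximizes each currency dissipation (defaults: ATP, GTP,
NADH, NADPH, FADH2, trans-mitochondrial proton). When dissipation is
possible, a MIP (big-M linking, M = largest bound, activity epsilon 1e-4,
60 s per currency) finds the minimum-cardinality active set sustaining
dissipation >= 1; hitting the time limit returns the finding flagged
"minimality unproven" with the LP-active set.

## Validation

Phenotype arrays: per well, the element-class source exchange of the base
medium is closed and the mapped substrate's exchange opened at the uptake
rate (all ids for multi-metabolite substrates; missing exchanges are
auto-created and logged). Wells without a mapped metabolite are counted
but excluded from the statistics. Pre-binarized observed calls override
the dye-signal rule `(A590 - A750) >= threshold`. Fitness tables: a gene
is observed essential in a condition when flagged globally essential or
scoring below the cutoff (default -2.0 log2). Accuracy is reported in
percent to one decimal; MCC is defined 0 when a marginal is empty. The
always/never/conditional partition is computed from observed calls only,
and conditional-subset accuracy is the pooled accuracy restricted to those
genes.

## Synthetic data

The reconstruction universe is a linear conversion chain (each step
releases one water, so every reaction is balanced and every metabolite key
distinct) with GPR patterns cycling through single genes, isozyme pairs,
complexes and mixed rules; donors are gene-renamed projections of the
truth. Coverage removes genes from the ortholog map; spurious links
reassign donor genes to wrong groups; duplicate metabolites are injected
as same-key ids spliced into the chain via an isomerase; imbalances drop a
water product; duplicate reactions are scaled/reversed copies. All defects
are ledgered, and generation is a pure function of (seed, spec).

FAME samples draw totals uniformly on `[x0, x0 + 35]` wt% (spanning a
low-lipid rich medium to a strongly lipid-accumulating high-C:N medium),
add truncated Gaussian noise and restore closure by rescaling. Phenotype
and fitness data derive from the model's own predictions with Bernoulli
label flips; scores come from N(0, 0.5) (non-essential) vs N(-4, 1)
(essential), redrawn in the rare (~2%) case a draw crosses the midpoint
cutoff so the binarization reproduces the intended labels exactly — these
distributions are synthetic conventions chosen to straddle any reasonable
cutoff, and the generator does not model insertion-count-dependent noise
of real insertion-mutagenesis fitness scores.

What passing on synthetic data does and does not show: the generators
share the pipeline's own model family (exactly linear FAME responses,
label noise independent across gene-condition pairs, donors that are exact
projections), so green tests demonstrate correctness of the algorithms
and calibration under the stated noise, not robustness to the correlated
errors, annotation biases and partial observability of real data.

## The demo network

A ~110-reaction, six-compartment model: glycolysis, oxidative and
non-oxidative pentose phosphate pathway, a pyruvate-dehydrogenase bypass
to cytosolic acetyl-CoA, TCA cycle, oxidative phosphorylation on a
ubiquinone-9 pool (complex I pumping 4 H+ and the lumped bc1/oxidase 6 H+
per turnover, ATP synthase at 4 H+/ATP), the D-arabinitol/D-ribulose
pentose route (with the canonical xylulokinase encoded but held at zero
flux, matching its observed transcriptional silence), the peroxisomal
beta-oxidation-like p-coumarate route with cytosolic ortho-cleavage and
mitochondrial 3-oxoadipate conversion, and a lumped fatty-acid block
(C16:0/C18:0 synthesis, ER delta-9 desaturation). Biomass is a stylized
two-term objective (acetyl-unit carbon backbone at 0.85 g/gDW plus the
lean fatty-acid split at 0.15 g/gDW) — adequate for growth/no-growth
calls and deletion genetics, not for yield predictions. Simplifications
chosen for tractability and documented here: the 4-hydroxybenzoate
3-monooxygenase sits in the cytosol (its peroxisomal placement would
require a peroxisomal NADPH supply subsystem); a cytosolic
NADP-isocitrate dehydrogenase with citrate/oxoglutarate carriers provides
the NADPH surplus on non-sugar carbons (the p-coumarate route is exactly
NADPH-neutral through malic enzyme alone); a standard ATPM maintenance
reaction (floor 1 mmol/gDW/h) provides the ATP sink every flux model
needs. The naive ATP-per-glucose ceiling of 30 (2 glycolytic + 2
succinyl-CoA synthetase + 8 NADH_m at 10/4 + 2 cytosolic NADH and 2
quinol at 6/4) is encoded with the fixture and the LP optimum reaches
exactly that bound.

## Problem sizes

Defaults were chosen so the whole suite runs on a laptop-class single
core: synthetic universes of 30-50 reactions, 200 random LP-vs-oracle
networks of up to 6 reactions, 20-seed Monte-Carlo for the regression and
10-seed for the validation round trip, and the ~110-reaction demo network
for everything end-to-end. All scale linearly if users raise them.
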