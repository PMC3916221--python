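# Methods

This note documents the models and algorithms implemented in `phylorecon`,
the defaults and their rationale, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Phase I: enzyme presence inference

### Model

For each complete EC number an independent Bayesian network is instantiated
whose topology is the rooted phylogeny. Hidden binary nodes `X_s` mark
presence of the enzyme in species `s` (leaves = present species, internal
nodes = hypothetical ancestors). The root has prior `P(X_root = 1) = 0.5`
(uniform; configurable). Every edge carries a Bernoulli transition CPD
(`p_gain`, `p_stay`); every leaf observes two continuous evidence variables —
the reciprocal-search score and the remote-homology shared-feature fraction —
through four class-conditional densities shared by all species and enzymes.

A species with no hit for an enzyme contributes the observation *score 0*,
not missing data: absence of a hit is evidence of absence, and the
absent-class densities place most of their mass near zero.

### Evidence scores

The reciprocal score combines the forward and reverse search p-values as
`-log10(p_f) - log10(p_r)`, p-values floored at 1e-300. The scorer is
pluggable; any replacement must be symmetric and non-increasing in each
p-value so that a high score requires both search directions to be
significant. An optional transform `p = 1 - exp(-E)` converts E-values to
p-values for inputs that carry E-values. The shared-feature fraction is
consumed as given (its denominator is a property of the external
trace-graph database and is not recomputed). Per (species, EC) the table
keeps the *maximum* score over hits whose target is annotated with the EC.

### CPD estimation

Ancestral reference states are imputed per EC by minimum-change parsimony.
The implementation is a per-node dynamic program over change counts
(Sankoff-style), which is exact on arbitrary — including multifurcating —
rooted trees and coincides with Fitch's set method on bifurcating ones.
Tie-breaking is deterministic: an ambiguous node inherits its parent's state
in the top-down pass and an ambiguous root is called absent. This favours
late, independent gains over early gain plus losses when both are equally
parsimonious, which is the conservative choice for presence calls.

Edge CPDs are estimated per edge by counting transitions over all ECs with a
pseudocount (default 1):

    p_gain = (#{parent 0 -> child 1} + k) / (#{parent 0} + 2k)

and analogously `p_stay` on parent-present cases. An edge with no
parent-absent (or no parent-present) observations falls back to the pooled
global counts. A fully pooled `global` mode is also available; per-edge is
the default because edges differ in length and annotation quality, and with
pseudocounts the per-edge estimates are well behaved even on small EC sets.

Evidence densities are Gaussian-kernel KDEs with Silverman's `nrd0`
bandwidth `h = 0.9 min(sd, IQR/1.34) n^{-1/5}`. To avoid near-zero densities
and overfitting, 100 regularization points (configurable) placed uniformly
on `[0, max observed score]` are appended to each class before fitting; the
maximum is taken per class. When a class is degenerate (zero spread) the
bandwidth is floored at 1e-3 times the data range (1e-3 absolute when the
range is zero), which keeps every density strictly positive on the observed
score range.

### Inference

Marginals are computed exactly by a two-pass message schedule: an upward
pass collects subtree likelihoods, a downward pass distributes the
complementary evidence; this is belief propagation on a singly connected
network (the polytree algorithm) specialised to trees. Messages are
renormalised at every node so arbitrarily scaled densities cannot overflow.
The implementation is validated against brute-force enumeration of all joint
presence states on random trees (max abs deviation < 1e-9 required).

The no-phylogeny baseline ("naive") is the same model restricted to a single
node: the four evidence densities plus a class prior taken from reference
presence frequencies (with a +1/+2 smoothing).

## Reaction universe

Reactions are read from a KEGG-like flat format; blacklisted "general"
reactions (reactant classes rather than concrete molecules) are removed
first. Each remaining reaction is mass balanced by an integer program
(HiGHS via `scipy.optimize.milp`): existing reactant coefficients are
integers bounded below by their original values and above by 15; water and
protons may be added to either side (0–15); at most one C1 unit (carbonic
acid) may be added in total; element balance is enforced over C, H, O, N, S,
P (configurable); the total coefficient sum is minimised. Helper bounds of
15 match the reactant bound and keep the program finite. Charge is not
balanced separately — proton addition absorbs it. Reactions that cannot be
balanced, or that contain a reactant without a formula, are flagged and
excluded from reconstruction (their direction constraints must then come
from manual curation). Reactions with the same molecule on both sides are
rejected at parse time because atom-transfer semantics become ambiguous.

Atom mappings are bijections from substrate atom slots
(molecule, occurrence, atom index) to product atom slots that preserve
element labels; validation checks bijectivity and label preservation over
the tracked elements (by default the elements actually present in the
mapping, so carbon-only mappings of full reactions are accepted). A greedy
element-wise mapper provides valid — not chemically optimal — mappings for
synthetic fixtures; production use expects precomputed mappings as input.

## Phase II: gapless assembly

Reaction costs are `-ln(max posterior over annotated ECs) + base_cost`
(posteriors floored at 1e-12; EC-less reactions get a fixed spontaneous
cost). Defaults: `base_cost = 1.0`, `spontaneous_cost = 2.0`, acceptance and
rejection thresholds corresponding to posteriors 0.5 and 1e-4. These are
package defaults, all configurable; they have not been validated against any
published genome-scale model.

The atom graph has one node per (molecule, atom index) and one directed edge
per mapping pair, in both directions for reversible reactions. Candidate
reactions with cost below the acceptance threshold are attempted in
increasing order of *estimated addition cost*: the sum over the reaction's
substrate atoms of the cheapest reaction-path cost (Dijkstra) from nutrient
atoms or products of already accepted reactions, accepted reactions costing
zero. The estimate is a heuristic ordering device — per-atom paths may share
reactions, which are then counted once per atom.

For each attempted reaction a best-first search looks for a gapfill pathway:
partial pathways (reaction sets) are kept in a priority queue keyed by
accumulated cost (each member counted once, ties broken by sorted reaction
ids); the cheapest is popped, its *flagged atoms* (substrate atoms of the
target and of every member not yet BFS-reachable from nutrient atoms) are
computed, and the lexicographically first flagged atom is resolved by each of
the `k` (default 5) cheapest linear reaction paths from the sources to that
atom. Reversible reactions must have *all* their atoms traceable before
being used, since they may run in either direction. Pathways exceeding the
rejection threshold are pruned; the search gives up after a configurable
expansion budget (default 10,000), which is reported distinctly from a cost
rejection. With unlimited `k` and budget the search recovers the
subset-enumeration optimum on the generated small universes (where every
atom edge is realized by a unique reaction; with many reactions realizing
the same transfer the per-edge cheapest-reaction choice makes the search
heuristic).

On success the reaction and its pathway members are accepted; members whose
own cost exceeds the acceptance threshold carry `gapfill` provenance and are
permanent once added. On failure the policy either rejects the reaction
(guaranteeing the gapless invariant, checked by an independent BFS oracle in
the tests) or adds it flagged with a gap for later curation. Identical
inputs yield identical reconstructions; all tie-breaks are lexicographic.

## Steady-state analyses

The LP model places internal reactions with direction-derived bounds
(|v| ≤ 1000), uptake exchanges only for media metabolites, and export-only
exchanges for (by default) all metabolites so mass-balanced byproducts have
sinks — without them, any byproduct of an essential reaction would falsely
block growth in uncompartmentalised models. Biomass is a pseudo-reaction
consuming components in fixed proportions; a component absent from the
network leaves biomass structurally blocked (yield 0) rather than raising.
Optional couplings: CO2 export may not exceed bicarbonate intake
(`v_EX_co2 + v_EX_hco3 ≤ 0` in the export-positive convention), and an
ATP/O flux-ratio equality over configured reaction ids. Yields below 1e-6
are reported as zero to mask LP degeneracy.

Gene knockouts are complex-aware: deleting a gene kills every complex that
contains it; a co-member is lost only when no functional complex containing
it remains; a reaction is removed only when no remaining functional gene
carries any of its EC numbers (functional paralogs rescue it). Growth calls
normalise mutant biomass by wild type and count a prediction correct when
|predicted − observed| ≤ 0.5; observations are binarized at 0.5 for the
growth/no-growth class (the agreement rule fixes 0.5 as the natural
symmetric choice; configurable). Cases with empty deletion sets are flagged
trivial and excluded from headline metrics.

## Synthetic data generator

Universes are layered carbon-skeleton chemistries: nutrients in layer zero;
each later metabolite made by one condensation or cleavage reaction from
strictly earlier metabolites (so the "spine" is gapless by construction,
which the tests certify rather than assume); decoy condensations produce
dead-end products. All molecules are pure carbon skeletons, making balancing
exact and greedy mappings total. Presence evolves by per-edge Bernoulli
gain/loss (defaults gain 0.1, loss 0.2, root prior 0.5 — moderate turnover
so that clades share signal without being constant); evidence scores are
right-skewed class-conditionals (blast-like: gamma(6, 60) vs gamma(1.2, 30)
with a 30% exact-zero mass for absent; shared-fraction: Beta(5,2) vs
Beta(2,5)), deliberately overlapping so no classifier is perfect.

The benchmark scenarios fix their conditions once: poor sequencing masks 50%
of enzymes' evidence in four of twelve leaves; the distant-species scenario
replaces scores above caps (200 blast-like, 0.5 shared-fraction — the caps
sit at the strong end of the *synthetic* score scale, playing the role that
absolute database-scale caps play on real data) with draws from an
absent-class donor pool in a four-leaf clade of eight, with the spine
treated as core metabolism present in all species. Reported AUCs are
qualitative: their orderings (comparative inference above naive above single
channels under masking; reconstruction above posterior thresholding under
score capping) are the reproducible quantity, not their absolute values,
which depend on the synthetic distributions.

What the generator does not emulate: real reaction chemistry (hydrogens,
heteroatoms, cofactors and currency metabolites), correlated gene loss,
annotation noise in the reference calls, or the heavy-tailed hit-score
distributions of real homology searches. Passing tests therefore certify
algorithmic correctness and the direction of the comparative/gapfilling
advantages under the model's own assumptions — not reconstruction accuracy
on real proteomes.

## Problem sizes and known limitations

Default test/benchmark sizes (12-leaf trees, 150 enzymes, ~26-reaction
universes, 20 benchmark replicates) are chosen so the full suite and the
acceptance script each run in minutes on a single core while keeping the
statistical assertions stable across seeds.

Limitations: strictly vertical evolution (no horizontal transfer); no
compartments; no thermodynamic direction inference (directions are inputs);
pathway search is heuristic at production settings; gapfill members are
never displaced once added; the optimal atom-mapping problem is out of scope
(precomputed or greedy mappings are consumed).
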