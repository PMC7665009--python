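# Methods

## Model

Development is treated as a cumulative presence process. For species
*s* with character-onset times in thermal units (degree-Celsius-days),
normalized time is

    pct(c) = 100 · (t_onset(c) − t0) / (t100 − t0)

with t0 the thermal time of fecundation and t100 that of a fixed
reference event shared by all species. An OTU is a pair
*(species, landmark)*; its state for character *c* is present iff
pct(c) ≤ landmark (closed boundary: an event recorded "at 25%" is
visible at the 25% landmark — staging tables report events at sampled
times, so ties belong to the landmark), absent if later, unknown if the
onset is unavailable. 0% rows are all-absent by definition, including
for characters with unknown onsets: nothing precedes fecundation.

Analyses operate on a *time frame*: an ordered set of interior
landmarks; the 0% and 100% boundary rows are always included, anchoring
each series at the organ-free start and the fully scored endpoint.

## Parsimony machinery

Characters are binary, unweighted, unordered; `?` is the full state set
{0, 1}. Trees are rooted by a hypothetical all-absent ancestor, making
"gain" and "loss" (reversal) directional. Scoring is Fitch counting;
state sets are packed into two per-row bit masks (zero-bits, one-bits),
so one node combination costs a handful of integer operations for all
53 characters at once. For multifurcating trees (consensus trees,
condensed trees) an exact two-state dynamic program replaces the
pairwise Fitch pass, since union/intersection rules are only exact on
binary trees.

**Row merging.** Identical rows are merged into one search taxon and
re-expanded afterwards; rows equal to the all-absent ancestor (the 0%
rows) become children of the root. Merging is what makes the printed
tree counts well defined: with four identical outgroup rows, unmerged
binary resolutions would multiply every topology by arbitrary
arrangements of identical leaves.

**Exact search.** Topologies are enumerated by stepwise leaf insertion;
Fitch length is monotone under leaf addition, so a partial tree whose
bound exceeds the incumbent is pruned with its whole subtree of
completions. Two admissible bound terms are added to the partial
length:

1. *Uncovered characters* — a character whose definite presences all
   lie among not-yet-inserted taxa contributes zero steps to the
   partial tree but at least one to any completion. Insertion order
   adds the least developed OTUs first precisely to keep this term
   large for long.
2. *Incompatible pairs* — two characters failing the four-gamete test
   on the full taxon set (the root supplies the (0,0) combination)
   jointly need ≥ 3 steps; a greedy matching over incompatible
   uncovered pairs adds one step per pair. Both terms are precomputable
   per insertion level because the inserted-taxon set depends only on
   depth.

Per-edge insertion costs are computed exactly in O(1) per edge from
Fitch up/down state sets (the state set optimally available on an edge
is the Fitch combination of the subtree set below it and the
complement-tree set above it; inserting a leaf costs one step exactly
for characters whose leaf state misses that set). The initial upper
bound comes from the heuristic search. On the bundled data the exact
search enumerates all optimal trees for the 20-OTU frames in well under
a second and for the full 32-OTU matrix in about ten seconds on one
CPU; length-only confirmation (pruning ties) takes about two seconds.

**Heuristic search.** Stepwise addition in matrix row order (plus four
seeded random-addition replicates when a seed is given), then
first-improvement SPR to a local optimum, collecting distinct
equal-best trees. Deterministic for a fixed seed. On the bundled
matrix it reaches the global optimum of every frame.

**Condensation.** Equally parsimonious binary trees are condensed by
collapsing internal branches of zero optimized length, then
deduplicated by canonical form. Two rules are provided: `max-zero`
collapses branches whose length is zero under *every* optimal
reconstruction; `min-zero` also collapses those that are merely
ambiguous (zero under *some* reconstruction). Per-branch minima and
maxima come from a two-sided dynamic program asking, per character and
edge, whether a change there is forced in all optimal reconstructions
or possible in some. `max-zero` is the default: calibrated against the
four printed tree counts of the worked analyses (2, 1, 4 and 50), which
it reproduces exactly, while `min-zero` merges some of them (1, 1, 2,
and fewer). If a search hits the `max_trees` cap the result is flagged
`capped` and only strictly better trees are pursued further, so the
optimal length is still certified.

**Ensemble indices.** CI = M/S, RI = (G−S)/(G−M), where M and G sum
per-character minimum steps (1 if both definite states occur) and
star-tree maxima (min of the definite-state counts). Both sums are
taken over the analyzed rows *plus the all-absent root ancestor*: the
root is an OTU of the analysis — development demonstrably starts
organ-free — and including it reproduces all four printed RIs (0.96,
0.97, 0.96, 0.96) under truncation, which excluding it does not (the
5–10–50% frame would give 0.9695 → 0.96 and the combined frame
0.9577 → 0.95). M and S are unchanged by the extra row whenever a 0%
row is present. Reported indices are *truncated*, not rounded, to two
decimals: 53/62 = 0.8548 → 0.85 and 53/71 = 0.7464 → 0.74 are only
consistent with truncation. Full-precision values are always carried
alongside, as is a CI over parsimony-informative characters only
(uninformative characters cost the same on every tree).

**ACCTRAN.** After the exact per-node cost arrays are computed, final
states are assigned root-down; when assigning the parent's state or its
opposite costs the same, the opposite is chosen, which accelerates
transformations: gains are pushed rootward and compensated by later
reversals. The mapped changes always sum to the tree length.

## Heterochrony detection

Three labelled modes appear side by side in every report:

* **strict** (set-based): character absent in the focal OTU and
  definitely present in *every* other species at that landmark (late);
  mirrored for advanced. Unknown states disqualify the character.
* **majority**: present in more than half of the other species that
  have a definite state; species with unknown states abstain rather
  than count against.
* **tree**: ACCTRAN gains are read off the strict consensus of all MP
  trees. A species is late at landmark L for character *c* when the
  gain of *c* subtends every other species' L-OTU but not the focal
  one; advanced when the gain's clade contains the focal L-OTU and
  every other species only enters the clade after L.

The set-based and tree-based views can disagree on single characters:
missing data (e.g. a character unavailable in one species throughout)
removes a character from the strict screen while the tree
reconstruction may still place its gain informatively. Directionality
is defined per landmark; time-segment labels are presentation only.

## Synthetic data

The generator emulates the study design: n_species (default 4) sharing
one normalized onset schedule for n_characters (default 53) — drawn
uniformly over (0, 100)% or supplied explicitly — expressed in
species-specific thermal spans drawn uniformly from 300–1500 °C·d (the
range spanned by spring- and autumn-spawning freshwater teleosts).
Injected heterochronies are additive shifts in percent points (the
scale on which the biology is stated); shifted onsets may exceed 100%,
in which case the character is absent at every interior landmark but
present in the all-present 100% row, consistent with the fixture's
structure. Missing data is i.i.d. per-cell masking.

What the generator does *not* emulate: intraspecific onset variability,
correlated missingness (real staging tables lose whole organ systems,
not random cells), character dependencies, and temperature-dependent
rate curves. Passing recovery tests therefore show the pipeline is
correct and sensitive under clean conditions, not that real staging
tables of arbitrary quality will yield unambiguous heterochronies.

The recovery harness scores the strict set-based detector: an injected
shift counts as recovered if a strict event matches its species and
direction at a landmark the shift straddles and names at least one
shifted character. With no injections and no reports, precision and
recall are 1 by convention.

## Numerical and design choices

* Landmarks are identified by their printed percent value; frames
  always include the 0% and 100% boundary rows (the printed CI
  arithmetic implies they were present in the original analyses).
* The truncation helper adds 1e-9 before flooring so that exact
  two-decimal ratios are not knocked down by binary representation.
* Ties in stepwise addition and SPR are broken by traversal order,
  which is deterministic; equal-best tree pools are kept as sorted
  canonical forms.
* Degenerate inputs fail loudly: empty frames, degenerate thermal
  spans (t100 ≤ t0), all-constant matrices (undefined indices), trees
  whose leaves do not match the matrix, matrices with fewer than two
  distinct non-ancestral rows.
* Test-suite problem sizes: the brute-force Fitch oracle runs on ≤ 12
  leaves, exhaustive tree enumeration on ≤ 7 distinct rows (10 395
  topologies), and the recovery grids on 4 species × 10–12 characters —
  sizes at which the independent oracles are themselves fast and
  exact.

## Known limitations

* Binary characters only — no multistate, ordered, polymorphic or
  weighted coding.
* The exact search is exponential in the worst case; matrices far less
  hierarchical than developmental data (or with heavy missingness,
  which creates large plateaus of equally parsimonious trees) should
  use heuristic mode with a tree cap.
* Tree-based diagnostics depend on the consensus resolution: over-
  collapsed consensus trees (heavy conflict) weaken node-based
  late/advanced calls; the set-based screens are unaffected.
* One printed index of the original analyses (the 5–10–20% frame CI)
  is reproduced only under the all-character convention (0.8689 →
  0.86); the informative-only variant is reported alongside because
  parsimony programs differ in which convention they print.
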