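# Methods

## The reconciliation model

A reconciliation embeds a rooted gene tree into a rooted binary species
tree.  Every gene leaf maps to the species carrying it; every internal
gene node `u` maps to a species node `m(u)` and is labeled with one
event:

* **co-divergence** at an internal species node `x`: one child image in
  each child subtree of `x`;
* **duplication** on the edge above `x`: both child images inside the
  subtree of `x`;
* **transfer** from the edge above `x`: one child image stays inside the
  subtree of `x`, the other lands on a node *incomparable* to `x`
  (neither ancestor nor descendant).

Losses are charged per species edge a child image sits below its starting
point (one fewer for co-divergence, where the child starts one edge
down).  No loss is charged above the gene root: the family enters the
species tree wherever its root maps.  The total cost is the weighted
event count with defaults δ=1.5 (duplication), λ=1 (loss), τ=6
(transfer), 0 (co-divergence) — the scheme used in published
reconciliations of fungal metabolic enzymes.  All comparisons run on
integer-scaled costs (1.5 → 3 at scale 2), so ties are exact and the
co-optimal solution count is an exact integer (values above 10⁶ occur
and are handled).

The model is **undated**: the DP forbids ancestor–descendant transfers
but does not order species nodes in time.  A post-hoc feasibility check
builds the strict precedence graph the transfers imply — ancestry edges
plus, for a transfer from edge `(p(x),x)` to edge `(p(z),z)`, the
overlap constraints `p(x) ≺ z` and `p(z) ≺ x` — and rejects solutions
whose graph is cyclic.  When *every* co-optimal solution is infeasible
the result carries `feasible=False` and no event counts, mirroring how
the fungal clade 1 reconciliation fails rather than being silently
repaired.  This two-stage design (rather than a fully dated model) is
deliberate: a dated model could never fail, and observing failure is part
of the analysis.

**Canonical solution.**  Event counts are reported for one co-optimal
solution chosen by: temporal feasibility first, then fewest transfers,
fewest duplications, and earliest postorder placement.  Co-optimal
solutions are enumerated up to a cap (default 20 000); beyond the cap the
canonical solution is the best of the enumerated prefix and the
feasibility verdict is flagged non-exhaustive.

**Multifurcations.**  Weak-edge collapsing (support < 98, strictly — an
edge at exactly 98 survives) produces polytomies.  These are resolved to
a minimum-cost binary resolution: exhaustively over the joint resolution
space while it holds ≤ 1000 combinations; otherwise every polytomy starts
from a greedy deepest-species-LCA agglomeration and is refined one
polytomy at a time, exhaustively over its own resolutions up to degree 5.
Joint exhaustion over many polytomies is combinatorially impossible
((2k−3)!! per polytomy, multiplied), and in practice the greedy-plus-
refinement search reaches cost 0 on congruent instances and matches the
exhaustive search on everything small enough to check.

**DL mode** is the same machinery with transfers disabled; on binary gene
trees it reproduces the classical LCA reconciliation, which the package
also implements independently (`lca_reconcile`) as a cross-check.

## What the simulator emulates

`simulate_species_tree` runs a constant-rate birth–death process from a
root bifurcation at time 0, stopping the first time the extant lineage
count reaches `n` (plus a uniform fraction of the next waiting interval,
so leaves stay contemporaneous); extinct replicates are resampled.  The
result is ultrametric with exact `n−1` internal nodes.

`simulate_gene_family` evolves a single root copy down the species tree
with exponential waiting times per lineage (Gillespie-style).
Duplication splits the lineage in place; loss ends it; transfer places an
*additive* copy on a species edge drawn uniformly among the edges alive
at the event time, so simulated transfers are temporally feasible by
construction.  Under a small duplication rate and no loss, the expected
number of duplications is `rate × total branch length` — the analytic
oracle the tests use.

Ground truth distinguishes *all* events from *visible* ones:

* a duplication is visible when both daughter subtrees survive;
* a transfer is visible when the recipient subtree survives;
* a loss is visible for each co-divergence of a surviving lineage whose
  sister copy left no survivors (that is exactly the loss a parsimonious
  observer of the pruned tree must infer).

Recovery tests compare inferred counts to visible counts, because
reconciliation can only see surviving lineages.

The standard synthetic conditions are a 16-species Yule tree (birth 1.0)
with rates 0.08 / 0.06 / 0.05 (duplication / transfer / loss per lineage
per unit time), giving roughly one to two events per type per family —
"low rates" at sizes a single CPU reconciles in milliseconds.  Support
degradation marks exactly `round(f · n_internal_edges)` edges weak
(uniform in `[support_low, 98)`), the rest strong (`[98, support_high]`).

The BGC generator gives each clade an anchor gene (the two type III PKS
domains, core-flagged) plus tailoring domains included with per-domain
probabilities and shared noise domains.  The gene order is drawn once per
clade profile and shared within the clade, so clusters with identical
content are also architecturally identical (adjacency index 1) while
order still varies between clades; pairwise instance similarities come
from a deterministic hash model (same-clade pairs near 1, cross-clade
halved) so no quadratic table is stored.

What the simulator does **not** emulate: sequence evolution (similarity
values are modeled, not aligned), rate heterogeneity across lineages,
replacing transfers, gene-order rearrangement within clusters, or
correlated domain gain/loss.  Passing recovery tests therefore show the
inference machinery is sound on data matching its model assumptions, not
that real genomes satisfy those assumptions.

## BGC distance and occurrence conventions

`d(A,B) = 1 − (0.22·J + 0.76·DSS + 0.02·AI)`.  J is the Jaccard index
over domain-type sets.  AI is the Jaccard index over unordered adjacent
domain-type pairs read along each cluster; when both clusters have no
adjacencies (single-domain clusters) AI is 1 if their type sets match and
0 otherwise, so identity still scores distance 0 and disjointness 1.
DSS pairs instances within each domain type by maximum-total-similarity
assignment (exact, via the Hungarian algorithm — copy numbers are small),
scores unmatched instances 0, and weights anchor-domain instances double;
without sequences, same-type similarity defaults to 1 and the metric
degrades gracefully to content/architecture comparison.  Families are
connected components with edges at distance ≤ 0.5 (boundary included);
no affinity-propagation step is applied.

`O(C,d)` sums, over the families of clade C, the fraction of member BGCs
containing domain `d` — counting a BGC once however many copies it has,
after excluding domains that only occur on core (biosynthetic) genes.
Frequency divides by the clade's family count, so `0 ≤ O ≤ n_families`
and `0 ≤ frequency ≤ 1`.  Enrichment uses the 2×2 chi-square with Yates'
continuity correction (statistic clamped at zero; a zero marginal yields
an undefined statistic and p = 1 by convention), one-sided: a domain is
enriched only when p < α *and* its group proportion exceeds the
background proportion.  α defaults to 0.05 with no multiple-testing
correction; a Bonferroni option exists but is off by default.  The
background is strictly non-BGC genes.

## Other numerical and design choices

* Coordinates are 0-based half-open internally; GFF3 input (1-based
  inclusive) is converted at the boundary.  Multi-PKS loci chain type III
  genes on one scaffold with gaps ≤ 20 kb (a transparent surrogate for
  cluster-prediction regions; configurable).
* Domain presence defaults to e-value ≤ 1e-5 in the hit-table reader.
* Percentages in presence/absence reports round half-up to integers.
* Clade extraction takes maximal clades with subtending support ≥ 95
  (configurable) and ≥ 2 leaves; clades are numbered by their
  alphabetically smallest member, making the assignment invariant to
  Newick rotation.  A curated seed-taxa mode reproduces hand-defined
  clades.
* Nested-foreign-clade candidates require the parent context (parent
  clade minus the candidate) to be > 90% one foreign kingdom, and a
  candidate may not be a child of the root — a clean kingdom split is
  separation, not nesting.
* Pipeline stages communicate through files; a stage re-runs when forced,
  requested, missing an output, or downstream of a stage that ran.
  Reports carry no timestamps, so same-seed re-runs are byte-identical.

## Test-suite problem sizes

The reconciliation oracle suite enumerates every (mapping,
event-labeling) reconciliation by brute force and checks exact agreement
of cost *and* co-optimal count: all rooted species topologies on 3 and 4
labeled leaves crossed with seeded random gene trees (2–4 leaves,
repeated leaf assignments allowed), plus seeded random 5-leaf and 6-leaf
pairs — a few hundred instances in total.  The Monte-Carlo simulator
checks use 1000 species-tree replicates (ultrametricity bookkeeping) and
2000 gene-family replicates (Poisson duplication expectation within three
standard errors).  Parameter recovery uses 200 families at the standard
synthetic conditions.

## Known limitations

* **Transfer and loss recovery under the published cost scheme.**  With
  τ=6 against δ=1.5 and λ=1, a transfer between species edges fewer than
  about five edges apart is cheaper to explain as duplication-plus-losses
  or pure losses, so parsimony systematically under-infers short-range
  transfers and the converted events inflate inferred losses.  At the
  standard synthetic conditions duplications recover with Spearman
  ρ ≈ 0.89, while transfers (ρ ≈ 0.74) and losses (ρ ≈ 0.67) stay below
  the 0.8 recovery bar the test suite asserts; the corresponding
  acceptance test is left failing as an honest record.  This is a
  property of parsimony at these costs, not of the implementation: the
  dynamic program agrees exactly with brute-force enumeration wherever
  enumeration is possible, and the inferred cost never exceeds the priced
  true history on any simulated family.
* The co-optimal count after polytomy resolution refers to the selected
  resolution only; counts are not aggregated across equally cheap
  resolutions.
* `class_presence_absence` treats each genome as one sample; no
  phylogenetic correction for relatedness is attempted.
* The similarity hash model is a stand-in for alignment-based domain
  similarity and should not be compared numerically to alignment scores.
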