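# Methods

## Problem and objective

The package extracts a forest subnetwork *G′* = (*V′*, *E′*) from a
template interactome *G* = (*V*, *E*) minimizing

F(G′) = Σ_{e∈E′} c_e + Σ_{v∉V′} p′_v + w·k,

where the penalized prizes p′_v = max(0, β·p_v − μ·degree(v)) fold the
prize-scaling parameter β and the hub penalty μ into a single per-node
value before solving. Three choices here were genuinely open and are the
package's own:

- **Clamping.** The degree penalty can drive a prize negative; a negative
  prize would act as an extra node cost the objective does not define, so
  penalized prizes are clamped at 0. This keeps the forgone-prize term
  non-negative and makes p′ pointwise monotone non-increasing in μ.
- **Order of operations.** The penalty applies after β scaling
  (p′ = β·p − μ·deg). The two orders differ only by rescaling μ; fixing
  one makes μ's recommended range [1e-4, 5e-2] directly interpretable at
  β = 1, the default.
- **Degree.** degree(v) is taken in the full template network, never in a
  candidate solution: the penalty models the hub's a-priori promiscuity,
  not its role in one particular forest.

Node identifiers are opaque case-sensitive strings; duplicate undirected
edges keep the minimum cost (the most confident report of an
interaction); self-loops are dropped.

## Heuristic solver

PCSF is NP-hard, so `solve_pcsf` is a heuristic built from well-understood
parts, all deterministic (ties broken by sorted identifiers, so fixed
inputs give bit-identical outputs):

1. **Root reduction.** An artificial root is connected to every terminal
   with positive penalized prize by an edge of cost w. Any rooted tree in
   the augmented graph whose root edges are deleted yields a forest in
   which each surviving root edge charged exactly w — the w·k term is
   exact by construction. The root deliberately connects to terminals
   only: a tree of prize-less Steiner nodes can never pay for itself.
2. **Goemans–Williamson moat growth.** Every node starts as a singleton
   cluster with potential p′_v; active clusters (not containing the root,
   potential remaining) grow moats at unit rate; an edge becomes tight —
   merging its two clusters — when the moats on its sides have jointly
   paid its cost; a cluster dies when its potential is exhausted. Events
   are processed in deterministic order (smallest time, then smallest
   edge/cluster identity).
3. **Tree-DP pruning.** Rather than classical strong pruning, the grown
   tree is reduced by an exact dynamic program that finds the optimal
   *subforest within the tree's edges*: per node, A(v) = best profit with
   v included and its component left open; B(v) = best unconstrained
   profit, B(v) = max(A(v) − w, Σ_children B). This subsumes leaf pruning
   *and* cutting an over-expensive edge into two trees, and on ties
   prefers exclusion, so no zero-prize leaf survives.
4. **Local search.** To a fixed point, the best of three move types is
   applied and the forest re-pruned: open a profitable singleton tree;
   attach a missed terminal via its cheapest path (path-node prizes
   offset edge costs); merge two trees through the cheapest connecting
   path (saving one w). A depth-1 lookahead then retries near-miss moves
   (immediate gain in (−w, 0]) because a merge can pay off only through
   the follow-up attachments it enables; the expanded state is accepted
   only if its final objective is strictly better. Finally the node set
   is re-spanned by a minimum spanning forest of its induced subgraph and
   each Steiner node's deletion is trialled the same way.
5. **Safety net.** The result is compared against the empty forest and
   the best set of isolated terminals ({v : p′_v > w}) and is never worse
   than either.

If no node retains a positive penalized prize (μ too large), the empty
forest is returned with a warning rather than an error.

`solve_exact` is the independent authority for tests: depth-first
enumeration of all acyclic edge subsets (union-find cycle pruning, ≤ 20
edges guarded) plus the optimal choice of isolated prize nodes
(include iff p′ > w). Ties within 1e-12 of the best objective are broken
by lexicographically smallest sorted edge list, then node list; a node
with p′ exactly equal to w is excluded, which realizes the smaller node
list. On 200-instance batches of random graphs (≤ 10 nodes, ≤ 14 edges,
w ∈ {0.5, 1, 2}) the heuristic matches the oracle on ≥ 99% of instances
across every seed batch tried, with worst observed ratio ≤ 1.08.

Objective comparisons use absolute tolerance 1e-9 (costs and prizes are
user-scale reals); internal tie decisions use 1e-12.

## Randomization

`pcsf_rand` re-solves on n independently perturbed graphs and counts
appearances. The noise model is **multiplicative uniform**:
c_e → c_e·(1 + u), u ~ U[−r, r] i.i.d. per edge and run. Multiplicative
noise keeps the perturbation scale-free across heterogeneous cost ranges
— a 10% wobble means the same thing for a 0.05 and a 0.9 cost — which is
the natural reading of a relative noise level r; an additive strategy
(offset scaled by the mean cost) is selectable by configuration. r < 1 is
enforced so costs stay positive. One master `SeedSequence` spawns n
independent substreams, so results are invariant to execution order and
bit-reproducible from the seed. Defaults n = 10, r = 0.1. Prizes are
never perturbed (out of scope).

## Clustering and enrichment

Subnetworks are clustered by Girvan–Newman divisive edge-betweenness
(networkx), evaluated unweighted; the dendrogram cut maximizing
modularity is kept, starting from the partition into connected components
so clustering only ever refines connectivity. Singletons are their own
clusters; ids are contiguous from 1 in order of smallest member.

Enrichment for each (cluster, gene set) pair uses the one-sided Fisher
exact test, computed as the hypergeometric upper tail
P(overlap ≥ observed) over the universe. The **universe is the full
template interactome** — the frame the subnetwork was drawn from — not
the genome; using the genome would overstate enrichment for anything
network-biased. Benjamini–Hochberg adjustment is applied within each
cluster across all tested sets (matching per-cluster reporting), rows are
ranked by (adjusted p, raw p, set name) for stable output, and the top 15
per cluster are kept by default. Set members outside the universe are
ignored at test time. Note the hypergeometric null is discrete, so under
random relabeling the fraction of raw p < 0.05 is the largest attainable
level *below* 0.05 for each table geometry (≈ 2–3% for the geometries in
the calibration test), not 5% exactly; the calibration test compares the
empirical fraction against that exact attainable level.

## Synthetic instances

The generator emulates the structure the method assumes: a connected
Barabási–Albert background (n = 300 nodes, 2 edges per arrival, so hubs
with degree ≫ median exist) with i.i.d. uniform(0.1, 1.0) edge costs —
the scale of confidence-derived interaction costs — and a planted
connected module of 15 nodes grown by seeded random frontier expansion,
carrying gamma(shape 2) prizes of mean 5, far above typical connection
costs, as a strongly dysregulated pathway would. Two percent of the
remaining nodes get gamma prizes of mean 0.5, emulating scattered
sub-threshold signal. The named small fixtures isolate single behaviours:
a 6-node toy whose optimum (3.7 at w = 2, β = 1, μ = 0) is frozen from
the oracle; two cheap terminal chains joined by a 1.5-cost bridge, where
the exact tree count drops from 2 to 1 once w exceeds the bridge cost;
and a hub instance in which ten degree-11 terminals of prize 0.5 hang off
a prize-less hub — at μ = 0 collecting them (hub as Steiner connector) is
optimal, while at μ = 5e-2 the degree penalty (0.55) wipes their prizes
and the hub leaves the solution.

What the synthetic data does *not* emulate: real PPI topology beyond a
heavy-tailed degree sequence (no duplication-divergence structure, no
community structure in the background), correlated costs, identifier
noise, or realistic prize distributions from any specific assay. Passing
tests therefore demonstrate correctness and robustness of the
optimization and statistics under the stated generative assumptions, not
biological validity on any particular dataset.

## Problem sizes and degenerate inputs

Test and acceptance workloads use 200 random oracle-comparison instances
(≤ 10 nodes, ≤ 14 edges — the exhaustive oracle's comfortable range), the
300-node recovery instance with 10 noisy runs, 100 random Fisher tables
against a brute-force tail sum, and a few hundred relabeling replicates
for null calibration; these sizes give stable statistics while keeping a
full run in seconds to minutes on one core. Degenerate inputs are legal
where meaningful: a single prized node with no edges solves via the
trivial-solution comparison; an empty forest is a valid solution (and the
correct one when every prize is below w); an all-zero prize vector yields
the empty forest with a warning; empty subnetworks cannot be clustered
and raise.

## Known limitations

- The heuristic carries no approximation guarantee; quality is
  established empirically against the exhaustive oracle at small sizes.
- Exact solving is limited to 20 edges by design; it exists as a test
  authority, not a production path.
- Enrichment ignores relationships among gene sets (no GO-hierarchy-aware
  testing, no term-redundancy reduction).
- Edges are undirected and unsigned; no identifier translation between
  naming systems is attempted.
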