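# Methods

## Model and assumptions

A consumer-resource-toxin (CRT) model abstracts a microbial community to
its qualitative interaction structure. Each of `S` taxa is a
self-replicator; `M` food resources mediate all positive interactions and
`T` toxins all negative ones. The model deliberately drops stoichiometry,
rates and abundances, which buys three strong assumptions:

* **Essential resources.** A taxon needs *all* of its required resources
  to replicate; resources are not substitutable.
* **Fast, unneutralizable toxins.** A single toxin produced within a
  community kills every sensitive member before any other process
  matters. Toxins stand in for any mechanism enforcing mutual exclusion
  (amensalism, predation, interference competition).
* **Closure is vacuous.** Taxa never create new taxa, so the closure
  half of the chemical-organization-theory definition holds for every
  subset; only self-maintenance (condition 1) and toxin compatibility
  (condition 2) discriminate.

Because one table cell encodes the one relation between a (taxon,
resource) pair, a taxon can never both produce and require the same
resource; this is an encoding restriction, asserted rather than silently
repaired.

## Enumeration

The brute-force path scans the power set (vectorized over chunks with
numpy; default refusal above S = 20). The constructive path grows, for
each taxon, all minimal self-maintaining closures: unmet requirements are
resolved by *minimal producing sets* (inclusion-minimal supplier sets,
enumerated as minimal hitting sets), branching over alternatives; the
collected closures are closed under pairwise union and toxin filtering is
a final removal pass. Every toxin-free organization decomposes into
per-taxon closures of this form, so union closure regenerates the full
set; the test suite nevertheless treats brute force as the oracle and
asserts equivalence on random models up to S = 12.

`generate_organization` (the random-encounter collapse) removes
toxin-sensitive taxa in one initial pass computed from the producers
present in the *initial* set, then removes starved taxa simultaneously
per round (Jacobi-style, hence order-independent) to a fixed point.
Sensitive taxa are never re-added even if the producer later starves —
the fast-toxin assumption — so the result is always an organization,
though not necessarily the largest one the initial set contains.

## Extended hierarchy

Nodes are the organizations plus their *pairwise* unions and
intersections (not iterated over derived sets; pairwise closure matches
the worked example's node inventory). A derived set that is both a union
and an intersection is necessarily an organization — self-maintaining as
a union of organizations, toxin-compatible as a subset of one — so the
three node statuses are mutually exclusive, with green taking precedence.
Cover edges are computed per node by scanning strictly smaller nodes in
decreasing cardinality and keeping the maximal ones; a quadratic oracle
check backs this in the tests. Export order is ascending cardinality,
then lexicographic, for reproducible diffs.

Interaction clusters subtract from each organization the union of all
organizations strictly below it. A cluster that is itself an
organization is context-free, otherwise context-dependent; every cluster
is connected in the resource-dependency graph (asserted on all clusters
of 100 random toxin-free models). Elementary organizations are those
with non-empty clusters; the package verifies that every other
organization is the union of the elementary organizations it contains.

## Random models and study sizes

The generator draws table cells i.i.d. row-major from one seeded PCG64
stream: food cells are `+`/`−`/`0` with probability 1/3 each by default,
toxin cells `+` with `p_toxin_produce` and `−` with `p_toxin_sensitive`
(default 0.1 each). These defaults are the standard conditions of the
simulation studies: S = 10, M = 10, T = 5 for ensemble statistics and
S = 10, M = 30, T = 3 for the resource-specialization contrast. Ensemble
sizes are 100 models for node-count statistics and 50 for
measurement-effort studies, with replicate *r* of a run seeded `seed + r`.
Organization counts include the empty organization, and all reported
counts of derived sets are counts of *distinct* taxa sets.

What the generator does not emulate: phylogenetic correlation between
rows, resource classes with different producibility, abundance-dependent
interaction strengths, or environment-supplied (external) resources.
Passing ensemble tests therefore demonstrate combinatorial properties of
the model class, not fits to any particular real community.

## Measurement simulation

Measurements are organizations by assumption (communities are observed in
attractors). Three encounter modes: `novel` draws uniformly without
replacement (a seeded permutation), `neutral` uniformly with replacement,
`random` collapses a random taxa set (per-taxon inclusion probability
0.5) through `generate_organization` — initial sets collapsing to the
empty set count as measurements of the empty organization. Repeat
measurements are no-ops.

Reconstruction tracks pairwise unions and intersections of measured sets.
A set appearing as both is an *additional organization* and provably
true: it is self-maintaining as a union of organizations and
toxin-compatible as a subset of a measured organization. Recovery curves
therefore default to counting measured plus additional organizations
(no false-discovery inflation); a `plus_all_candidates` policy exposes
the optimistic count, and the false discovery rate of a candidate
category is the fraction of its sets that are not true organizations —
undefined (returned as `None`) for empty categories. Without toxins the
union-FDR is identically zero, since unions of organizations are then
always organizations.

## Inference

**Toxin tables.** Candidate impairings come from decompositions of each
non-persistent union into two organizations, seeded by the pair's set
differences and minimized side-wise; a pair `(A,B)` is an impairing when
no organization contains `A ∪ B`, and minimality is verified against all
one-element-smaller variants. A minimum-cardinality impairing subset
explaining every non-persistent union is found by exact set cover
(capped), and each impairing becomes one toxin with two orientations;
alternatives are verified to reproduce the red/green classification.
Multi-taxon sides translate to "all of one side produces, all of the
other is sensitive", an extrapolation flagged on the output.

**Food tables.** The search must return a table whose implied
organization set — self-maintaining sets containing no impairing pair —
equals the measurements *exactly*; resource count is minimized
heuristically. Three steps:

1. *Requirement assignment.* A taxon whose monoculture was measured can
   require nothing (a requirement is never satisfiable alone); every
   other taxon receives at least one requirement. This step fixes the
   number of seed resources reported as `n_seed_requirements`.
2. *Supply synthesis.* For a taxon `t`, any resource column requiring
   `t` with producer set `D` imposes the constraint "some member of `D`
   is present"; for measured sets to survive, `D` must intersect every
   witness `X∖{t}` with `t ∈ X` measured. The admissible producer sets
   are exactly the minimal hitting sets of the witness family. Ruling
   out every unobserved, unblocked composition is then a covering
   problem over (taxon, producer-set) pairs; a seeded greedy cover adds
   whole producer-set groups (one group = one future column) and prunes
   redundant pairs.
3. *Resource sharing.* Requirements backed by the same producer set
   share one column — producer/requirement conflicts cannot arise
   within a group, since an admissible producer set never contains its
   own consumer.

If even the strongest admissible table (all minimal hitting sets as
conjuncts) leaves an unobserved composition implied, the model class
cannot express the measurements; the strongest table is returned flagged
`exact=False` together with the residual symmetric difference. Distinct
greedy tie-break variants are explored and the best tables by (resource
count, non-zero entries) returned. On the five-taxon worked example this
reconstructs a four-resource table — the same resource count as the
generating model — whose cross-feeding links differ from the original,
as expected for an under-determined inverse problem.

## Numerical and degenerate-input choices

* Taxa sets are `frozenset[str]`; all serialized output is sorted by
  cardinality then lexicographically, so runs diff cleanly.
* All stochastic operations take an explicit integer seed; nothing reads
  global RNG state.
* Empty models (S = 0), toxin-free models (T = 0) and the empty taxa set
  are first-class inputs throughout.
* Exact combinatorial searches carry caps (power-set scan S ≤ 20,
  producing-set candidates ≤ 20, impairing set cover ≤ 20, food-table
  taxa ≤ 16) and raise a capacity error with a pointer to the heuristic
  alternative rather than running away.
* Greedy tie-breaks draw uniformly among equally good candidates from
  the call's seeded generator.

## Known limitations

* The taxa-only reduction enumerates minimal producing sets exactly only
  for small candidate pools; the greedy path returns one locally minimal
  set, not all of them.
* `generate_organization` implements the fast-toxin reading; determining
  the true largest contained organization is ambiguous when toxin
  producers themselves starve.
* Food-table inference guarantees exactness when it reports it, but
  resource-count minimality is heuristic (greedy cover), and the search
  space restriction to minimal-hitting-set producer columns means some
  exotic exact tables are out of reach.
* Higher-order effects — a third taxon neutralizing a pairwise toxin
  interaction — are outside the model class by design: a sign table per
  (taxon, toxin) pair cannot express them.
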