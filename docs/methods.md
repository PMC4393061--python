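# Methods

## The dual-graph model and its constraint system

A dual graph represents each RNA stem as a vertex and each
single-stranded motif as an edge; loops and parallel edges are
allowed.  The package enforces the model's constraint system exactly:

- a loop contributes **2** to the degree of its vertex.  This is not a
  stylistic choice: only under this convention does the constraint
  system (degree ≤ 4, size 2n − 1, degree sequence (4,…,4,2) or
  (4,…,4,3,3)) reproduce the known catalogs — e.g. exactly three
  topologies at order 2;
- connectivity is required.  It is implicit in the biology (one
  molecule's stems joined by strands) and necessary combinatorially:
  without it the order-4 count is not 30;
- a vertex with two loops would have degree 4 with no external
  incidence and therefore be disconnected at order ≥ 2; the enumerator
  needs no special case, and a test asserts no catalog member carries
  a double loop.

## Enumeration and canonicalization

Candidates are generated by recursive multiplicity assignment over the
labeled edge slots (all vertex pairs plus loops) with per-vertex
degree-cap pruning and target size 2n − 1, then filtered by degree
sequence and connectivity, then deduplicated by canonical key.  The
canonical key is the lexicographic minimum over all vertex relabelings
of the sorted edge multiset — exhaustive (n ≤ 8, i.e. ≤ 40320
permutations), hence exact; correctness trumps asymptotics at this
scale.  An independent oracle (generate *all* labeled edge multisets,
filter, deduplicate by pairwise bijection search, no canonical forms)
reproduces the catalogs at small orders.

The package's catalog numbering (`Dn.k`, sorted by canonical key) is
internal; `DualGraphCatalog.with_id_mapping` accepts a mapping for
users who hold identifiers from an external database.  The counts
produced by this constraint system are 3, 8, 30, 118 at orders 2–5.
The 118 at order 5 exceeds the 108 reported by the external database's
graph-growing update; the constraint system implemented here is
exactly the one stated above, and no additional unstated constraint is
guessed at to force agreement.

## Line graphs

The line graph has one vertex per edge of the source multigraph —
each parallel copy and each loop individually — and an adjacency
whenever two source edges share an endpoint.  A loop occupies its
vertex and is therefore adjacent to every other edge there, but not to
itself; parallel edges share both endpoints but produce a single
adjacency: the output is simple.  Line-graph vertices are labeled
`(u, v, k)` with `k` the parallel index for traceability.  This is
what lets exact simple-graph invariants (cliques, chromatic data,
domination, …) quantify multigraph topology.

## Distance conventions

Loops are real strands, so four conventions are provided: STANDARD
(loops ignored, zero diagonal), LOOP_DIAGONAL (diagonal marks loop
vertices), LOOP_TRAVERSAL (a path's cost additionally counts one per
loop-bearing vertex it meets; endpoints included by default, with a
switch, since the rule is stated for traversals generally), and
WEIGHTED_TRAVERSAL.  The weighted rule is defined from one-hop
traversal options: each of the k parallel edges from u to v, each
optionally preceded by one traversal of a loop at u, all equally
weighted; the distance is the total weight of the minimal-length
options, i.e. 1/(1 + loops at u).  This generalization is anchored by
the model's worked configuration — loop at u plus double edge: four
options, weight 1/4 each, distance 1/2 — and degrades to the classical
distance 1 on plain edges.  Two readings of that worked value ("weight
mass of shortest traversals", implemented, versus "shortest length ÷
parallel multiplicity") coincide on the anchor case; the choice is a
package convention, not an asserted intent.  Because the one-hop value
depends on loops at the traversal's source, orientations can differ;
the matrix entry takes the cheaper orientation so the matrix stays
symmetric.  Weighted values are exact `fractions.Fraction`s.

## Descriptors

The descriptor suite adopts the standard literature definitions:
Balaban's J (with loops contributing an edge term (sᵤ²)^(−1/2) and
counting in m and μ), Wiener as the sum of pairwise distances, Randić
as Σ (dᵤdᵥ)^(−1/2), Platt as Σ (dᵤ + dᵥ − 2).  Distance-based indices
are registered once per distance convention, giving the Balaban/Wiener
variant families.  Two Laplacian variants are registered: the classic
loops-ignored L = D − A (connected ⇒ exactly one zero eigenvalue) and
a loop-weighted variant in which each loop adds 2 to the diagonal,
shifting the spectrum strictly upward; the two families disagree only
on looped graphs and both are informative, so neither is silently
preferred.

Line-graph invariants are computed **exactly** by exhaustive search,
valid up to 12 vertices (order-5 line graphs have 9): cliques via
Bron–Kerbosch, independence as clique of the complement, domination by
subset enumeration, chromatic number by backtracking from the clique
lower bound, chromatic index as Δ-edge-colorability (Vizing), and
circular chromatic number by testing (k, d)-colorings in increasing
k/d over (χ − 1, χ], k ≤ 2|V|, with exact rational output.  The
circular chromatic *index* requires the line graph of the line graph,
which exceeds the exhaustive bound for order-5 catalogs; such cells
are recorded as flagged missing values, never silent zeros — the
feature-table contract is that a descriptor either computes exactly or
is visibly absent.

The default registry names 34 descriptors.  The original analysis
used on the order of a hundred invariants whose precise membership is
not recoverable; the registry is a documented best-effort
reconstruction and is extensible by constructing `DescriptorSpec`s.

## Normalization and screening

Descriptors are standardized against the verified reference class:
I ↦ (I − mean_ref)/stdev_ref, computed per order.  The standard
deviation is the sample (n−1) deviation by default with a population
(ddof=0) switch.  Constant-over-reference descriptors are excluded
with a warning.  Screening reports each descriptor's [10th, 90th]
reference percentile band (linear interpolation between order
statistics) and the fraction of candidates outside it; descriptors
with no candidates outside the band cannot discriminate, matching
their ROC AUC ≈ 0.5.

## The cognitive one-class algorithm

Given seed positives P₀ and an unclassified pool S, the algorithm
first manufactures "large-σ" negatives: vectors at least `sigma_min`
reference standard deviations from every training pattern **in every
descriptor** (random side of the training range per coordinate, plus
an exponential overshoot).  The per-descriptor scale matters: it is
the same scale on which the features are standardized, and it keeps
the geometry consistent as dimensionality grows.  Each iteration:

1. train the scorer on P ∪ N (default scorer: one-hidden-layer
   feed-forward network, logistic output, L2 penalty α = 0.5, lbfgs;
   a logistic-regression scorer satisfies the same contract and is
   swappable);
2. compute the **Youden band** on the training scores — the interval
   of thresholds maximizing sensitivity + specificity − 1, with
   midpoints between adjacent scores as candidates.  Scores inside
   the band are ambiguous;
3. promote up to `n` top-scoring S members **above** the band into P,
   demote up to `m` bottom-scoring members strictly **below** it into
   N (defaults: 10% of the initial |S| each);
4. return misclassified members of N and P to S.  A freshly trained
   network classifies its own training patterns correctly almost by
   construction, so "misclassified" is judged against the method's
   founding prior instead: only patterns many standard deviations
   from the positive class can be asserted negative.  An N member is
   returned when it is as close to P as P members are to each other
   (within 1.25× the median nearest-neighbor distance of P), or when
   it is near P (within max(sigma_min, 1.25×) of that scale) and
   isolated among the negatives — a pattern backed by other nearby
   negatives is negative on the data's evidence, not just its own
   label.  A non-seed P member farther from every seed than
   max(sigma_min, 1.5× the seed nearest-neighbor scale) has no
   support from the original class and is returned.  Seeds never
   move;
5. drop the synthetic negatives after the first iteration, re-seeding
   them in a later iteration only if N has no real member (the
   scorer needs both classes);
6. stop when S is empty and N is empty, at a fixed point, or at
   `max_iter` (default 20).

The number of synthetic negatives defaults to max(2 |P₀|, 40): the
scaffolding must surround the positive class densely enough that no
direction is left unguarded, and at least balance the positives.
Every random draw descends from the single run seed; identical seeds
give byte-identical histories.

Behavior on synthetic data (and what it shows): on single-class
Gaussian data the final negative set empties and S is absorbed into P;
on two classes separated by 6σ per descriptor, a two-class partition
emerges with the second class accumulating in N_f (≈ 99% of held
patterns partitioned correctly over 10 seeds at 20 dimensions,
100 + 100 patterns).  Real descriptor panels are correlated,
discrete-valued and non-Gaussian, so these tests validate the
algorithm's mechanics, not its biological conclusions.  On the real
catalogs with synthetic verified labels the algorithm absorbs all
order-4 and order-5 topologies into P — consistent with the view that
the verified class typifies the whole space — but with synthetic
labels that observation is a pipeline demonstration, not a biological
finding.  Persistence-in-N ranking and a triangle/max-degree
annotation of N_f members are surfaced in reports as descriptive
structure, never as a classification rule.

## Numerical and reproducibility choices

- Exact arithmetic where the quantity is exactly rational: weighted
  distances, circular chromatic numbers.
- Laplacian eigenvalues via symmetric eigensolver; the connectivity
  zero is asserted to 1e−9.
- Ties everywhere break by pattern/graph id under stable sorts; the
  ROC-threshold operation breaks Youden ties toward the larger
  threshold.
- k-medoids is a deterministic PAM (greedy BUILD + best-improvement
  SWAP); hierarchical clustering is average linkage on Euclidean
  distances.
- All randomness (labels, synthetic negatives, scorer initialization)
  descends from explicit seeds; pipeline bundles are byte-identical
  under identical configs.
- Problem sizes used by the shipped tests and the acceptance script —
  orders ≤ 5, 200-graph invariant oracles at order ≤ 8, 10-seed
  one-class trials at 20 dimensions — were chosen so the whole suite
  completes in well under a minute while remaining exhaustive where
  exactness is claimed.

## Known limitations

- Enumeration and canonicalization are exhaustive by design and
  intentionally refuse orders above 6 and 8 respectively.
- The 118-vs-108 order-5 discrepancy with the external database is
  reported, not resolved; resolving it would require the database's
  unstated extra constraint, if any.
- The catalog-to-database identifier mapping, the identities of the
  verified sets, and any findings that depend on them (which specific
  graphs end in N_f, correlation values for particular graphs) are out
  of scope: labels here are synthetic stand-ins.
- Descriptor cells whose exact computation exceeds the exhaustive
  bound are missing by contract; no approximate fallback is provided.
- The q/r membership-consistency rules in the one-class loop are a
  package design choice among several defensible readings of
  "not correctly classified"; alternatives tried (judging by the
  iteration's own scorer; cross-fitted half-scorers; purely Euclidean
  distance gates) either made the step vacuous or behaved poorly on
  the synthetic benchmarks, and are documented here for
  reproducibility.
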