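# rnadual

Dual multigraph models of RNA secondary structure: exhaustive
enumeration of the possible topologies, loop-aware topological
descriptors, and one-class screening of which topologies look RNA-like.

## The problem

An RNA secondary structure can be coarse-grained as a **dual graph**:
each stem (helix of base pairs) becomes a vertex and each
single-stranded motif — hairpin loop, bulge, internal loop, junction —
becomes an edge joining the stems it connects.  A motif can connect a
stem to itself (a loop) or connect the same two stems more than once
(parallel edges), so dual graphs are multigraphs; unlike the tree
model, they can also represent pseudoknots.  Because a stem meets at
most two strands on each side, every vertex has degree ≤ 4; in fact a
dual graph of order *n* has exactly 2*n* − 1 edges and degree sequence
(4, …, 4, 2) or (4, …, 4, 3, 3), and it is connected (one molecule).

Only a small number of topologies are *verified* — observed in a real
RNA molecule.  The scientific question this package addresses is: of
all combinatorially possible topologies, which ones have the
topological character of RNA?  Since there are essentially no verified
non-RNA examples, this is a **one-class classification** (data domain
description) problem over vectors of graph descriptors.

## What the package computes

- **Enumeration** (`rnadual.enumeration`): every dual graph of order
  2–6 up to isomorphism, by recursive edge addition with degree-cap
  pruning and exhaustive-permutation canonical keys.  Counts: 3, 8, 30
  and 118 at orders 2, 3, 4, 5.
- **Line graphs** (`rnadual.linegraph`): the simple line graph of each
  multigraph (one vertex per edge; adjacency = incidence, with a loop
  incident to every other edge at its vertex), which makes the
  classical simple-graph invariants applicable.
- **Distances** (`rnadual.distances`): four distance-matrix conventions
  for loops — standard, loop-marked diagonal, forced loop traversal,
  and a random-walk-motivated weighted traversal in exact rational
  arithmetic (a loop at *u* plus a double edge *u–v* gives four
  traversal options of weight 1/4 and distance 1/2).
- **Descriptors** (`rnadual.descriptors`): Balaban's
  J = (m/(μ+1)) · Σ₍ᵤᵥ₎∈E (sᵤ sᵥ)^(−1/2) under each distance
  convention, Wiener, Randić and Platt indices, Laplacian spectra, and
  exact (exhaustive-search) line-graph invariants: clique,
  independence and domination numbers, diameter, maximum degree,
  chromatic number and index, circular chromatic number — a registry
  of 34 named descriptors.
- **Normalization & screening** (`rnadual.features`):
  Iₙₒᵣₘ = (Iₒᵦₛ − mean_ref)/stdev_ref against the verified reference
  class; 10–90 percentile-band discriminability screening; per-
  descriptor ROC AUC.
- **One-class toolbox** (`rnadual.oneclass`): nearest-neighbor
  ranking, average-linkage/PAM clustering, leave-one-as-negative
  screening, and the iterative cognitive one-class algorithm that
  grows the positive class P from the verified seed, using synthetic
  "large-σ" negatives and ROC-band thresholds, until the unclassified
  pool S is absorbed or a stable negative class N_f emerges.

Verified/unclassified labels live in external curated databases and
are not redistributed; `rnadual.fixtures` generates clearly flagged
synthetic stand-ins so the full pipeline runs end to end.

## Worked example

```python
from rnadual import (enumerate_dual_graphs, compute_feature_table,
                     normalize, FeatureMatrix, cognitive_one_class, nn_rank)
from rnadual.fixtures import make_label_fixture

catalog = enumerate_dual_graphs(4)
print(len(catalog))                    # 30 topologies of order 4
fm = compute_feature_table(catalog)    # 30 x 34 descriptor table
complete = [c for c in fm.values.columns if not fm.missing[c].any()]
labels = make_label_fixture(catalog, 17, seed=1)   # synthetic "verified" split
verified = tuple(labels.index[labels == "verified"])
normed, stats = normalize(FeatureMatrix(values=fm.values[complete],
                                        reference_ids=verified))
print(nn_rank(normed, list(verified)).head(3))
sets = cognitive_one_class(normed, list(verified), seed=1)
print(len(sets.P), sets.N_f)
```

prints

```
30
D4.22    1.883648
D4.25    2.355774
D4.9     2.717602
30 []
```

— all 30 order-4 topologies, a 30 × 34 feature table, the three
unclassified graphs nearest the (synthetic) verified class in
normalized descriptor space, and a one-class run that absorbs every
candidate into P with an empty final negative set: under this labeling
every topology looks like the reference class.  The same pipeline at
order 5 (118 topologies, 18 verified) behaves the same way.

A command-line interface mirrors the library:

```
rnadual enumerate --order 5 --out catalog.json     # "118 dual graphs of order 5"
rnadual run --order 4 --seed 1 --outdir out/       # full pipeline bundle
```

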