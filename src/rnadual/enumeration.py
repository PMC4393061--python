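"""Exhaustive enumeration of RNA dual graphs of a given order.

A dual graph of order ``n`` models an RNA secondary structure with
``n`` stems.  Because a double-stranded stem can meet at most two
strands on each side, each vertex has degree at most four, and the
complete constraint system is:

* exactly ``2n - 1`` edges;
* degree sequence ``(4, ..., 4, 2)`` or ``(4, ..., 4, 3, 3)``;
* connected (a dual graph represents a single molecule, its stems
  joined by strands).

Enumeration proceeds by recursive multiplicity assignment over the
labeled edge slots (all vertex pairs plus loops) with degree-cap
pruning, followed by degree-sequence and connectivity filters and
canonical-key deduplication.  At the orders in scope this is exhaustive
by construction and takes seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

from .multigraph import CanonicalKey, Multigraph, are_isomorphic, canonical_key

__all__ = [
    "DualGraphCatalog",
    "valid_degree_sequences",
    "is_dual_graph",
    "enumerate_dual_graphs",
    "enumerate_dual_graphs_bruteforce",
    "MIN_ORDER",
    "MAX_ORDER",
]

MIN_ORDER = 2
MAX_ORDER = 6


@dataclass(frozen=True)
class DualGraphCatalog:
    """One representative per isomorphism class of dual graphs of an order.

    Entries are sorted by canonical key and assigned ids ``Dn.1``,
    ``Dn.2``, ... .  This numbering is internal to the package; a
    mapping onto external database identifiers can be supplied by users
    who have one (see :meth:`with_id_mapping`).
    """

    order: int
    graphs: list[Multigraph]
    keys: list[CanonicalKey]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.ids:
            object.__setattr__(
                self, "ids", [f"D{self.order}.{i + 1}" for i in range(len(self.graphs))]
            )

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self):
        return iter(zip(self.ids, self.graphs))

    def with_id_mapping(self, mapping: dict[str, str]) -> "DualGraphCatalog":
        """Relabel catalog ids through *mapping* (e.g. external database ids)."""
        return DualGraphCatalog(
            order=self.order,
            graphs=list(self.graphs),
            keys=list(self.keys),
            ids=[mapping.get(i, i) for i in self.ids],
        )


def valid_degree_sequences(n: int) -> set[tuple[int, ...]]:
    """The two admissible degree sequences at order ``n``.

    All vertices have degree 4 except either one of degree 2 or two of
    degree 3; both sequences sum to ``4n - 2 = 2(2n - 1)``, consistent
    with the edge count.
    """
    if n < 2:
        raise ValueError(f"dual graphs need order >= 2 (stems joined by strands); got {n}")
    return {
        (4,) * (n - 1) + (2,),
        (4,) * (n - 2) + (3, 3),
    }


def is_dual_graph(g: Multigraph) -> bool:
    """True iff *g* satisfies all dual-graph constraints at its order."""
    n = g.order
    if n < 2:
        return False
    if g.size != 2 * n - 1:
        return False
    if g.degree_sequence() not in valid_degree_sequences(n):
        return False
    return g.is_connected()


def _edge_slots(n: int) -> list[tuple[int, int]]:
    """All unordered vertex pairs on 0..n-1, loops included, sorted."""
    return [(i, j) for i in range(n) for j in range(i, n)]


def enumerate_dual_graphs(n: int) -> DualGraphCatalog:
    """All dual graphs of order ``n`` up to isomorphism.

    Recursive edge addition over labeled vertices with a per-vertex
    degree cap of 4 and target size ``2n - 1``; candidates passing the
    degree-sequence and connectivity filters are deduplicated by
    canonical key and sorted.
    """
    if not (MIN_ORDER <= n <= MAX_ORDER):
        raise ValueError(
            f"enumeration is exhaustive only for {MIN_ORDER} <= n <= {MAX_ORDER}; got {n}"
        )
    target_size = 2 * n - 1
    slots = _edge_slots(n)
    sequences = valid_degree_sequences(n)

    found: dict[CanonicalKey, Multigraph] = {}
    degrees = [0] * n
    chosen: list[tuple[int, int]] = []

    def recurse(slot_idx: int, remaining: int) -> None:
        if remaining == 0:
            g = Multigraph(range(n), chosen)
            if tuple(sorted(degrees, reverse=True)) in sequences and g.is_connected():
                key = canonical_key(g)
                if key not in found:
                    found[key] = g
            return
        if slot_idx >= len(slots):
            return
        u, v = slots[slot_idx]
        inc = 2 if u == v else 1
        # max copies of this slot allowed by the degree caps
        if u == v:
            cap = (4 - degrees[u]) // 2
        else:
            cap = min(4 - degrees[u], 4 - degrees[v])
        cap = min(cap, remaining)
        for mult in range(cap + 1):
            if mult:
                degrees[u] += inc
                if u != v:
                    degrees[v] += 1
                chosen.append((u, v))
            recurse(slot_idx + 1, remaining - mult)
        # unwind
        while chosen and chosen[-1] == (u, v):
            chosen.pop()
            degrees[u] -= inc
            if u != v:
                degrees[v] -= 1

    recurse(0, target_size)

    keys = sorted(found)
    graphs = [found[k] for k in keys]
    return DualGraphCatalog(order=n, graphs=graphs, keys=keys)


def enumerate_dual_graphs_bruteforce(n: int) -> list[Multigraph]:
    """Independent oracle: labeled generation plus pairwise isomorphism.

    Generates every multiset of ``2n - 1`` edge slots outright (no
    degree pruning), filters by :func:`is_dual_graph`, and deduplicates
    by pairwise :func:`are_isomorphic` — no canonical keys involved.
    Practical only for small ``n``; used to cross-check the main
    generator.
    """
    if n < 2:
        raise ValueError("order must be >= 2")
    slots = _edge_slots(n)
    reps: list[Multigraph] = []
    for combo in combinations_with_replacement(slots, 2 * n - 1):
        g = Multigraph(range(n), combo)
        if not is_dual_graph(g):
            continue
        if not any(are_isomorphic(g, r) for r in reps):
            reps.append(g)
    return reps
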