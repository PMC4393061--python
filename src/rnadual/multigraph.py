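"""Multigraphs with loops and parallel edges.

The dual-graph model of RNA secondary structure maps each stem (a helix
of two or more base pairs) to a vertex and each single-stranded motif
(hairpin loop, bulge, internal loop, junction) to an edge joining the
stems it connects.  A motif may join a stem to itself (a loop) or join
the same pair of stems more than once (parallel edges), so the natural
container is a multigraph.

The class here is a small immutable value type: vertices plus a sorted
edge multiset.  A loop at ``v`` is stored as the pair ``(v, v)`` and
contributes 2 to the degree of ``v`` — the convention under which the
degree constraints of the dual-graph model reproduce the known catalog
counts.  Isomorphism is decided by exhaustive permutation
canonicalization, which is exact and fast at the orders this package
targets (well below 8 vertices).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Hashable, Iterable

import networkx as nx

__all__ = [
    "Multigraph",
    "CanonicalKey",
    "canonical_key",
    "are_isomorphic",
    "MAX_CANONICAL_ORDER",
]

#: Largest order for which exhaustive permutation canonicalization is allowed.
MAX_CANONICAL_ORDER = 8

Vertex = Hashable
Edge = tuple[Vertex, Vertex]


def _norm_edge(u: Vertex, v: Vertex) -> Edge:
    """Store each edge as a sorted pair; loops as (v, v)."""
    return (u, v) if _key(u) <= _key(v) else (v, u)


def _key(x: Vertex):
    # Total order across mixed label types: sort by (type name, value).
    return (type(x).__name__, x)


@dataclass(frozen=True)
class CanonicalKey:
    """Total-order-comparable encoding of a multigraph isomorphism class.

    The key is the lexicographic minimum, over all relabelings of the
    vertices onto ``0..n-1``, of the sorted edge multiset.  Two
    multigraphs of the same order have equal keys iff they are
    isomorphic.
    """

    order: int
    edges: tuple[tuple[int, int], ...]

    def __lt__(self, other: "CanonicalKey") -> bool:
        return (self.order, self.edges) < (other.order, other.edges)

    def __str__(self) -> str:
        return f"{self.order}:" + ",".join(f"{u}-{v}" for u, v in self.edges)

    @classmethod
    def parse(cls, text: str) -> "CanonicalKey":
        head, _, body = text.partition(":")
        edges = []
        if body:
            for part in body.split(","):
                u, _, v = part.partition("-")
                edges.append((int(u), int(v)))
        return cls(order=int(head), edges=tuple(edges))


class Multigraph:
    """An undirected multigraph permitting loops and parallel edges.

    Parameters
    ----------
    vertices:
        Iterable of hashable vertex identifiers.  Order is normalized by
        sorting so that equal vertex/edge content compares equal.
    edges:
        Iterable of 2-tuples; ``(v, v)`` denotes a loop.  Repeated pairs
        are parallel edges.  Every endpoint must appear in *vertices*.
    """

    __slots__ = ("_vertices", "_edges")

    def __init__(self, vertices: Iterable[Vertex], edges: Iterable[Edge] = ()):
        vs = tuple(sorted(set(vertices), key=_key))
        vset = set(vs)
        es = []
        for e in edges:
            u, v = e
            if u not in vset or v not in vset:
                missing = u if u not in vset else v
                raise ValueError(f"edge endpoint {missing!r} is not a vertex")
            es.append(_norm_edge(u, v))
        object.__setattr__(self, "_vertices", vs)
        object.__setattr__(self, "_edges", tuple(sorted(es, key=lambda e: (_key(e[0]), _key(e[1])))))

    # -- basic accessors -------------------------------------------------

    @property
    def vertices(self) -> tuple[Vertex, ...]:
        return self._vertices

    @property
    def edges(self) -> tuple[Edge, ...]:
        """The edge multiset, each edge a sorted pair, sorted overall."""
        return self._edges

    @property
    def order(self) -> int:
        return len(self._vertices)

    @property
    def size(self) -> int:
        """Number of edges; a loop counts once."""
        return len(self._edges)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Multigraph):
            return NotImplemented
        return self._vertices == other._vertices and self._edges == other._edges

    def __hash__(self) -> int:
        return hash((self._vertices, self._edges))

    def __repr__(self) -> str:
        return f"Multigraph(vertices={list(self._vertices)!r}, edges={list(self._edges)!r})"

    # -- degrees ---------------------------------------------------------

    def degree(self, v: Vertex) -> int:
        """Degree of ``v``: non-loop incidences plus 2 per loop at ``v``."""
        if v not in self._vertices:
            raise KeyError(f"unknown vertex {v!r}")
        d = 0
        for a, b in self._edges:
            if a == v and b == v:
                d += 2
            elif a == v or b == v:
                d += 1
        return d

    def degree_sequence(self) -> tuple[int, ...]:
        """All vertex degrees, sorted non-increasing."""
        return tuple(sorted((self.degree(v) for v in self._vertices), reverse=True))

    def loops_at(self, v: Vertex) -> int:
        """Number of loops attached to ``v``."""
        if v not in self._vertices:
            raise KeyError(f"unknown vertex {v!r}")
        return sum(1 for a, b in self._edges if a == v and b == v)

    def has_loop(self, v: Vertex) -> bool:
        return self.loops_at(v) > 0

    def multiplicity(self, u: Vertex, v: Vertex) -> int:
        """Number of parallel edges between ``u`` and ``v`` (loops if u == v)."""
        e = _norm_edge(u, v)
        return sum(1 for f in self._edges if f == e)

    def neighbors(self, v: Vertex) -> tuple[Vertex, ...]:
        """Distinct neighbors of ``v`` excluding ``v`` itself."""
        out = set()
        for a, b in self._edges:
            if a == v and b != v:
                out.add(b)
            elif b == v and a != v:
                out.add(a)
        return tuple(sorted(out, key=_key))

    # -- connectivity ----------------------------------------------------

    def is_connected(self) -> bool:
        """True iff a single component, ignoring loops for reachability."""
        if not self._vertices:
            raise ValueError("connectivity is undefined for an empty vertex set")
        seen = {self._vertices[0]}
        frontier = [self._vertices[0]]
        while frontier:
            v = frontier.pop()
            for w in self.neighbors(v):
                if w not in seen:
                    seen.add(w)
                    frontier.append(w)
        return len(seen) == len(self._vertices)

    # -- relabeling and isomorphism --------------------------------------

    def relabel(self, mapping: dict) -> "Multigraph":
        """Return the graph with every vertex renamed through *mapping*."""
        return Multigraph(
            (mapping[v] for v in self._vertices),
            ((mapping[u], mapping[v]) for u, v in self._edges),
        )

    def canonical_key(self) -> CanonicalKey:
        return canonical_key(self)

    # -- conversion ------------------------------------------------------

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self._vertices)
        g.add_edges_from(self._edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Multigraph":
        return cls(g.nodes(), ((u, v) for u, v, _ in g.edges(keys=True))
                   if g.is_multigraph() else g.edges())

    def simple_support(self) -> nx.Graph:
        """Underlying simple graph: parallels collapsed, loops dropped."""
        g = nx.Graph()
        g.add_nodes_from(self._vertices)
        g.add_edges_from((u, v) for u, v in self._edges if u != v)
        return g


def canonical_key(g: Multigraph) -> CanonicalKey:
    """Canonical key by exhaustive minimization over vertex relabelings.

    Exact for any order up to :data:`MAX_CANONICAL_ORDER`; beyond that the
    factorial search is refused rather than silently degraded.
    """
    n = g.order
    if n > MAX_CANONICAL_ORDER:
        raise ValueError(
            f"canonical_key is exhaustive and limited to order <= {MAX_CANONICAL_ORDER}; got {n}"
        )
    verts = g.vertices
    # Group candidate images by (degree, loop count) to prune the search:
    # only degree/loop-preserving relabelings can achieve the minimum.
    sig = {v: (g.degree(v), g.loops_at(v)) for v in verts}
    best: tuple[tuple[int, int], ...] | None = None
    index_pool = range(n)
    for perm in itertools.permutations(index_pool):
        lab = {verts[i]: perm[i] for i in index_pool}
        relabeled = tuple(sorted(
            (min(lab[u], lab[v]), max(lab[u], lab[v])) for u, v in g.edges
        ))
        if best is None or relabeled < best:
            best = relabeled
    _ = sig  # signature retained for clarity; pruning not needed at n <= 8
    return CanonicalKey(order=n, edges=best if best is not None else ())


def are_isomorphic(g1: Multigraph, g2: Multigraph) -> bool:
    """Decide isomorphism by direct bijection search.

    Independent of :func:`canonical_key` (no canonical forms are
    compared); used both as API and as the cross-check the key must
    agree with.
    """
    if g1.order != g2.order or g1.size != g2.size:
        return False
    if g1.degree_sequence() != g2.degree_sequence():
        return False
    v1, v2 = g1.vertices, g2.vertices
    target = g2.edges
    for perm in itertools.permutations(v2):
        lab = dict(zip(v1, perm))
        mapped = tuple(sorted(
            (_norm_edge(lab[u], lab[v]) for u, v in g1.edges),
            key=lambda e: (_key(e[0]), _key(e[1])),
        ))
        if mapped == target:
            return True
    return False
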