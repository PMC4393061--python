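"""Distance matrices of dual multigraphs under loop-aware conventions.

In a simple graph the distance from a vertex to itself is zero and a
shortest path never revisits structure, but a loop in a dual graph is a
real strand of unpaired bases: a traversal that reaches a looped stem
can be required to traverse the loop.  Four conventions are provided:

``STANDARD``
    Unit edge lengths, loops ignored, zero diagonal.
``LOOP_DIAGONAL``
    As ``STANDARD`` off-diagonal; the diagonal entry is 1 at a vertex
    carrying a loop, else 0.
``LOOP_TRAVERSAL``
    Diagonal as ``LOOP_DIAGONAL``; the length of a path additionally
    counts 1 for each loop-bearing vertex it meets (any traversal must
    include a loop when encountered), and the distance minimizes this
    inflated cost over all simple paths.
``WEIGHTED_TRAVERSAL``
    A random-walk-motivated weighting.  For adjacent ``u, v``, the
    one-hop traversal options from ``u`` are each parallel edge,
    optionally preceded by one traversal of a loop at ``u``; all
    options get equal weight, and the distance is the total weight of
    the minimal-length options.  With one loop at ``u`` and a double
    edge there are four options of weight 1/4 and the two direct ones
    are shortest, giving 1/2.  Multi-hop distances minimize the sum of
    one-hop values over simple paths.

Weighted values are exact :class:`fractions.Fraction` numbers so that
1/4 and 1/2 are represented without rounding.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .multigraph import Multigraph, Vertex

__all__ = [
    "Convention",
    "DistanceMatrix",
    "distance_matrix",
    "weighted_traversal_distance",
    "distance_sums",
]


class Convention(enum.Enum):
    STANDARD = "standard"
    LOOP_DIAGONAL = "loopdiag"
    LOOP_TRAVERSAL = "looptrav"
    WEIGHTED_TRAVERSAL = "weighted"


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric vertex-by-vertex distance matrix under one convention."""

    convention: Convention
    vertices: tuple[Vertex, ...]
    values: np.ndarray  # object array of Fractions/ints, shape (n, n)

    def __getitem__(self, pair: tuple[Vertex, Vertex]):
        i = self.vertices.index(pair[0])
        j = self.vertices.index(pair[1])
        return self.values[i, j]

    def as_float(self) -> np.ndarray:
        return self.values.astype(float)


def _simple_paths(g: Multigraph, u: Vertex, v: Vertex):
    """All vertex-simple paths from u to v as vertex tuples (u == v -> (u,))."""
    if u == v:
        yield (u,)
        return
    stack = [(u, (u,))]
    while stack:
        node, path = stack.pop()
        for w in g.neighbors(node):
            if w == v:
                yield path + (w,)
            elif w not in path:
                stack.append((w, path + (w,)))


def _loop_traversal_cost(g: Multigraph, path: tuple, count_endpoints: bool) -> int:
    edges = len(path) - 1
    verts = path if count_endpoints else path[1:-1]
    return edges + sum(1 for w in verts if g.has_loop(w))


def weighted_traversal_distance(g: Multigraph, u: Vertex, v: Vertex) -> Fraction:
    """One-hop weighted traversal distance between adjacent vertices.

    Options from ``u`` to ``v``: each of the ``k`` parallel edges,
    each optionally preceded by one traversal of a loop at ``u`` (one
    option per loop).  Every option has equal weight ``1 / (k(1 + l))``
    with ``l`` loops at ``u``; the returned value is the total weight
    of the minimal-length options, i.e. ``1 / (1 + l)``.
    """
    k = g.multiplicity(u, v) if u != v else 0
    if k == 0:
        raise ValueError(
            f"{u!r} and {v!r} are not adjacent; use distance_matrix for multi-hop distances"
        )
    loops = g.loops_at(u)
    n_options = k * (1 + loops)  # direct edges, plus loop-then-edge combinations
    weight = Fraction(1, n_options)
    n_minimal = k  # the direct single-edge traversals are always shortest
    return weight * n_minimal


def _weighted_path_cost(g: Multigraph, path: tuple) -> Fraction:
    return sum(
        (weighted_traversal_distance(g, a, b) for a, b in zip(path, path[1:])),
        Fraction(0),
    )


def distance_matrix(
    g: Multigraph,
    convention: Convention = Convention.STANDARD,
    *,
    count_endpoint_loops: bool = True,
) -> DistanceMatrix:
    """Pairwise distances of a connected multigraph under a convention.

    ``count_endpoint_loops`` applies to ``LOOP_TRAVERSAL`` only: whether
    a loop at either endpoint of a path inflates its cost, in addition
    to loops at interior vertices (default) — the convention is stated
    for traversals generally, so endpoints are included unless turned
    off.

    ``WEIGHTED_TRAVERSAL`` one-hop values depend on the loops at the
    traversal's source, so the two orientations of a path can differ;
    the matrix entry takes the cheaper orientation, keeping the matrix
    symmetric.
    """
    if not g.is_connected():
        raise ValueError("distance matrix requires a connected multigraph")
    verts = g.vertices
    n = len(verts)
    dm = np.empty((n, n), dtype=object)

    loop_diag = convention in (
        Convention.LOOP_DIAGONAL,
        Convention.LOOP_TRAVERSAL,
        Convention.WEIGHTED_TRAVERSAL,
    )
    for i, v in enumerate(verts):
        dm[i, i] = Fraction(1) if (loop_diag and g.has_loop(v)) else Fraction(0)

    for i, j in itertools.combinations(range(n), 2):
        u, v = verts[i], verts[j]
        if convention in (Convention.STANDARD, Convention.LOOP_DIAGONAL):
            d = Fraction(min(len(p) - 1 for p in _simple_paths(g, u, v)))
        elif convention is Convention.LOOP_TRAVERSAL:
            d = Fraction(min(
                _loop_traversal_cost(g, p, count_endpoint_loops)
                for p in _simple_paths(g, u, v)
            ))
        else:  # WEIGHTED_TRAVERSAL
            forward = min(_weighted_path_cost(g, p) for p in _simple_paths(g, u, v))
            backward = min(_weighted_path_cost(g, p) for p in _simple_paths(g, v, u))
            d = min(forward, backward)
        dm[i, j] = dm[j, i] = d

    return DistanceMatrix(convention=convention, vertices=verts, values=dm)


def distance_sums(dm: DistanceMatrix) -> np.ndarray:
    """Row sums s_i = sum_j d(i, j), diagonal included (Balaban's s_i)."""
    return dm.values.sum(axis=1)
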