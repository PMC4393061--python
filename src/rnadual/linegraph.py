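"""Line graphs of multigraphs.

Most classical graph descriptors are defined for simple graphs only.
The line graph — one vertex per edge of the source graph, adjacency
when the source edges are incident — converts a dual multigraph into a
simple graph while retaining the loop and parallel-edge structure as
adjacency patterns, which is what makes the simple-graph invariant
toolbox applicable to RNA dual graphs.  In the RNA reading, line-graph
vertices correspond to the unpaired-base motifs of the molecule.

Conventions:

* every edge of the source, including each parallel copy and each loop,
  becomes its own line-graph vertex;
* two line-graph vertices are adjacent iff the source edges share at
  least one endpoint — a loop at ``v`` occupies ``v`` and is therefore
  adjacent to every other edge touching ``v``;
* the result is simple: a loop is not adjacent to itself, and parallel
  edges (which share both endpoints) produce a single adjacency.

Line-graph vertices are labeled ``(u, v, k)`` with ``k`` the parallel
index, so each vertex traces back to its originating edge.
"""

from __future__ import annotations

import networkx as nx

from .enumeration import DualGraphCatalog
from .multigraph import Multigraph

__all__ = ["line_graph_of_multigraph", "line_graph_catalog"]


def line_graph_of_multigraph(g: Multigraph) -> nx.Graph:
    """The (simple) line graph of a multigraph with loops and parallels."""
    labeled = []
    counts: dict[tuple, int] = {}
    for u, v in g.edges:
        k = counts.get((u, v), 0)
        counts[(u, v)] = k + 1
        labeled.append((u, v, k))
    lg = nx.Graph()
    lg.add_nodes_from(labeled)
    for i, e in enumerate(labeled):
        eu, ev = e[0], e[1]
        for f in labeled[i + 1:]:
            fu, fv = f[0], f[1]
            if eu == fu or eu == fv or ev == fu or ev == fv:
                lg.add_edge(e, f)
    return lg


def line_graph_catalog(catalog: DualGraphCatalog) -> list[nx.Graph]:
    """Line graphs of every catalog member, in catalog order.

    Each output has ``2n - 1`` vertices, the size of the source dual
    graph.
    """
    return [line_graph_of_multigraph(g) for g in catalog.graphs]
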