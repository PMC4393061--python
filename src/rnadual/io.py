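"""Reading and writing multigraphs and catalogs.

Three interchange formats are supported:

* a plain-text edge list — one edge per line, ``u v``, loops written as
  ``u u``, ``#`` starting a comment line;
* GraphML via :mod:`networkx` (parallel edges become distinct ``<edge>``
  elements, loops self-edges);
* a JSON catalog schema ``{order, count, graphs: [{id, edges,
  degree_sequence, canonical_key}]}``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING, Union

import networkx as nx

from .multigraph import Multigraph

if TYPE_CHECKING:  # pragma: no cover
    from .enumeration import DualGraphCatalog

PathLike = Union[str, Path]


# -- edge-list dialect ---------------------------------------------------

def write_edgelist(g: Multigraph, path: PathLike) -> None:
    lines = [f"# vertices: {' '.join(str(v) for v in g.vertices)}"]
    lines += [f"{u} {v}" for u, v in g.edges]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edgelist(path: PathLike) -> Multigraph:
    """Parse the edge-list dialect; malformed lines raise with their number."""
    vertices: list[str] = []
    edges: list[tuple[str, str]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if line.startswith("# vertices:"):
            vertices = line.removeprefix("# vertices:").split()
            continue
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'u v', got {raw!r}")
        edges.append((parts[0], parts[1]))
    seen = dict.fromkeys(vertices)
    for u, v in edges:
        seen.setdefault(u)
        seen.setdefault(v)
    return Multigraph(seen, edges)


# -- GraphML -------------------------------------------------------------

def write_graphml(g: Multigraph, path: PathLike) -> None:
    nx.write_graphml(g.to_networkx(), str(path))


def read_graphml(path: PathLike) -> Multigraph:
    return Multigraph.from_networkx(nx.read_graphml(str(path), force_multigraph=True))


# -- JSON catalog --------------------------------------------------------

def catalog_to_dict(catalog: "DualGraphCatalog") -> dict:
    return {
        "order": catalog.order,
        "count": len(catalog.graphs),
        "graphs": [
            {
                "id": gid,
                "edges": [[u, v] for u, v in g.edges],
                "degree_sequence": list(g.degree_sequence()),
                "canonical_key": str(key),
            }
            for gid, g, key in zip(catalog.ids, catalog.graphs, catalog.keys)
        ],
    }


def write_catalog(catalog: "DualGraphCatalog", path: PathLike) -> None:
    Path(path).write_text(json.dumps(catalog_to_dict(catalog), indent=1) + "\n")


def read_catalog(path: PathLike) -> "DualGraphCatalog":
    from .enumeration import DualGraphCatalog
    from .multigraph import CanonicalKey

    data = json.loads(Path(path).read_text())
    graphs, keys, ids = [], [], []
    for entry in data["graphs"]:
        edges = [tuple(e) for e in entry["edges"]]
        verts = sorted({v for e in edges for v in e})
        graphs.append(Multigraph(verts, edges))
        keys.append(CanonicalKey.parse(entry["canonical_key"]))
        ids.append(entry["id"])
    return DualGraphCatalog(order=data["order"], graphs=graphs, keys=keys, ids=ids)
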