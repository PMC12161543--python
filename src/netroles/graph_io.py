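"""Plain-text I/O for directed networks and node-role reports.

Networks are exchanged as edge lists: one ``source target`` pair per line,
whitespace- or character-delimited, ``#`` comments ignored.  Node labels are
opaque strings and are never coerced to numbers; internal integer indices are
assigned by first appearance and used only inside the algorithms.

A single-field line declares an isolated node, which lets a graph with
isolated nodes survive a write/read round trip.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable
from pathlib import Path
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .roles import RoleAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "DirectedGraph",
    "EdgeListParseError",
    "read_edge_list",
    "write_edge_list",
    "write_role_report",
    "summary_dict",
]


class EdgeListParseError(ValueError):
    """Raised for a malformed edge-list line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class DirectedGraph:
    """A simple directed graph: ordered node labels plus a set of edges.

    Duplicate edges collapse silently (only the zero/nonzero structure of the
    adjacency matrix matters); the number collapsed is logged.  Self-loops are
    legal and preserved.

    Parameters
    ----------
    edges:
        Iterable of ``(source, target)`` label pairs.
    nodes:
        Optional labels declared up front (e.g. isolated nodes).  Endpoints
        of ``edges`` are appended in first-appearance order.
    """

    __slots__ = ("_nodes", "_edges", "_index")

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
    ):
        order: dict[str, int] = {}
        for v in nodes:
            order.setdefault(v, len(order))
        edge_set: set[tuple[str, str]] = set()
        n_dup = 0
        for u, v in edges:
            order.setdefault(u, len(order))
            order.setdefault(v, len(order))
            if (u, v) in edge_set:
                n_dup += 1
            else:
                edge_set.add((u, v))
        if n_dup:
            logger.info("collapsed %d duplicate edge(s)", n_dup)
        self._nodes: tuple[str, ...] = tuple(order)
        self._index: dict[str, int] = order
        # deterministic iteration order for downstream algorithms
        self._edges: tuple[tuple[str, str], ...] = tuple(
            sorted(edge_set, key=lambda e: (order[e[0]], order[e[1]]))
        )

    # -- basic accessors ----------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return self._edges

    @property
    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._edges)

    @property
    def N(self) -> int:
        return len(self._nodes)

    @property
    def M(self) -> int:
        return len(self._edges)

    def index(self, label: str) -> int:
        return self._index[label]

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return edge in self.edge_set

    def __eq__(self, other) -> bool:
        if not isinstance(other, DirectedGraph):
            return NotImplemented
        return self._nodes == other._nodes and set(self._edges) == set(other._edges)

    def __hash__(self):  # pragma: no cover - rarely used
        return hash((self._nodes, frozenset(self._edges)))

    def __repr__(self) -> str:
        return f"DirectedGraph(N={self.N}, M={self.M})"

    # -- derived quantities -------------------------------------------------

    def out_degrees(self) -> dict[str, int]:
        d = {v: 0 for v in self._nodes}
        for u, _ in self._edges:
            d[u] += 1
        return d

    def in_degrees(self) -> dict[str, int]:
        d = {v: 0 for v in self._nodes}
        for _, v in self._edges:
            d[v] += 1
        return d

    def reverse(self) -> "DirectedGraph":
        """The dual graph with every edge direction flipped."""
        return DirectedGraph(((v, u) for u, v in self._edges), nodes=self._nodes)


def read_edge_list(
    path: str | Path,
    delimiter: str | None = None,
    comment_prefix: str = "#",
    strict: bool = False,
) -> DirectedGraph:
    """Parse a plain-text edge list into a :class:`DirectedGraph`.

    Parameters
    ----------
    path:
        File to read.  An empty file yields an empty graph.
    delimiter:
        Field separator; ``None`` splits on any whitespace run.
    comment_prefix:
        Lines starting with this prefix are skipped (after stripping).
    strict:
        When true, a single-field line raises :class:`EdgeListParseError`
        instead of declaring an isolated node.

    Notes
    -----
    Fields beyond the first two (e.g. weights) are ignored.  Duplicate edge
    lines collapse to a single edge.
    """
    path = Path(path)
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or (comment_prefix and line.startswith(comment_prefix)):
                continue
            fields = line.split(delimiter)
            fields = [f for f in fields if f != ""]
            if len(fields) >= 2:
                edges.append((fields[0], fields[1]))
            elif len(fields) == 1:
                if strict:
                    raise EdgeListParseError(
                        f"expected two fields, got {line!r}", lineno
                    )
                nodes.append(fields[0])
            else:  # pragma: no cover - blank handled above
                raise EdgeListParseError("empty line", lineno)
    return DirectedGraph(edges, nodes=nodes)


def write_edge_list(graph: DirectedGraph, path: str | Path, delimiter: str = "\t") -> None:
    """Write a graph as an edge list; isolated nodes become single-field lines."""
    path = Path(path)
    non_isolated = {u for u, _ in graph.edges} | {v for _, v in graph.edges}
    with path.open("w", encoding="utf-8") as fh:
        for u, v in graph.edges:
            fh.write(f"{u}{delimiter}{v}\n")
        for v in graph.nodes:
            if v not in non_isolated:
                fh.write(f"{v}\n")


def summary_dict(graph: DirectedGraph, roles: "RoleAssignment") -> dict:
    """JSON-ready counts: N, M and the four category tallies."""
    counts = roles.category_counts()
    return {
        "N": graph.N,
        "M": graph.M,
        "n_D": counts["driver"],
        "n_S": counts["sensor"],
        "n_DS": counts["ds"],
        "n_O": counts["ordinary"],
    }


def write_role_report(
    graph: DirectedGraph,
    roles: "RoleAssignment",
    path: str | Path,
    summary_path: str | Path | None = None,
) -> None:
    """Write a per-node TSV role report plus a JSON count summary.

    Columns: ``node, in_degree, out_degree, is_driver, is_sensor, category``
    where category is ``ds`` when both flags hold, ``driver``/``sensor`` for
    an exclusive flag, and ``ordinary`` for neither.  The counts are appended
    as ``#`` footer lines and, if ``summary_path`` is given, written as JSON.
    """
    if set(roles.nodes) != set(graph.nodes):
        raise ValueError("role assignment does not cover the graph's node set")
    path = Path(path)
    kin = graph.in_degrees()
    kout = graph.out_degrees()
    with path.open("w", encoding="utf-8") as fh:
        fh.write("node\tin_degree\tout_degree\tis_driver\tis_sensor\tcategory\n")
        for v in graph.nodes:
            fh.write(
                f"{v}\t{kin[v]}\t{kout[v]}\t"
                f"{int(roles.is_driver[v])}\t{int(roles.is_sensor[v])}\t"
                f"{roles.category(v)}\n"
            )
        summary = summary_dict(graph, roles)
        for key in ("n_D", "n_S", "n_DS", "n_O"):
            fh.write(f"# {key}={summary[key]}\n")
    if summary_path is not None:
        Path(summary_path).write_text(
            json.dumps(summary, indent=2) + "\n", encoding="utf-8"
        )
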