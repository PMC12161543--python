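"""Per-category degree statistics.

For each node category (driver, sensor, ds, ordinary, plus the whole graph)
this reports the mean out-degree, mean in-degree, their sum (total degree)
and their difference.  Driver and sensor sets overlap on the dual-identity
nodes by default; ``exclusive=True`` removes the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph_io import DirectedGraph
from .roles import RoleAssignment

__all__ = ["CategoryStats", "category_degree_stats"]


@dataclass(frozen=True)
class CategoryStats:
    """Degree means over one category; means are None when the set is empty."""

    count: int
    mean_out: float | None
    mean_in: float | None

    @property
    def total(self) -> float | None:
        if self.count == 0:
            return None
        return self.mean_out + self.mean_in

    @property
    def diff(self) -> float | None:
        if self.count == 0:
            return None
        return self.mean_out - self.mean_in


def category_degree_stats(
    graph: DirectedGraph,
    roles: RoleAssignment,
    exclusive: bool = False,
) -> dict[str, CategoryStats]:
    """Mean in/out degree per category, keyed driver/sensor/ds/ordinary/all.

    With the default overlapping convention the driver set is every node
    flagged as driver (dual-identity nodes included) and likewise for
    sensors; ``exclusive=True`` restricts driver/sensor to nodes with exactly
    one flag.
    """
    kin = graph.in_degrees()
    kout = graph.out_degrees()
    members: dict[str, list[str]] = {
        "driver": [],
        "sensor": [],
        "ds": [],
        "ordinary": [],
        "all": list(graph.nodes),
    }
    for v in graph.nodes:
        d, s = roles.is_driver[v], roles.is_sensor[v]
        if d and s:
            members["ds"].append(v)
        if d and not (exclusive and s):
            members["driver"].append(v)
        if s and not (exclusive and d):
            members["sensor"].append(v)
        if not d and not s:
            members["ordinary"].append(v)

    out: dict[str, CategoryStats] = {}
    for cat, vs in members.items():
        if not vs:
            out[cat] = CategoryStats(count=0, mean_out=None, mean_in=None)
        else:
            out[cat] = CategoryStats(
                count=len(vs),
                mean_out=sum(kout[v] for v in vs) / len(vs),
                mean_in=sum(kin[v] for v in vs) / len(vs),
            )
    return out
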