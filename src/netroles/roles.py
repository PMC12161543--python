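"""Node-role classification from a maximum matching.

A node is a *driver* iff its right copy is unmatched, a *sensor* iff its left
copy is unmatched, a *dual-identity* (DS) node iff both, and *ordinary* iff
neither.  Driver and sensor counts are both ``N - |maximum matching|``, so
they agree on every graph.

When a perfect matching exists the literal classification flags no nodes at
all; `apply_min_one_convention` optionally promotes the first node to
driver-and-sensor for users who want the minimum-input count of one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np

from .graph_io import DirectedGraph
from .matching import Matching, build_bipartite, has_augmenting_path, hopcroft_karp

__all__ = [
    "RoleAssignment",
    "RoleFractions",
    "classify_nodes",
    "classify",
    "role_fractions",
    "apply_min_one_convention",
    "resample_fractions",
]

CATEGORIES = ("driver", "sensor", "ds", "ordinary")


@dataclass(frozen=True)
class RoleAssignment:
    """Per-node driver/sensor flags keyed by node label."""

    nodes: tuple[str, ...]
    is_driver: dict[str, bool]
    is_sensor: dict[str, bool]

    def category(self, v: str) -> str:
        d, s = self.is_driver[v], self.is_sensor[v]
        if d and s:
            return "ds"
        if d:
            return "driver"
        if s:
            return "sensor"
        return "ordinary"

    @property
    def drivers(self) -> frozenset[str]:
        return frozenset(v for v in self.nodes if self.is_driver[v])

    @property
    def sensors(self) -> frozenset[str]:
        return frozenset(v for v in self.nodes if self.is_sensor[v])

    @property
    def ds_nodes(self) -> frozenset[str]:
        return self.drivers & self.sensors

    @property
    def ordinary(self) -> frozenset[str]:
        return frozenset(
            v for v in self.nodes if not self.is_driver[v] and not self.is_sensor[v]
        )

    def category_counts(self) -> dict[str, int]:
        """Overlapping driver/sensor counts plus ds and ordinary."""
        return {
            "driver": len(self.drivers),
            "sensor": len(self.sensors),
            "ds": len(self.ds_nodes),
            "ordinary": len(self.ordinary),
        }


@dataclass(frozen=True)
class RoleFractions:
    """Category proportions; driver/sensor overlap, so n_D + n_S - n_DS + n_O = 1."""

    n_D: float
    n_S: float
    n_DS: float
    n_O: float

    @property
    def n_D_only(self) -> float:
        return self.n_D - self.n_DS

    @property
    def n_S_only(self) -> float:
        return self.n_S - self.n_DS


def classify_nodes(
    graph: DirectedGraph, matching: Matching, verify: bool = True
) -> RoleAssignment:
    """Flag each node driver/sensor from the unmatched copies of ``matching``.

    ``matching`` must be a maximum matching of ``build_bipartite(graph)``;
    with ``verify`` (default) this is checked by searching for an augmenting
    path and a ``ValueError`` is raised if one exists.
    """
    rep = matching.rep
    if rep.labels != graph.nodes:
        raise ValueError("matching was built for a different graph")
    if verify and has_augmenting_path(rep, matching):
        raise ValueError("matching is not maximum: an augmenting path exists")
    is_driver = {
        v: matching.right_match[i] == -1 for i, v in enumerate(graph.nodes)
    }
    is_sensor = {
        v: matching.left_match[i] == -1 for i, v in enumerate(graph.nodes)
    }
    return RoleAssignment(graph.nodes, is_driver, is_sensor)


def classify(
    graph: DirectedGraph, left_order: Sequence[int] | None = None
) -> RoleAssignment:
    """Convenience pipeline: bipartite rep -> Hopcroft-Karp -> roles."""
    rep = build_bipartite(graph)
    matching = hopcroft_karp(rep, left_order=left_order)
    return classify_nodes(graph, matching, verify=False)


def role_fractions(assignment: RoleAssignment, n: int | None = None) -> RoleFractions:
    """Category counts over N.  Raises on an empty graph (fractions undefined)."""
    if n is None:
        n = len(assignment.nodes)
    if n <= 0:
        raise ValueError("fractions are undefined for an empty graph")
    counts = assignment.category_counts()
    return RoleFractions(
        n_D=counts["driver"] / n,
        n_S=counts["sensor"] / n,
        n_DS=counts["ds"] / n,
        n_O=counts["ordinary"] / n,
    )


def apply_min_one_convention(assignment: RoleAssignment) -> RoleAssignment:
    """Promote the first node to driver and sensor if nothing is flagged.

    Under a perfect matching the literal classification leaves every node
    ordinary; the minimum-input/-output view instead says one (arbitrary)
    node must receive an input and one must feed an output.
    """
    if assignment.drivers or assignment.sensors:
        return assignment
    if not assignment.nodes:
        return assignment
    first = assignment.nodes[0]
    is_driver = dict(assignment.is_driver)
    is_sensor = dict(assignment.is_sensor)
    is_driver[first] = True
    is_sensor[first] = True
    return RoleAssignment(assignment.nodes, is_driver, is_sensor)


def resample_fractions(
    graph: DirectedGraph, resamples: int = 1, seed: int = 0
) -> dict:
    """Classify under ``resamples`` random left-node orders and summarize.

    Driver/sensor fractions are matching-independent; the DS and ordinary
    fractions can vary across maximum matchings, so their spread is reported
    as mean and (population) standard deviation.
    """
    if resamples < 1:
        raise ValueError("resamples must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(resamples):
        order = None if r == 0 else rng.permutation(graph.N)
        rows.append(role_fractions(classify(graph, left_order=order)))
    n_ds = [f.n_DS for f in rows]
    n_o = [f.n_O for f in rows]
    mean_ds = sum(n_ds) / len(n_ds)
    mean_o = sum(n_o) / len(n_o)
    return {
        "resamples": resamples,
        "n_D": rows[0].n_D,
        "n_S": rows[0].n_S,
        "n_DS_mean": mean_ds,
        "n_DS_sd": math.sqrt(sum((x - mean_ds) ** 2 for x in n_ds) / len(n_ds)),
        "n_O_mean": mean_o,
        "n_O_sd": math.sqrt(sum((x - mean_o) ** 2 for x in n_o) / len(n_o)),
    }
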