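"""Shared fixtures: tiny worked-example graphs and random-graph factories."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from netroles.graph_io import DirectedGraph

DATA_DIR = Path(__file__).resolve().parent.parent / "data"

#: printed Table-1 driver fractions for the four spot-check networks; the
#: edge lists themselves ship separately (see data/README.md)
REAL_NETWORK_ND = {
    "TRN-EC-2": 0.728,
    "TRN-Yeast-2": 0.821,
    "Grassland": 0.522,
    "USair97": 0.334,
}


def find_dataset(name: str) -> Path | None:
    """Locate a user-supplied real-network edge list under data/ by name."""
    if not DATA_DIR.exists():
        return None
    token = name.lower().replace("-", "").replace("_", "")
    for path in sorted(DATA_DIR.rglob("*")):
        if not path.is_file() or path.name.lower().endswith((".md", ".json")):
            continue
        stem = path.stem.lower().replace("-", "").replace("_", "")
        if token == stem or token in stem:
            return path
    return None


@pytest.fixture
def star_graph() -> DirectedGraph:
    """The 3-node worked example: one root feeding two leaves."""
    return DirectedGraph([("x1", "x2"), ("x1", "x3")])


@pytest.fixture
def cycle3() -> DirectedGraph:
    return DirectedGraph([("x1", "x2"), ("x2", "x3"), ("x3", "x1")])


def random_digraph(
    rng: np.random.Generator,
    n: int,
    p: float = 0.3,
    self_loops: bool = True,
) -> DirectedGraph:
    """Uniform G(n, p) digraph with string labels, used across tests."""
    edges = []
    for i in range(n):
        for j in range(n):
            if (i != j or self_loops) and rng.random() < p:
                edges.append((f"n{i}", f"n{j}"))
    return DirectedGraph(edges, nodes=[f"n{i}" for i in range(n)])


@pytest.fixture
def make_random_digraph():
    return random_digraph
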