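"""Seeded random-network generators and the degree-preserving null model.

Two ensembles:

* directed Erdős–Rényi: edges drawn uniformly over ordered pairs of distinct
  nodes until exactly M distinct edges exist;
* static-model scale-free: source i drawn with weight i^(-a_out), target j
  with weight j^(-a_in); the resulting in/out degree exponents are
  gamma = 1 + 1/a.

Self-loops and duplicate edges are rejected in both.  The degree-preserving
rewiring performs double-edge swaps, the standard null model that keeps every
node's in- and out-degree fixed while randomizing everything else.
"""

from __future__ import annotations

import numpy as np

from .graph_io import DirectedGraph

__all__ = [
    "generate_er",
    "generate_sf",
    "rewire_degree_preserving",
    "GenerationError",
]


class GenerationError(RuntimeError):
    """Raised when a generator cannot place the requested number of edges."""


def _labels(n: int) -> list[str]:
    return [f"v{i}" for i in range(1, n + 1)]


def _check_capacity(n: int, m: int) -> None:
    if m < 0 or n < 0:
        raise ValueError("N and M must be non-negative")
    if m > n * (n - 1):
        raise ValueError(
            f"M={m} exceeds simple-digraph capacity N(N-1)={n * (n - 1)}"
        )


def generate_er(n: int, m: int, seed: int = 0) -> DirectedGraph:
    """Directed ER graph: exactly ``m`` uniform edges, no self-loops/duplicates."""
    _check_capacity(n, m)
    rng = np.random.default_rng(seed)
    edges: set[tuple[int, int]] = set()
    while len(edges) < m:
        batch = max(1024, 2 * (m - len(edges)))
        src = rng.integers(0, n, size=batch)
        tgt = rng.integers(0, n, size=batch)
        for i, j in zip(src.tolist(), tgt.tolist()):
            if i != j:
                edges.add((i, j))
                if len(edges) == m:
                    break
    labels = _labels(n)
    return DirectedGraph(
        ((labels[i], labels[j]) for i, j in edges), nodes=labels
    )


def generate_sf(
    n: int,
    m: int,
    a_in: float,
    a_out: float,
    seed: int = 0,
    draw_budget_factor: int = 100,
) -> DirectedGraph:
    """Static-model scale-free digraph with exactly ``m`` edges.

    Source and target are drawn independently each step with probabilities
    proportional to ``i**-a_out`` and ``j**-a_in`` (1-based node rank); draws
    that would create a self-loop or duplicate are rejected.  Gives power-law
    in/out degrees with exponent ``1 + 1/a`` for large n.

    Raises
    ------
    GenerationError
        If ``m`` distinct edges cannot be placed within
        ``draw_budget_factor * m`` draws (dense, strongly skewed regimes).
    """
    _check_capacity(n, m)
    if not (0 < a_in < 1 and 0 < a_out < 1):
        raise ValueError("a_in and a_out must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    ranks = np.arange(1, n + 1, dtype=float)
    p_out = ranks**-a_out
    p_out /= p_out.sum()
    p_in = ranks**-a_in
    p_in /= p_in.sum()

    edges: set[tuple[int, int]] = set()
    budget = max(draw_budget_factor * m, 1)
    draws = 0
    while len(edges) < m:
        batch = min(max(1024, 2 * (m - len(edges))), budget - draws)
        if batch <= 0:
            raise GenerationError(
                f"placed only {len(edges)}/{m} edges within {budget} draws"
            )
        src = rng.choice(n, size=batch, p=p_out)
        tgt = rng.choice(n, size=batch, p=p_in)
        draws += batch
        for i, j in zip(src.tolist(), tgt.tolist()):
            if i != j:
                edges.add((i, j))
                if len(edges) == m:
                    break
    labels = _labels(n)
    return DirectedGraph(
        ((labels[i], labels[j]) for i, j in edges), nodes=labels
    )


def rewire_degree_preserving(
    graph: DirectedGraph,
    swaps: int | None = None,
    seed: int = 0,
    attempt_factor: int = 100,
) -> DirectedGraph:
    """Randomize a digraph by double-edge swaps, preserving all degrees.

    A swap picks edges ``(a,b)`` and ``(c,d)`` and replaces them with
    ``(a,d)`` and ``(c,b)``; candidates that would create a self-loop or a
    duplicate edge (or change nothing, when ``a==c`` or ``b==d``) are
    rejected.  Each node's in- and out-degree are invariant by construction.

    Parameters
    ----------
    swaps:
        Successful swaps to perform; default ``10 * M`` (a common mixing
        heuristic).  Attempts are capped at ``attempt_factor * swaps``; a
        graph with no admissible swap is returned unchanged.
    """
    m = graph.M
    if m < 2:
        return graph
    if swaps is None:
        swaps = 10 * m
    rng = np.random.default_rng(seed)
    edge_list = list(graph.edges)
    edge_set = set(edge_list)
    done = 0
    attempts = 0
    max_attempts = max(attempt_factor * swaps, 1)
    while done < swaps and attempts < max_attempts:
        attempts += 1
        x, y = rng.integers(0, m, size=2).tolist()
        if x == y:
            continue
        a, b = edge_list[x]
        c, d = edge_list[y]
        if a == c or b == d:
            continue  # swap would be a no-op
        if a == d or c == b:
            continue  # would create a self-loop
        if (a, d) in edge_set or (c, b) in edge_set:
            continue
        edge_set.remove((a, b))
        edge_set.remove((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edge_list[x] = (a, d)
        edge_list[y] = (c, b)
        done += 1
    return DirectedGraph(edge_list, nodes=graph.nodes)
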