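"""Bipartite representation of a digraph and maximum matching.

A directed graph on nodes ``x_1..x_N`` maps to a bipartite graph with a left
copy ``x_i^l`` (rows of the adjacency structure read column-wise: out-edges)
and a right copy ``x_i^r`` per node, and one undirected edge
``(x_j^l, x_i^r)`` per directed edge ``x_j -> x_i``.  Maximum matchings of
this bipartite graph drive the node-role classification.

`hopcroft_karp` is the production algorithm; `brute_force_max_matching` is an
independent exhaustive oracle for small instances, kept deliberately naive.
"""

from __future__ import annotations

from collections import deque
from collections.abc import Sequence
from dataclasses import dataclass, field

from .graph_io import DirectedGraph

__all__ = [
    "BipartiteRep",
    "Matching",
    "build_bipartite",
    "hopcroft_karp",
    "brute_force_max_matching",
    "has_augmenting_path",
]

_INF = float("inf")


@dataclass(frozen=True)
class BipartiteRep:
    """Bipartite double cover of a digraph's adjacency structure.

    ``labels[i]`` names both copies of node *i*; ``adj[i]`` lists the right
    copies adjacent to left copy *i*, i.e. the out-neighbourhood of node *i*
    in the source digraph, as indices sorted by node order.
    """

    labels: tuple[str, ...]
    adj: tuple[tuple[int, ...], ...]

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def left_nodes(self) -> tuple[str, ...]:
        return tuple(f"{v}^l" for v in self.labels)

    @property
    def right_nodes(self) -> tuple[str, ...]:
        return tuple(f"{v}^r" for v in self.labels)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            (f"{self.labels[i]}^l", f"{self.labels[j]}^r")
            for i in range(self.n)
            for j in self.adj[i]
        )

    @property
    def m(self) -> int:
        return sum(len(a) for a in self.adj)


@dataclass(frozen=True)
class Matching:
    """A set of bipartite edges with no shared endpoints.

    ``left_match[i]`` is the right index matched to left copy *i* (or -1);
    ``right_match[j]`` is the inverse map.
    """

    rep: BipartiteRep
    left_match: tuple[int, ...]
    right_match: tuple[int, ...]

    def __post_init__(self):
        for i, j in enumerate(self.left_match):
            if j >= 0 and self.right_match[j] != i:
                raise ValueError("inconsistent matching maps")
        for j, i in enumerate(self.right_match):
            if i >= 0 and self.left_match[i] != j:
                raise ValueError("inconsistent matching maps")

    @classmethod
    def from_pairs(
        cls, rep: BipartiteRep, pairs: Sequence[tuple[str, str]]
    ) -> "Matching":
        """Build a matching from ``(source_label, target_label)`` node pairs."""
        index = {v: i for i, v in enumerate(rep.labels)}
        lm = [-1] * rep.n
        rm = [-1] * rep.n
        for u, v in pairs:
            i, j = index[u], index[v]
            if j not in rep.adj[i]:
                raise ValueError(f"({u}, {v}) is not a bipartite edge")
            if lm[i] != -1 or rm[j] != -1:
                raise ValueError("pairs share an endpoint; not a matching")
            lm[i] = j
            rm[j] = i
        return cls(rep, tuple(lm), tuple(rm))

    @property
    def size(self) -> int:
        return sum(1 for j in self.left_match if j >= 0)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        lab = self.rep.labels
        return frozenset(
            (f"{lab[i]}^l", f"{lab[j]}^r")
            for i, j in enumerate(self.left_match)
            if j >= 0
        )

    @property
    def matched_left(self) -> frozenset[str]:
        return frozenset(
            self.rep.labels[i] for i, j in enumerate(self.left_match) if j >= 0
        )

    @property
    def matched_right(self) -> frozenset[str]:
        return frozenset(
            self.rep.labels[j] for j, i in enumerate(self.right_match) if i >= 0
        )


def build_bipartite(graph: DirectedGraph) -> BipartiteRep:
    """Left/right copies per node, one bipartite edge per directed edge.

    A self-loop ``(u, u)`` becomes the edge ``(u^l, u^r)``.
    """
    n = graph.N
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in graph.edges:
        adj[graph.index(u)].append(graph.index(v))
    return BipartiteRep(graph.nodes, tuple(tuple(sorted(a)) for a in adj))


def hopcroft_karp(
    rep: BipartiteRep, left_order: Sequence[int] | None = None
) -> Matching:
    """Maximum matching by BFS layering plus DFS augmentation.

    The returned matching is maximum; its edge set (not its size) depends on
    the order in which free left copies are explored, so ``left_order`` fixes
    the tie-breaking and makes runs reproducible.  Default: node order.
    """
    n = rep.n
    adj = rep.adj
    order = list(range(n)) if left_order is None else list(left_order)
    if sorted(order) != list(range(n)):
        raise ValueError("left_order must be a permutation of range(n)")

    match_l = [-1] * n
    match_r = [-1] * n
    dist = [0.0] * n

    def bfs() -> bool:
        queue = deque()
        for u in order:
            if match_l[u] == -1:
                dist[u] = 0
                queue.append(u)
            else:
                dist[u] = _INF
        reachable_free = False
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                w = match_r[v]
                if w == -1:
                    reachable_free = True
                elif dist[w] == _INF:
                    dist[w] = dist[u] + 1
                    queue.append(w)
        return reachable_free

    def augment(root: int, iters: list) -> bool:
        # Iterative alternating DFS along the BFS layers.  ``stack`` holds
        # left copies; ``via[d]`` is the right copy taken out of stack[d].
        stack = [root]
        via = [-1]
        while stack:
            u = stack[-1]
            advanced = False
            for v in iters[u]:
                w = match_r[v]
                if w == -1:
                    via[-1] = v
                    for uu, vv in zip(stack, via):
                        match_l[uu] = vv
                        match_r[vv] = uu
                    return True
                if dist[w] == dist[u] + 1:
                    via[-1] = v
                    stack.append(w)
                    via.append(-1)
                    advanced = True
                    break
            if not advanced:
                dist[u] = _INF  # dead end for this phase
                stack.pop()
                via.pop()
        return False

    while bfs():
        iters = [iter(a) for a in adj]
        for u in order:
            if match_l[u] == -1:
                augment(u, iters)
    return Matching(rep, tuple(match_l), tuple(match_r))


def has_augmenting_path(rep: BipartiteRep, matching: Matching) -> bool:
    """True iff an alternating path joins a free left copy to a free right copy.

    By Berge's lemma this is equivalent to the matching not being maximum.
    """
    match_l = matching.left_match
    match_r = matching.right_match
    seen = [False] * rep.n
    queue = deque(u for u in range(rep.n) if match_l[u] == -1)
    for u in queue:
        seen[u] = True
    while queue:
        u = queue.popleft()
        for v in rep.adj[u]:
            w = match_r[v]
            if w == -1:
                return True
            if not seen[w]:
                seen[w] = True
                queue.append(w)
    return False


_BRUTE_FORCE_EDGE_LIMIT = 20


def brute_force_max_matching(rep: BipartiteRep) -> int:
    """Exact maximum matching size by exhaustive branch over the edge list.

    Refuses instances with more than 20 edges.  Intentionally independent of
    `hopcroft_karp`: no layering, no augmentation, just include/exclude
    recursion.
    """
    edges = [(i, j) for i in range(rep.n) for j in rep.adj[i]]
    if len(edges) > _BRUTE_FORCE_EDGE_LIMIT:
        raise ValueError(
            f"instance has {len(edges)} edges; brute force is limited to "
            f"{_BRUTE_FORCE_EDGE_LIMIT}"
        )

    def best_from(pos: int, used_l: int, used_r: int) -> int:
        if pos == len(edges):
            return 0
        score = best_from(pos + 1, used_l, used_r)
        i, j = edges[pos]
        if not (used_l >> i) & 1 and not (used_r >> j) & 1:
            score = max(
                score, 1 + best_from(pos + 1, used_l | (1 << i), used_r | (1 << j))
            )
        return score

    return best_from(0, 0, 0)
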