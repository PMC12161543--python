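"""Degree-distribution theory for driver/sensor/DS fractions.

The pipeline: a paired in/out degree distribution feeds a two-sided
leaf/root fixed point (the core-percolation self-consistency equations of
greedy leaf removal); the fixed point yields core and root fractions, which
give the driver fraction

    n_D = n_S = 1 - (n_r + min(nc_plus, nc_minus)),

and the degree distribution alone gives the heuristic dual-identity estimate

    n_DS = P(0-)P(0+) + P(0-)P(1+) + P(1-)P(0+).

Closed forms are provided for the Poisson (directed ER) and truncated-gamma
(static-model scale-free) distributions.  `glr` is the combinatorial greedy
leaf removal on an actual bipartite graph, used to validate the theory.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, replace

import numpy as np
import scipy.special as sc

from .graph_io import DirectedGraph
from .matching import BipartiteRep, Matching

logger = logging.getLogger(__name__)

__all__ = [
    "DegreeDistribution",
    "FixedPointSolution",
    "AnalyticPrediction",
    "GLRResult",
    "ConvergenceError",
    "glr",
    "empirical_distribution",
    "poisson_distribution",
    "sf_distribution",
    "solve_fixed_point",
    "core_and_root_fractions",
    "predict_nD",
    "predict_nDS",
    "predict",
    "er_closed_forms",
    "sf_closed_forms",
    "upper_incomplete_gamma",
]


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach tolerance; carries last iterate."""

    def __init__(self, message: str, last: "FixedPointSolution"):
        super().__init__(message)
        self.last = last


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegreeDistribution:
    """Paired in/out degree mass functions over k = 0..k_max, plus the mean.

    ``p_in[k]`` is P(k-), ``p_out[k]`` is P(k+); ``mean_k`` is M/N, which is
    simultaneously the mean in-degree and the mean out-degree.
    """

    p_in: np.ndarray
    p_out: np.ndarray
    mean_k: float

    def validate(self, atol: float = 1e-9, mean_atol: float = 1e-6) -> None:
        for name, p in (("p_in", self.p_in), ("p_out", self.p_out)):
            if np.any(p < -1e-15):
                raise ValueError(f"{name} has negative mass")
            if abs(p.sum() - 1.0) > atol:
                raise ValueError(f"{name} sums to {p.sum()}, not 1")
        for name, p in (("p_in", self.p_in), ("p_out", self.p_out)):
            m = float(np.arange(len(p)) @ p)
            if abs(m - self.mean_k) > mean_atol * max(1.0, self.mean_k):
                raise ValueError(f"mean of {name} is {m}, expected {self.mean_k}")

    # P(0) and P(1) on each side, used by the DS estimate
    def p0_in(self) -> float:
        return float(self.p_in[0])

    def p1_in(self) -> float:
        return float(self.p_in[1]) if len(self.p_in) > 1 else 0.0

    def p0_out(self) -> float:
        return float(self.p_out[0])

    def p1_out(self) -> float:
        return float(self.p_out[1]) if len(self.p_out) > 1 else 0.0


def empirical_distribution(graph: DirectedGraph) -> DegreeDistribution:
    """Exact in/out degree histograms of a graph, normalized by N."""
    if graph.N == 0:
        raise ValueError("degree distribution undefined for an empty graph")
    kin = np.fromiter(graph.in_degrees().values(), dtype=int, count=graph.N)
    kout = np.fromiter(graph.out_degrees().values(), dtype=int, count=graph.N)
    return DegreeDistribution(
        p_in=np.bincount(kin) / graph.N,
        p_out=np.bincount(kout) / graph.N,
        mean_k=graph.M / graph.N,
    )


_TAIL_MASS = 1e-12
_K_CAP = 10_000


def poisson_distribution(mean_k: float, k_max: int | None = None) -> DegreeDistribution:
    """Poisson(mean_k) on both sides (directed ER limit), truncated and renormalized."""
    if mean_k < 0:
        raise ValueError("mean_k must be >= 0")
    if k_max is None:
        # smallest k with tail mass below threshold
        if mean_k == 0:
            k_max = 1
        else:
            k_max = max(int(math.ceil(mean_k)), 1)
            while sc.pdtrc(k_max, mean_k) > _TAIL_MASS and k_max < _K_CAP:
                k_max += max(1, k_max // 2)
            k_max = min(k_max, _K_CAP)
    k = np.arange(k_max + 1)
    with np.errstate(divide="ignore"):
        logp = k * np.log(mean_k) - mean_k - sc.gammaln(k + 1) if mean_k > 0 else None
    p = np.exp(logp) if mean_k > 0 else np.where(k == 0, 1.0, 0.0)
    p = p / p.sum()
    return DegreeDistribution(p_in=p, p_out=p, mean_k=float(mean_k))


def upper_incomplete_gamma(s: float, x: float) -> float:
    """Non-regularized upper incomplete gamma, valid for any real s and x > 0.

    For s > 0 this is scipy's regularized routine rescaled; for s <= 0 it is
    obtained by the downward recurrence
    ``Gamma(s, x) = (Gamma(s+1, x) - x**s * exp(-x)) / s``, with
    ``Gamma(0, x) = E1(x)`` handled exactly along the way.
    """
    s = float(s)
    x = float(x)
    if x < 0:
        raise ValueError("x must be >= 0")
    if x == 0:
        if s <= 0:
            raise ValueError("Gamma(s, 0) diverges for s <= 0")
        return float(sc.gamma(s))
    if s > 0:
        return float(sc.gammaincc(s, x) * sc.gamma(s))
    if s == 0:
        return float(sc.exp1(x))
    steps = int(math.floor(-s)) + 1  # s + steps lies in (0, 1]
    g = float(sc.gammaincc(s + steps, x) * sc.gamma(s + steps))
    for j in range(steps - 1, -1, -1):
        t = s + j
        if t == 0.0:
            g = float(sc.exp1(x))
        else:
            g = (g - x**t * math.exp(-x)) / t
    return g


def sf_distribution(
    mean_k: float,
    gamma: float,
    k_max: int | None = None,
    renormalize: bool = True,
) -> DegreeDistribution:
    """Static-model scale-free degree distribution on both sides.

    ``P(k) = delta * Gamma(k - 1/a, mean_k*(1-a)) / k!`` with
    ``a = 1/(gamma - 1)`` and ``delta = (mean_k*(1-a))**(1/a) / a``; the tail
    decays as ``k**-gamma``.  (The division by ``a`` is what makes the mass
    function sum to 1 with mean ``mean_k``; both are asserted by the test
    suite against the static-model generator.)  Requires ``gamma > 2`` so
    that ``a`` lies in (0, 1).  Truncated at ``k_max`` (default: tail mass
    below 1e-12, capped at 10_000) and renormalized unless ``renormalize``
    is false.
    """
    if gamma <= 2:
        raise ValueError("gamma must exceed 2 (so the weight exponent is in (0,1))")
    if mean_k <= 0:
        raise ValueError("mean_k must be > 0")
    a = 1.0 / (gamma - 1.0)
    x = mean_k * (1.0 - a)
    delta = x ** (1.0 / a) / a

    cap = _K_CAP if k_max is None else k_max
    k = np.arange(cap + 1)
    s = k - 1.0 / a
    p = np.empty(cap + 1)
    small = s <= 0.5  # recurrence region; also covers s <= 0
    for kk in k[small]:
        p[kk] = delta * upper_incomplete_gamma(kk - 1.0 / a, x) / math.factorial(kk)
    big = ~small
    if np.any(big):
        sb = s[big]
        p[big] = (
            delta
            * sc.gammaincc(sb, x)
            * np.exp(sc.gammaln(sb) - sc.gammaln(k[big] + 1.0))
        )
    if k_max is None:
        tail = np.cumsum(p[::-1])[::-1]  # tail[k] = sum_{j >= k} p[j]
        keep = np.nonzero(tail > _TAIL_MASS)[0]
        cut = int(keep[-1]) + 1 if len(keep) else 1
        p = p[: cut + 1]
    if renormalize:
        p = p / p.sum()
    return DegreeDistribution(p_in=p, p_out=p, mean_k=float(mean_k))


# ---------------------------------------------------------------------------
# fixed point and predictions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedPointSolution:
    """Leaf/root probabilities per side, plus iteration diagnostics.

    ``alpha_plus``/``beta_plus`` are the probabilities that an edge's left
    endpoint becomes a leaf / a root during greedy leaf removal;
    ``alpha_minus``/``beta_minus`` are the right-side analogues.
    """

    alpha_plus: float
    alpha_minus: float
    beta_plus: float
    beta_minus: float

    iterations: int = 0
    residual: float = float("nan")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.alpha_plus, self.alpha_minus, self.beta_plus, self.beta_minus)

    def symmetric_alpha_beta(self, atol: float = 1e-6) -> tuple[float, float]:
        """Collapse to (alpha, beta) when the two sides agree; error otherwise."""
        if (
            abs(self.alpha_plus - self.alpha_minus) > atol
            or abs(self.beta_plus - self.beta_minus) > atol
        ):
            raise ValueError(
                "fixed point is not symmetric; closed forms for symmetric "
                "distributions do not apply"
            )
        return (
            0.5 * (self.alpha_plus + self.alpha_minus),
            0.5 * (self.beta_plus + self.beta_minus),
        )


@dataclass(frozen=True)
class AnalyticPrediction:
    """Core/root fractions and the resulting category-fraction estimates."""

    nc_plus: float
    nc_minus: float
    n_r: float
    n_D: float = float("nan")
    n_DS: float = float("nan")
    n_O: float = float("nan")


def _edge_weights(p: np.ndarray, mean_k: float) -> np.ndarray:
    """Q(k) = k P(k) / <k> for k >= 1 (distribution of the far-end degree)."""
    if mean_k <= 0:
        return np.zeros(max(len(p) - 1, 0))
    k = np.arange(1, len(p))
    return k * p[1:] / mean_k


def _iterate(q_out, q_in, state, k_out, k_in):
    ap, am, bp, bm = state
    # leaf probabilities from current root probabilities ...
    ap_new = float(q_out @ bm ** k_out)
    am_new = float(q_in @ bp ** k_in)
    # ... then root probabilities from the fresh leaf probabilities
    bp_new = float(1.0 - q_out @ (1.0 - am_new) ** k_out)
    bm_new = float(1.0 - q_in @ (1.0 - ap_new) ** k_in)
    new = np.clip([ap_new, am_new, bp_new, bm_new], 0.0, 1.0)
    return tuple(float(v) for v in new)


def solve_fixed_point(
    dist: DegreeDistribution,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    check_alternative_init: bool = True,
) -> FixedPointSolution:
    """Solve the two-sided leaf/root self-consistency equations.

    Plain alternating iteration from ``alpha = beta = 0``: each sweep updates
    the leaf probabilities from the current root probabilities and then the
    root probabilities from the fresh leaf values, until the largest
    coordinate change drops below ``tol``.  With ``check_alternative_init``
    the all-ones start is also iterated and a warning logged if it lands on a
    different fixed point (the zero-start solution is always the one
    returned).

    A zero-mean distribution returns the empty-graph limit
    ``alpha = 1, beta = 0`` directly (every node is an isolated leaf).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if dist.mean_k == 0:
        return FixedPointSolution(1.0, 1.0, 0.0, 0.0, iterations=0, residual=0.0)
    q_out = _edge_weights(dist.p_out, dist.mean_k)
    q_in = _edge_weights(dist.p_in, dist.mean_k)
    k_out = np.arange(len(q_out), dtype=float)  # exponents k - 1
    k_in = np.arange(len(q_in), dtype=float)

    def run(start: tuple) -> tuple[tuple, int, float]:
        state = start
        residual = float("inf")
        for it in range(1, max_iter + 1):
            new = _iterate(q_out, q_in, state, k_out, k_in)
            residual = max(abs(a - b) for a, b in zip(new, state))
            state = new
            if residual < tol:
                return state, it, residual
        return state, max_iter, residual

    state, iterations, residual = run((0.0, 0.0, 0.0, 0.0))
    solution = FixedPointSolution(*state, iterations=iterations, residual=residual)
    if residual >= tol:
        raise ConvergenceError(
            f"fixed point not converged after {iterations} iterations "
            f"(residual {residual:.3e})",
            solution,
        )
    if check_alternative_init:
        alt_state, _, alt_res = run((1.0, 1.0, 1.0, 1.0))
        if alt_res < tol and max(
            abs(a - b) for a, b in zip(alt_state, state)
        ) > 1e-6:
            logger.warning(
                "fixed point from all-ones start differs from zero start; "
                "reporting the zero-start solution"
            )
    return solution


def core_and_root_fractions(
    dist: DegreeDistribution, fp: FixedPointSolution
) -> AnalyticPrediction:
    """Core fractions per side and the overall root fraction.

    The root fraction counts matching edges claimed by greedy leaf removal;
    the smaller core fraction counts the matching edges the residual core can
    still contribute.
    """
    ap, am, bp, bm = fp.as_tuple()
    k_out = np.arange(len(dist.p_out), dtype=float)
    k_in = np.arange(len(dist.p_in), dtype=float)
    mk = dist.mean_k
    nc_plus = float(
        dist.p_out @ ((1.0 - am) ** k_out - bm**k_out) - mk * ap * (1.0 - am - bm)
    )
    nc_minus = float(
        dist.p_in @ ((1.0 - ap) ** k_in - bp**k_in) - mk * am * (1.0 - ap - bp)
    )
    n_r = float(
        (1.0 - dist.p_out @ (1.0 - am) ** k_out)
        + (1.0 - dist.p_in @ (1.0 - ap) ** k_in)
        - mk * ap * am
    )
    clip = lambda v: float(np.clip(v, 0.0, 1.0))  # noqa: E731
    return AnalyticPrediction(
        nc_plus=clip(nc_plus), nc_minus=clip(nc_minus), n_r=clip(n_r)
    )


def predict_nD(pred: AnalyticPrediction) -> float:
    """Driver (= sensor) fraction from root and core fractions."""
    return float(np.clip(1.0 - (pred.n_r + min(pred.nc_plus, pred.nc_minus)), 0.0, 1.0))


def predict_nDS(dist: DegreeDistribution) -> float:
    """Heuristic dual-identity fraction from the P(0)/P(1) masses alone."""
    return (
        dist.p0_in() * dist.p0_out()
        + dist.p0_in() * dist.p1_out()
        + dist.p1_in() * dist.p0_out()
    )


def predict(
    dist: DegreeDistribution,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> tuple[AnalyticPrediction, FixedPointSolution]:
    """Full pipeline: fixed point -> core/root fractions -> n_D, n_DS, n_O.

    ``n_O`` is closed by the accounting identity
    ``n_D + n_S - n_DS + n_O = 1`` with ``n_S = n_D``.
    """
    fp = solve_fixed_point(dist, tol=tol, max_iter=max_iter)
    pred = core_and_root_fractions(dist, fp)
    n_d = predict_nD(pred)
    n_ds = predict_nDS(dist)
    n_o = float(np.clip(1.0 - 2.0 * n_d + n_ds, 0.0, 1.0))
    return replace(pred, n_D=n_d, n_DS=n_ds, n_O=n_o), fp


def er_closed_forms(
    mean_k: float, fp: FixedPointSolution, atol: float = 1e-6
) -> tuple[float, float]:
    """Poisson closed forms: n_DS = exp(-2<k>)(2<k>+1) and the matching n_O.

    ``fp`` must be the fixed point of the Poisson distribution, which is
    symmetric across sides; an asymmetric fixed point raises ``ValueError``.
    """
    alpha, beta = fp.symmetric_alpha_beta(atol=atol)
    n_ds = math.exp(-2.0 * mean_k) * (2.0 * mean_k + 1.0)
    n_o = n_ds - 2.0 * (alpha - beta + mean_k * alpha * (1.0 - beta)) + 1.0
    return n_ds, float(np.clip(n_o, 0.0, 1.0))


def sf_closed_forms(
    mean_k: float, gamma: float, fp: FixedPointSolution, atol: float = 1e-6
) -> tuple[float, float]:
    """Scale-free closed forms for n_DS and n_O.

    With ``a = 1/(gamma-1)``, ``x = <k>(1-a)``, ``delta = x**(1/a) / a`` and
    ``G_k = Gamma(k - 1/a, x) / k!``:

        n_DS = delta^2 G_0^2 + 2 delta^2 G_0 G_1
        n_O  = n_DS - 2<k> alpha (1-beta) (C_1 + C_2 + 1) + 3

    where C_1 and C_2 are ratios of upper incomplete gammas evaluated at
    ``x * alpha`` and ``x * (1-beta)``.  n_DS coincides exactly with the
    generic P(0)/P(1) estimate applied to `sf_distribution`.
    """
    if gamma <= 2:
        raise ValueError("gamma must exceed 2")
    alpha, beta = fp.symmetric_alpha_beta(atol=atol)
    a = 1.0 / (gamma - 1.0)
    x = mean_k * (1.0 - a)
    delta = x ** (1.0 / a) / a
    g0 = upper_incomplete_gamma(-1.0 / a, x)
    g1 = upper_incomplete_gamma(1.0 - 1.0 / a, x)
    n_ds = delta**2 * g0**2 + 2.0 * delta**2 * g0 * g1

    def c_ratio(arg: float) -> float:
        return upper_incomplete_gamma(-1.0 / a, arg) / upper_incomplete_gamma(
            1.0 - 1.0 / a, arg
        )

    c1 = c_ratio(x * alpha)
    c2 = c_ratio(x * (1.0 - beta))
    n_o = n_ds - 2.0 * mean_k * alpha * (1.0 - beta) * (c1 + c2 + 1.0) + 3.0
    return n_ds, float(np.clip(n_o, 0.0, 1.0))


# ---------------------------------------------------------------------------
# greedy leaf removal on an explicit bipartite graph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GLRResult:
    """Matching accumulated by leaf removal, the roots, and the residual core.

    Roots and core members are copy labels (``v^l`` / ``v^r``).
    """

    matching: Matching
    roots: frozenset[str]
    core: frozenset[str]


def glr(rep: BipartiteRep) -> GLRResult:
    """Greedy leaf removal on the bipartite representation.

    Repeatedly removes a degree-one node (leaf) together with its sole
    remaining neighbour (root) and records the connecting edge as a matching
    edge, until no degree-one node is left.  The residual nodes of degree
    at least two form the core; isolated leftovers are discarded.  Leaves
    are processed in node order (root/core *sizes* do not depend on the
    order).
    """
    n = rep.n
    total = 2 * n  # left copies 0..n-1, right copies n..2n-1
    neighbors: list[set[int]] = [set() for _ in range(total)]
    for i in range(n):
        for j in rep.adj[i]:
            neighbors[i].add(n + j)
            neighbors[n + j].add(i)
    degree = [len(neighbors[u]) for u in range(total)]
    alive = [True] * total
    queue = deque(u for u in range(total) if degree[u] == 1)
    pairs: list[tuple[str, str]] = []
    roots: set[int] = set()
    while queue:
        leaf = queue.popleft()
        if not alive[leaf] or degree[leaf] != 1:
            continue
        root = next(w for w in neighbors[leaf] if alive[w])
        left, right = (leaf, root) if leaf < n else (root, leaf)
        pairs.append((rep.labels[left], rep.labels[right - n]))
        roots.add(root)
        alive[leaf] = False
        alive[root] = False
        degree[leaf] = 0
        for w in neighbors[root]:
            if alive[w]:
                degree[w] -= 1
                if degree[w] == 1:
                    queue.append(w)
        degree[root] = 0

    def label(u: int) -> str:
        return f"{rep.labels[u]}^l" if u < n else f"{rep.labels[u - n]}^r"

    core = frozenset(label(u) for u in range(total) if alive[u] and degree[u] >= 2)
    return GLRResult(
        matching=Matching.from_pairs(rep, pairs),
        roots=frozenset(label(u) for u in roots),
        core=core,
    )
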