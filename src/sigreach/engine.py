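"""Exact two-terminal signal reachability via xy-polynomial collapsing.

Two-terminal reliability — the probability that at least one directed path of
independently present edges connects a source *s* to a target *t* — is
#P-complete, so no polynomial-time algorithm is expected.  The engine here
computes it exactly by multiplying, one edge at a time, the per-edge binomial

    p_i * x_i + (1 - p_i) * y_i

into a growing *xy-polynomial*.  Each non-free term ``a * x_S y_{Theta\\S}``
carries the probability ``a`` of the joint outcome "exactly the edges in S
(among those processed, Theta) are present".  Two free terms absorb resolved
outcomes: ``b x*`` (the target is already reached) and ``c y*`` (the target is
already cut off).  After every multiplication the polynomial is *collapsed*:

* a term whose present set S contains a directed s->t path moves into ``b``;
* a term whose absent set Theta\\S already disconnects s from t (no s->t path
  survives in E minus the absent edges) moves into ``c``.

Collapsing keeps the polynomial far smaller than the 2^|E| raw outcome space
on typical signaling topologies.  The fully multiplied, fully collapsed
polynomial has ``b`` equal to the reachability probability.

The same machinery yields the *deferred-edge linearization*: multiplying all
binomials except that of one edge *e* leaves reachability affine in p_e,

    R(p_e) = alpha + beta * p_e,   alpha = b,   beta = sum of surviving a_i,

which the local optimizer exploits for closed-form per-edge updates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .network import ProbabilisticNetwork, ReachabilityMatrix, ValidationError

__all__ = [
    "EngineError",
    "XYPolynomial",
    "LinearReachability",
    "ReachabilityEngine",
    "multiply_edge",
    "collapse",
    "reachability",
    "reachability_matrix",
    "linear_coefficients",
    "brute_force_reachability",
]

#: default cap on simultaneously live non-free terms
DEFAULT_TERM_CAP = 2_000_000
#: tolerated drift of b + c + sum(a_i) away from 1
CONSERVATION_TOL = 1e-9
#: brute-force enumeration refuses above this edge count
BRUTE_FORCE_MAX_EDGES = 20


class EngineError(Exception):
    """Raised on engine misuse or resource exhaustion."""


@dataclass
class XYPolynomial:
    """An xy-polynomial over a set of processed edge indices.

    ``terms`` maps each present-subset ``S`` (a frozenset of edge indices,
    subset of ``processed``) to its coefficient ``a >= 0``; the absent set is
    implicitly ``processed - S``.  ``b`` and ``c`` are the reached (x*) and
    cut (y*) coefficients.  When built from valid binomials the total mass
    ``b + c + sum(a)`` is 1.
    """

    processed: frozenset[int] = frozenset()
    terms: dict[frozenset[int], float] = field(default_factory=dict)
    b: float = 0.0
    c: float = 0.0

    @classmethod
    def empty(cls) -> "XYPolynomial":
        """The multiplicative identity: a single term with the empty subset."""
        return cls(processed=frozenset(), terms={frozenset(): 1.0}, b=0.0, c=0.0)

    def total(self) -> float:
        return self.b + self.c + sum(self.terms.values())

    def copy(self) -> "XYPolynomial":
        return XYPolynomial(self.processed, dict(self.terms), self.b, self.c)


def multiply_edge(poly: XYPolynomial, edge_index: int, p: float) -> XYPolynomial:
    """Multiply the binomial ``p x_e + (1-p) y_e`` into the polynomial.

    Every non-free term splits into a present branch (coefficient scaled by
    ``p``, subset grown by the edge) and an absent branch (scaled by
    ``1 - p``).  The free terms absorb both outcomes unchanged, because
    ``(p x_e)(b x*) + ((1-p) y_e)(b x*) = b x*`` and likewise for ``c y*``.
    Zero-coefficient branches are dropped to keep the term map sparse.
    """
    if edge_index in poly.processed:
        raise EngineError(f"edge {edge_index} already multiplied into the polynomial")
    if not 0.0 <= p <= 1.0:
        raise EngineError(f"edge probability {p} outside [0, 1]")
    q = 1.0 - p
    new_terms: dict[frozenset[int], float] = {}
    for subset, a in poly.terms.items():
        if p > 0.0:
            key = subset | {edge_index}
            new_terms[key] = new_terms.get(key, 0.0) + a * p
        if q > 0.0:
            new_terms[subset] = new_terms.get(subset, 0.0) + a * q
    return XYPolynomial(
        processed=poly.processed | {edge_index},
        terms=new_terms,
        b=poly.b,
        c=poly.c,
    )


class _PairContext:
    """Path/cut oracle for one (s, t) pair over a fixed edge universe.

    Results are memoized by edge subset; the caches persist for the lifetime
    of the context, so repeated collapses across candidate solutions and
    hill-climbing sweeps amortize their graph searches.
    """

    __slots__ = ("s", "t", "universe", "edge_list", "_path_cache", "_cut_cache")

    def __init__(
        self,
        network: ProbabilisticNetwork,
        s: str,
        t: str,
        universe: frozenset[int] | None = None,
    ) -> None:
        self.s = s
        self.t = t
        if universe is None:
            universe = frozenset(range(network.n_edges))
        self.universe = universe
        self.edge_list = network.edges
        self._path_cache: dict[frozenset[int], bool] = {}
        self._cut_cache: dict[frozenset[int], bool] = {}

    def _search(self, edge_indices) -> bool:
        """Directed BFS restricted to the given edge indices."""
        if self.s == self.t:
            return True
        adj: dict[str, list[str]] = {}
        for i in edge_indices:
            u, v = self.edge_list[i]
            adj.setdefault(u, []).append(v)
        frontier = [self.s]
        visited = {self.s}
        while frontier:
            nxt: list[str] = []
            for u in frontier:
                for v in adj.get(u, ()):
                    if v == self.t:
                        return True
                    if v not in visited:
                        visited.add(v)
                        nxt.append(v)
            frontier = nxt
        return False

    def has_path(self, present: frozenset[int]) -> bool:
        """Does the subgraph with exactly these edges contain an s->t path?"""
        hit = self._path_cache.get(present)
        if hit is None:
            hit = self._search(present)
            self._path_cache[present] = hit
        return hit

    def is_cut(self, absent: frozenset[int]) -> bool:
        """Does removing these edges from the universe disconnect s from t?"""
        hit = self._cut_cache.get(absent)
        if hit is None:
            hit = not self._search(self.universe - absent)
            self._cut_cache[absent] = hit
        return hit


def collapse(
    poly: XYPolynomial,
    network: ProbabilisticNetwork,
    s: str,
    t: str,
    *,
    _context: _PairContext | None = None,
) -> XYPolynomial:
    """Move resolved terms into the free coefficients.

    A term collapses to ``b`` when its present edges already form an s->t
    path, and to ``c`` when its absent edges already form an s->t cut (no
    path survives among the remaining edges of the universe).  Unresolved
    terms are kept verbatim; total mass is preserved exactly.
    """
    _validate_nodes(network, s, t)
    ctx = _context if _context is not None else _PairContext(network, s, t)
    b, c = poly.b, poly.c
    remaining: dict[frozenset[int], float] = {}
    for subset, a in poly.terms.items():
        if ctx.has_path(subset):
            b += a
        elif ctx.is_cut(poly.processed - subset):
            c += a
        else:
            remaining[subset] = a
    return XYPolynomial(processed=poly.processed, terms=remaining, b=b, c=c)


def _validate_nodes(network: ProbabilisticNetwork, *nodes: str) -> None:
    known = set(network.nodes)
    for node in nodes:
        if node not in known:
            raise ValidationError(f"unknown node {node!r}")


def _check_probabilities(network: ProbabilisticNetwork, probabilities) -> np.ndarray:
    p = np.asarray(probabilities, dtype=float)
    if p.shape != (network.n_edges,):
        raise ValidationError(
            f"probability vector of length {p.shape} does not match {network.n_edges} edges"
        )
    if p.size and (np.any(~np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0):
        raise ValidationError("edge probabilities must lie in [0, 1]")
    return p


def _reachable_from(edges, start: str, forward: bool = True) -> set[str]:
    adj: dict[str, list[str]] = {}
    for u, v in edges:
        if forward:
            adj.setdefault(u, []).append(v)
        else:
            adj.setdefault(v, []).append(u)
    visited = {start}
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in visited:
                    visited.add(v)
                    nxt.append(v)
        frontier = nxt
    return visited


class ReachabilityEngine:
    """Reusable reachability calculator for one fixed network topology.

    Precomputes, per (s, t) pair, the *relevant* edge subset — edges lying on
    at least one directed s->t walk — and a breadth-first multiplication
    order, and keeps per-pair path/cut caches alive across calls.  Irrelevant
    edges cannot change two-terminal reachability (their binomial splits
    every term into branches that collapse identically), so they are skipped.
    """

    def __init__(self, network: ProbabilisticNetwork, term_cap: int = DEFAULT_TERM_CAP):
        self.network = network
        self.term_cap = term_cap
        self._pair_data: dict[tuple[str, str], tuple[_PairContext, tuple[int, ...]]] = {}

    def _pair(self, s: str, t: str) -> tuple[_PairContext, tuple[int, ...]]:
        key = (s, t)
        cached = self._pair_data.get(key)
        if cached is not None:
            return cached
        net = self.network
        from_s = _reachable_from(net.edges, s, forward=True)
        to_t = _reachable_from(net.edges, t, forward=False)
        relevant = frozenset(
            i for i, (u, v) in enumerate(net.edges) if u in from_s and v in to_t
        )
        ctx = _PairContext(net, s, t, universe=relevant)
        order = self._bfs_order(relevant, s)
        self._pair_data[key] = (ctx, order)
        return ctx, order

    def _bfs_order(self, relevant: frozenset[int], s: str) -> tuple[int, ...]:
        """Order relevant edges by breadth-first discovery from the source.

        Earlier multiplication of edges near the source lets path collapses
        fire as soon as possible, bounding polynomial growth.  Edges leaving
        the same node keep their file order; any order is correct.
        """
        out: dict[str, list[int]] = {}
        for i in sorted(relevant):
            out.setdefault(self.network.edges[i][0], []).append(i)
        order: list[int] = []
        taken: set[int] = set()
        frontier = [s]
        seen_nodes = {s}
        while frontier:
            nxt: list[str] = []
            for u in frontier:
                for i in out.get(u, ()):
                    if i not in taken:
                        taken.add(i)
                        order.append(i)
                        v = self.network.edges[i][1]
                        if v not in seen_nodes:
                            seen_nodes.add(v)
                            nxt.append(v)
            frontier = nxt
        # relevant edges not discovered forward from s cannot exist by
        # construction, but be defensive:
        order.extend(i for i in sorted(relevant) if i not in taken)
        return tuple(order)

    def _run(
        self,
        probabilities: np.ndarray,
        s: str,
        t: str,
        skip_edge: int | None = None,
    ) -> XYPolynomial:
        ctx, order = self._pair(s, t)
        poly = XYPolynomial.empty()
        for i in order:
            if i == skip_edge:
                continue
            poly = multiply_edge(poly, i, float(probabilities[i]))
            poly = collapse(poly, self.network, s, t, _context=ctx)
            if abs(poly.total() - 1.0) > CONSERVATION_TOL:
                raise EngineError(
                    f"probability mass drifted to {poly.total():.12f} while "
                    f"processing edge {i} for pair ({s}, {t})"
                )
            if len(poly.terms) > self.term_cap:
                raise EngineError(
                    f"polynomial exceeded {self.term_cap} terms for pair ({s}, {t}); "
                    "raise term_cap or reduce the network"
                )
        return poly

    def pair_reachability(self, probabilities, s: str, t: str) -> float:
        _validate_nodes(self.network, s, t)
        p = _check_probabilities(self.network, probabilities)
        if s == t:
            return 1.0
        ctx, order = self._pair(s, t)
        if not order:
            return 0.0
        poly = self._run(p, s, t)
        if poly.terms:  # fully multiplied polynomials always collapse entirely
            raise EngineError("uncollapsed terms remain after full multiplication")
        return min(max(poly.b, 0.0), 1.0)

    def matrix(self, probabilities) -> ReachabilityMatrix:
        net = self.network
        net.require_terminals()
        p = _check_probabilities(net, probabilities)
        values = np.empty((len(net.sources), len(net.targets)))
        for i, s in enumerate(net.sources):
            for j, t in enumerate(net.targets):
                values[i, j] = self.pair_reachability(p, s, t)
        return ReachabilityMatrix(net.sources, net.targets, values)

    def linear(self, probabilities, deferred_edge: int, s: str, t: str) -> "LinearReachability":
        """Deferred-edge linearization R(p_e) = alpha + beta * p_e."""
        _validate_nodes(self.network, s, t)
        p = _check_probabilities(self.network, probabilities)
        if not 0 <= deferred_edge < self.network.n_edges:
            raise ValidationError(f"edge index {deferred_edge} out of range")
        if s == t:
            return LinearReachability(1.0, 0.0)
        ctx, order = self._pair(s, t)
        if deferred_edge not in ctx.universe:
            # the deferred edge lies on no s->t walk: reachability is constant
            return LinearReachability(self.pair_reachability(p, s, t), 0.0)
        poly = self._run(p, s, t, skip_edge=deferred_edge)
        alpha = poly.b
        beta = sum(poly.terms.values())
        return LinearReachability(min(alpha, 1.0), beta)


@dataclass(frozen=True)
class LinearReachability:
    """Reachability as an affine function alpha + beta * p_e of one edge."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.alpha and self.alpha + self.beta <= 1.0 + 1e-9):
            raise EngineError(
                f"invalid linearization alpha={self.alpha}, beta={self.beta}"
            )

    def __call__(self, p: float) -> float:
        return self.alpha + self.beta * p


# ---------------------------------------------------------------------------
# stateless convenience wrappers


def reachability(network: ProbabilisticNetwork, probabilities, s: str, t: str) -> float:
    """Exact probability of a signal propagating from s to t."""
    return ReachabilityEngine(network).pair_reachability(probabilities, s, t)


def reachability_matrix(network: ProbabilisticNetwork, probabilities) -> ReachabilityMatrix:
    """Signal reachability R_P over the declared source and target sets."""
    return ReachabilityEngine(network).matrix(probabilities)


def linear_coefficients(
    network: ProbabilisticNetwork, probabilities, deferred_edge: int, s: str, t: str
) -> LinearReachability:
    """Alpha/beta of the deferred-edge linearization for one (s, t) pair."""
    return ReachabilityEngine(network).linear(probabilities, deferred_edge, s, t)


def brute_force_reachability(
    network: ProbabilisticNetwork, probabilities, s: str, t: str
) -> float:
    """Reachability by enumerating all 2^|E| edge subsets (test oracle).

    Refuses above :data:`BRUTE_FORCE_MAX_EDGES` edges.
    """
    _validate_nodes(network, s, t)
    p = _check_probabilities(network, probabilities)
    n = network.n_edges
    if n > BRUTE_FORCE_MAX_EDGES:
        raise EngineError(f"brute force refused for |E| = {n} > {BRUTE_FORCE_MAX_EDGES}")
    if s == t:
        return 1.0
    ctx = _PairContext(network, s, t)
    total = 0.0
    for present in itertools.product((False, True), repeat=n):
        weight = 1.0
        for i, bit in enumerate(present):
            weight *= p[i] if bit else 1.0 - p[i]
        if weight == 0.0:
            continue
        subset = frozenset(i for i, bit in enumerate(present) if bit)
        if ctx.has_path(subset):
            total += weight
    return total
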