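"""Synthetic networks and reachability data with known ground truth.

Real applications of this package fit edge probabilities of curated
signaling topologies (e.g. KEGG pathway excerpts) against coexpression
matrices computed from patient expression cohorts.  Neither is bundled;
instead this module generates study instances whose every stage is known:

* a random directed acyclic network with designated receptor (source) and
  reporter (target) nodes, every target reachable from at least one source;
* a ground-truth probability vector P* drawn i.i.d. uniform on [0, 1];
* the clean empirical matrix C = R_{P*} computed by the exact engine, plus
  an optionally noise-perturbed copy (Gaussian in C-space, clipped to
  [0, 1]);
* a linear-propagation expression simulator for end-to-end tests of the
  coexpression front end.

Because distinct probability vectors can induce the same reachability
matrix, recovery on these instances is judged in R-space (fit quality), not
by entrywise comparison with P*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coexpression import ExpressionMatrix
from .engine import reachability_matrix
from .network import NetworkError, ProbabilisticNetwork, ReachabilityMatrix

__all__ = [
    "SyntheticInstance",
    "generate_network",
    "generate_instance",
    "fixture",
    "fixture_closed_form",
    "simulate_expression",
]

FIXTURE_NAMES = ("single-edge", "series", "parallel", "diamond", "bridge")
_MAX_ATTEMPTS = 200


@dataclass(frozen=True)
class SyntheticInstance:
    network: ProbabilisticNetwork
    ground_truth: np.ndarray
    c_clean: ReachabilityMatrix
    c_noisy: ReachabilityMatrix | None
    seed_state: object = None


def _search_nodes(edges, start: str) -> set[str]:
    adj: dict[str, list[str]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
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


def generate_network(
    n_nodes: int,
    n_edges: int,
    n_sources: int = 1,
    n_targets: int = 1,
    rng: np.random.Generator | int | None = None,
    allow_cycles: bool = False,
) -> ProbabilisticNetwork:
    """Random DAG with every target reachable from at least one source.

    Nodes are ordered G01..Gnn; edges point forward in that order (acyclic).
    The first `n_sources` nodes are reserved as sources (no incoming edges)
    and the last `n_targets` as targets (no outgoing edges), so sources are
    roots and targets are sinks.  Edge sets are rejection-sampled until
    every target is reachable; `allow_cycles` additionally rewires a few
    edges backwards for stress testing.
    """
    rng = np.random.default_rng(rng)
    if n_sources < 1 or n_targets < 1 or n_sources + n_targets > n_nodes:
        raise NetworkError("need n_sources + n_targets <= n_nodes, both >= 1")
    width = len(str(n_nodes))
    names = [f"G{i + 1:0{width}d}" for i in range(n_nodes)]
    sources = names[:n_sources]
    targets = names[-n_targets:]
    allowed = [
        (i, j)
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if names[j] not in sources and names[i] not in targets
    ]
    if n_edges > len(allowed):
        raise NetworkError(
            f"{n_edges} edges requested but only {len(allowed)} node pairs allowed"
        )
    for _ in range(_MAX_ATTEMPTS):
        picked = rng.choice(len(allowed), size=n_edges, replace=False)
        edges = [(names[allowed[k][0]], names[allowed[k][1]]) for k in sorted(picked)]
        reached: set[str] = set()
        for s in sources:
            reached |= _search_nodes(edges, s)
        if all(t in reached for t in targets):
            if allow_cycles and n_edges >= 2:
                # rewire one forward edge into a back-edge that is not a
                # duplicate or self-loop
                idx = int(rng.integers(n_edges))
                u, v = edges[idx]
                if (v, u) not in edges and v not in sources and u not in targets:
                    edges[idx] = (v, u)
                    reached = set()
                    for s in sources:
                        reached |= _search_nodes(edges, s)
                    if not all(t in reached for t in targets):
                        edges[idx] = (u, v)
            return ProbabilisticNetwork(
                nodes=tuple(names),
                edges=tuple(edges),
                sources=tuple(sources),
                targets=tuple(targets),
            )
    raise NetworkError(
        f"could not connect all targets in {_MAX_ATTEMPTS} attempts "
        f"({n_nodes} nodes, {n_edges} edges)"
    )


def generate_instance(
    network: ProbabilisticNetwork,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> SyntheticInstance:
    """Draw P* ~ U[0,1]^|E|, compute C = R_{P*}, optionally perturb it.

    Noise is additive Gaussian in C-space with the given standard deviation,
    clipped back into [0, 1] — the optimizer consumes C, so this is where
    measurement noise matters.
    """
    if noise_sd < 0.0:
        raise NetworkError("noise_sd must be >= 0")
    rng = np.random.default_rng(rng)
    p_star = rng.random(network.n_edges)
    c_clean = reachability_matrix(network, p_star)
    c_noisy = None
    if noise_sd > 0.0:
        perturbed = np.clip(
            c_clean.values + rng.normal(0.0, noise_sd, size=c_clean.values.shape),
            0.0,
            1.0,
        )
        c_noisy = ReachabilityMatrix(c_clean.sources, c_clean.targets, perturbed)
    return SyntheticInstance(
        network=network.with_probabilities(p_star),
        ground_truth=p_star,
        c_clean=c_clean,
        c_noisy=c_noisy,
    )


def fixture(name: str) -> ProbabilisticNetwork:
    """Canonical toy networks with closed-form s->t reachability.

    single-edge: s->t.
    series:      s->m->t                    R = p1 p2
    parallel:    two disjoint s->t routes   R = 1-(1-p1)(1-p2)
    diamond:     s->a->t, s->b->t           R = 1-(1-p1 p2)(1-p3 p4)
    bridge:      Wheatstone with a directed a->b bridge edge (edge 5).
    """
    if name == "single-edge":
        edges = [("s", "t")]
    elif name == "series":
        edges = [("s", "m"), ("m", "t")]
    elif name == "parallel":
        # a true multi-edge s->t pair is disallowed (one probability per
        # interaction), so the two routes run through distinct relay nodes;
        # pin the relay edges (2, 3) at probability 1 to realize the
        # textbook 1-(1-p1)(1-p2) form
        edges = [("s", "a"), ("s", "b"), ("a", "t"), ("b", "t")]
    elif name == "diamond":
        edges = [("s", "a"), ("a", "t"), ("s", "b"), ("b", "t")]
    elif name == "bridge":
        edges = [("s", "a"), ("s", "b"), ("a", "t"), ("b", "t"), ("a", "b")]
    else:
        raise NetworkError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    nodes = tuple(dict.fromkeys(n for e in edges for n in e))
    return ProbabilisticNetwork(
        nodes=nodes, edges=tuple(edges), sources=("s",), targets=("t",)
    )


def fixture_closed_form(name: str, p: np.ndarray) -> float:
    """Textbook closed-form reachability for each fixture, for cross-checks."""
    p = np.asarray(p, dtype=float)
    if name == "single-edge":
        return float(p[0])
    if name == "series":
        return float(p[0] * p[1])
    if name == "parallel":
        # routes s->a->t and s->b->t with edges (s,a),(s,b),(a,t),(b,t)
        return float(1.0 - (1.0 - p[0] * p[2]) * (1.0 - p[1] * p[3]))
    if name == "diamond":
        return float(1.0 - (1.0 - p[0] * p[1]) * (1.0 - p[2] * p[3]))
    if name == "bridge":
        # edges: 0 s->a, 1 s->b, 2 a->t, 3 b->t, 4 a->b; condition on edge 4
        with_bridge = p[0] * (1.0 - (1.0 - p[2]) * (1.0 - p[3])) + (1.0 - p[0]) * p[1] * p[3]
        without = 1.0 - (1.0 - p[0] * p[2]) * (1.0 - p[1] * p[3])
        return float(p[4] * with_bridge + (1.0 - p[4]) * without)
    raise NetworkError(f"unknown fixture {name!r}")


def simulate_expression(
    network: ProbabilisticNetwork,
    probabilities: np.ndarray,
    n_samples: int = 100,
    noise_sd: float = 0.1,
    rng: np.random.Generator | int | None = None,
) -> ExpressionMatrix:
    """Linear signal propagation: a crude expression emulator for CLI tests.

    Source nodes receive i.i.d. standard-normal latent activity; every other
    node, in topological order, sums `p_e * parent activity` over incoming
    edges plus Gaussian noise.  This produces receptor/reporter correlations
    that grow with path strength — sufficient for exercising the
    coexpression front end, with no pretence of transcriptional realism.
    """
    rng = np.random.default_rng(rng)
    order = _topological_order(network)
    values = {n: np.zeros(n_samples) for n in network.nodes}
    in_edges: dict[str, list[tuple[str, float]]] = {n: [] for n in network.nodes}
    for (u, v), p in zip(network.edges, probabilities):
        in_edges[v].append((u, float(p)))
    for node in order:
        if not in_edges[node]:
            values[node] = rng.normal(size=n_samples)
        else:
            acc = np.zeros(n_samples)
            for u, p in in_edges[node]:
                acc += p * values[u]
            values[node] = acc + rng.normal(0.0, noise_sd, size=n_samples)
    frame = pd.DataFrame(
        {f"sample{i + 1}": [values[n][i] for n in network.nodes] for i in range(n_samples)},
        index=list(network.nodes),
    )
    return ExpressionMatrix(frame)


def _topological_order(network: ProbabilisticNetwork) -> list[str]:
    indeg = {n: 0 for n in network.nodes}
    adj: dict[str, list[str]] = {n: [] for n in network.nodes}
    for u, v in network.edges:
        indeg[v] += 1
        adj[u].append(v)
    queue = [n for n in network.nodes if indeg[n] == 0]
    order: list[str] = []
    while queue:
        node = queue.pop(0)
        order.append(node)
        for v in adj[node]:
            indeg[v] -= 1
            if indeg[v] == 0:
                queue.append(v)
    if len(order) != len(network.nodes):
        raise NetworkError("expression simulation requires an acyclic network")
    return order
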