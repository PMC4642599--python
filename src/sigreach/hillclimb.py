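"""Phase 2 — per-edge closed-form hill climbing on the reachability error.

With all other edge probabilities fixed, the reachability of every (s, t)
pair is affine in the remaining edge's probability, R[s,t] = alpha_st +
beta_st * p_e (deferred-edge linearization).  The squared error

    SSE(p_e) = sum_{s,t} (C[s,t] - alpha_st - beta_st * p_e)^2

is then a 1-D convex quadratic whose unconstrained minimizer is

    p_e = sum beta_st (C[s,t] - alpha_st) / sum beta_st^2 ,

clipped to [0, 1] (convexity makes the nearest boundary optimal when the
minimizer falls outside).  An edge with beta_st identically zero influences
no pair; its probability is non-identifiable and left untouched.  Sweeping
the edges in fixed index order and iterating yields a monotone descent that
terminates once a full sweep improves the SSE by less than the tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import ReachabilityEngine
from .ga import CandidateSolution
from .network import ProbabilisticNetwork, ReachabilityMatrix, ValidationError

__all__ = [
    "PairLinearization",
    "HillClimbResult",
    "pair_linearizations",
    "optimal_edge_probability",
    "hill_climb",
]

DEFAULT_TOLERANCE = 1e-9
DEFAULT_MAX_SWEEPS = 1000


@dataclass(frozen=True)
class PairLinearization:
    """alpha/beta arrays over all (s, t) pairs for one deferred edge."""

    alpha: np.ndarray  # shape |S| x |T|
    beta: np.ndarray   # shape |S| x |T|

    def reachability_at(self, p: float) -> np.ndarray:
        return self.alpha + self.beta * p

    def sse_at(self, p: float, C: np.ndarray) -> float:
        return float(np.sum((C - self.alpha - self.beta * p) ** 2))


def pair_linearizations(
    network: ProbabilisticNetwork,
    psi: np.ndarray,
    edge: int,
    engine: ReachabilityEngine | None = None,
) -> PairLinearization:
    """Compute alpha_st, beta_st for every source/target pair at one edge."""
    network.require_terminals()
    if not 0 <= edge < network.n_edges:
        raise ValidationError(f"edge index {edge} out of range")
    engine = engine or ReachabilityEngine(network)
    shape = (len(network.sources), len(network.targets))
    alpha = np.empty(shape)
    beta = np.empty(shape)
    for i, s in enumerate(network.sources):
        for j, t in enumerate(network.targets):
            lin = engine.linear(psi, edge, s, t)
            alpha[i, j] = lin.alpha
            beta[i, j] = lin.beta
    return PairLinearization(alpha=alpha, beta=beta)


def optimal_edge_probability(
    network: ProbabilisticNetwork,
    psi: np.ndarray,
    edge: int,
    C: ReachabilityMatrix,
    engine: ReachabilityEngine | None = None,
) -> float:
    """Closed-form least-squares update for one edge, clipped to [0, 1]."""
    lin = pair_linearizations(network, psi, edge, engine=engine)
    denom = float(np.sum(lin.beta**2))
    if denom == 0.0:
        return float(psi[edge])
    num = float(np.sum(lin.beta * (C.values - lin.alpha)))
    return float(np.clip(num / denom, 0.0, 1.0))


@dataclass
class HillClimbResult:
    """Final solution plus convergence diagnostics."""

    solution: CandidateSolution
    sse: float
    sweeps: int
    converged: bool
    non_identifiable: tuple[int, ...] = ()
    sse_history: list[float] = field(default_factory=list)


def hill_climb(
    network: ProbabilisticNetwork,
    psi0: np.ndarray,
    C: ReachabilityMatrix,
    tolerance: float = DEFAULT_TOLERANCE,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
    engine: ReachabilityEngine | None = None,
) -> HillClimbResult:
    """Coordinate descent over edges until a sweep stops improving the SSE.

    Every single-edge update is the exact minimizer of the SSE along that
    coordinate, so the SSE sequence is non-increasing; being bounded below
    by zero it converges, and the loop exits once a full sweep gains less
    than `tolerance` (or `max_sweeps` is hit).
    """
    network.require_terminals()
    if tolerance <= 0.0:
        raise ValidationError("tolerance must be positive")
    engine = engine or ReachabilityEngine(network)
    psi = np.asarray(psi0, dtype=float).copy()
    if psi.shape != (network.n_edges,):
        raise ValidationError("psi0 length does not match edge count")
    Cv = C.values
    R = engine.matrix(psi)
    sse = float(np.sum((Cv - R.values) ** 2))
    history = [sse]
    converged = False
    flat_edges: set[int] = set()
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        sse_start = sse
        for edge in range(network.n_edges):
            lin = pair_linearizations(network, psi, edge, engine=engine)
            denom = float(np.sum(lin.beta**2))
            if denom == 0.0:
                flat_edges.add(edge)
                continue
            flat_edges.discard(edge)
            p_new = float(
                np.clip(np.sum(lin.beta * (Cv - lin.alpha)) / denom, 0.0, 1.0)
            )
            new_sse = lin.sse_at(p_new, Cv)
            # exact coordinate minimizer: never worse than the incumbent
            if new_sse > sse + 1e-12:
                raise RuntimeError(
                    f"SSE increased at edge {edge}: {sse} -> {new_sse}"
                )
            psi[edge] = p_new
            sse = new_sse
        history.append(sse)
        if sse_start - sse < tolerance:
            converged = True
            break
    solution = CandidateSolution.evaluate(engine, C, psi)
    return HillClimbResult(
        solution=solution,
        sse=sse,
        sweeps=sweeps,
        converged=converged,
        non_identifiable=tuple(sorted(flat_edges)),
        sse_history=history,
    )
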