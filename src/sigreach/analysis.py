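"""Post-fit analytics: quality, spread, condition contrasts, centrality.

Once edge probabilities have been fitted separately for several biological
conditions (e.g. disease subtypes) over one shared network topology, these
routines quantify:

* fit *quality* — the fitness as a percentage, 100 (1 - ||C - R||_2 / |SxT|);
* how spread the fitted probabilities are over [0, 1] (histogram entropy);
* how strongly conditions differ (pairwise Euclidean distances between their
  probability vectors);
* *outstanding* interactions — edges whose probability in one condition lies
  at least two standard deviations from that edge's mean across all
  conditions — and the gene set L of their endpoints, the input for
  downstream enrichment analysis;
* per-gene "removal centrality": a node's total contribution to
  source-to-target reachability, measured by deleting its incident edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ReachabilityEngine
from .ga import fitness
from .network import ProbabilisticNetwork, ValidationError

__all__ = [
    "ConditionProfile",
    "OutstandingReport",
    "quality",
    "probability_entropy",
    "condition_distances",
    "outstanding",
    "node_centrality",
]

OUTSTANDING_SIGMAS = 2.0


@dataclass(frozen=True)
class ConditionProfile:
    """One condition's fitted edge-probability vector (shared edge order)."""

    label: str
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1:
            raise ValidationError("probabilities must be a 1-D vector")
        object.__setattr__(self, "probabilities", p)


@dataclass(frozen=True)
class OutstandingReport:
    """Per-edge statistics across conditions and the flagged outliers."""

    edge_mean: np.ndarray
    edge_sd: np.ndarray
    #: (condition label, edge index) pairs with |p - mean| >= 2 sd, sd > 0
    flags: tuple[tuple[str, int], ...]
    #: per-condition outstanding gene set L (endpoints of flagged edges)
    gene_sets: dict[str, tuple[str, ...]]


def quality(C, R) -> float:
    """Fit quality in percent; 100 means the computed R reproduces C."""
    return 100.0 * fitness(C, R)


def probability_entropy(values, bins: int = 10) -> float:
    """Entropy (nats) of the histogram of probabilities over [0, 1].

    Bins are [0, 1/bins), ..., closing the final bin at 1; 0 log 0 := 0.
    Higher entropy means the values spread across the spectrum instead of
    crowding a few bins; the maximum is ln(bins).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValidationError("cannot compute entropy of an empty value set")
    if bins < 2:
        raise ValidationError("need at least 2 bins")
    if vals.min() < 0.0 or vals.max() > 1.0:
        raise ValidationError("probabilities must lie in [0, 1]")
    counts, _ = np.histogram(vals, bins=np.linspace(0.0, 1.0, bins + 1))
    p = counts[counts > 0] / vals.size
    return float(-np.sum(p * np.log(p)))


def _stack(profiles: list[ConditionProfile]) -> tuple[list[str], np.ndarray]:
    if len(profiles) < 2:
        raise ValidationError("need at least 2 condition profiles")
    lengths = {p.probabilities.shape[0] for p in profiles}
    if len(lengths) != 1:
        raise ValidationError("condition profiles must share one edge ordering")
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValidationError("condition labels must be unique")
    return labels, np.vstack([p.probabilities for p in profiles])


def condition_distances(
    profiles: list[ConditionProfile],
) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise Euclidean distances plus each condition's mean distance."""
    labels, mat = _stack(profiles)
    diff = mat[:, None, :] - mat[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=2))
    frame = pd.DataFrame(dist, index=labels, columns=labels)
    n = len(labels)
    mean = pd.Series(dist.sum(axis=1) / (n - 1), index=labels, name="mean_distance")
    return frame, mean


def outstanding(
    profiles: list[ConditionProfile],
    network: ProbabilisticNetwork | None = None,
) -> OutstandingReport:
    """Flag (condition, edge) pairs at least 2 sd from the edge's mean.

    Mean and population standard deviation are taken over all conditions.
    Edges identical in every condition have sd 0 and are never flagged.
    When `network` is given, the per-condition gene set L collects both
    endpoints of every flagged edge.
    """
    labels, mat = _stack(profiles)
    if len(profiles) < 3:
        raise ValidationError("outstanding analysis needs at least 3 conditions")
    if network is not None and network.n_edges != mat.shape[1]:
        raise ValidationError("profiles do not match the network's edge count")
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0)  # population (N) denominator
    flags: list[tuple[str, int]] = []
    for i, label in enumerate(labels):
        dev = np.abs(mat[i] - mean)
        # sd floor guards against floating-point dust when a row is constant
        hits = np.flatnonzero(
            (sd > 1e-12) & (dev >= OUTSTANDING_SIGMAS * sd * (1.0 - 1e-12))
        )
        flags.extend((label, int(e)) for e in hits)
    gene_sets: dict[str, tuple[str, ...]] = {}
    if network is not None:
        buckets: dict[str, list[str]] = {}
        for label, edge in flags:
            u, v = network.edges[edge]
            bucket = buckets.setdefault(label, [])
            for g in (u, v):
                if g not in bucket:
                    bucket.append(g)
        gene_sets = {k: tuple(v) for k, v in buckets.items()}
    return OutstandingReport(
        edge_mean=mean, edge_sd=sd, flags=tuple(flags), gene_sets=gene_sets
    )


def node_centrality(network: ProbabilisticNetwork, probabilities) -> pd.Series:
    """Removal centrality: a node's total contribution to reachability.

    centrality(v) = sum over (s, t) pairs (s != v != t) of
    R[s, t] - R_without_v[s, t], where R_without_v deletes every edge
    incident to v.  Non-negative because removing edges can only lower
    reachability; zero for nodes off every source->target path.
    """
    network.require_terminals()
    p = np.asarray(probabilities, dtype=float)
    engine = ReachabilityEngine(network)
    base = engine.matrix(p)
    out = {}
    for v in network.nodes:
        keep = [i for i, (a, b) in enumerate(network.edges) if v not in (a, b)]
        sub = ProbabilisticNetwork(
            nodes=network.nodes,
            edges=tuple(network.edges[i] for i in keep),
            sources=network.sources,
            targets=network.targets,
        )
        sub_engine = ReachabilityEngine(sub)
        sub_p = p[keep]
        total = 0.0
        for i, s in enumerate(network.sources):
            for j, t in enumerate(network.targets):
                if v in (s, t):
                    continue
                total += base.values[i, j] - sub_engine.pair_reachability(sub_p, s, t)
        out[v] = total
    return pd.Series(out, name="removal_centrality")
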