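"""Graph representation and file I/O for probabilistic signaling networks.

A probabilistic signaling network is a directed graph G = (V, E, P) in which
nodes are genes, edges are interactions, and ``P`` assigns each edge an
independent existence probability in [0, 1].  Two designated node sets play a
special role: the *sources* S (membrane receptor genes, where a signal enters)
and the *targets* T (reporter / transcription-factor genes, where it is read
out).  Reachability matrices over S x T hold either computed signal
reachability (R_P) or empirical coexpression values (C).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkError",
    "ParseError",
    "ValidationError",
    "ProbabilisticNetwork",
    "ReachabilityMatrix",
    "read_network",
    "write_probabilities",
    "read_matrix",
    "write_matrix",
    "read_node_list",
    "write_node_list",
]

#: decimal digits used when serializing probabilities
PROB_DECIMALS = 6


class NetworkError(Exception):
    """Base class for network model errors."""


class ParseError(NetworkError):
    """A file could not be parsed (malformed line, ragged table, ...)."""


class ValidationError(NetworkError):
    """Parsed content violates a model invariant."""


@dataclass(frozen=True)
class ProbabilisticNetwork:
    """A directed network with optional per-edge existence probabilities.

    Parameters
    ----------
    nodes
        All node identifiers (opaque, case-sensitive strings).
    edges
        Ordered directed edges ``(source, target)``; the position of an edge
        in this list is its identity throughout the package.
    probabilities
        Optional vector, one entry in [0, 1] per edge (the function P).
    sources, targets
        The receptor set S and reporter set T.  May be empty for networks
        that are only used structurally; reachability-matrix operations
        require both to be non-empty.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    probabilities: np.ndarray | None = None
    sources: tuple[str, ...] = ()
    targets: tuple[str, ...] = ()
    edge_index: dict[tuple[str, str], int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValidationError("duplicate node identifiers")
        index: dict[tuple[str, str], int] = {}
        for i, (u, v) in enumerate(self.edges):
            if (u, v) in index:
                raise ValidationError(f"duplicate directed edge ({u}, {v})")
            if u not in node_set or v not in node_set:
                raise ValidationError(f"edge ({u}, {v}) references unknown node")
            if u == v:
                raise ValidationError(f"self-loop ({u}, {v}) not allowed in a validated network")
            index[(u, v)] = i
        for name, group in (("source", self.sources), ("target", self.targets)):
            for node in group:
                if node not in node_set:
                    raise ValidationError(f"{name} node {node!r} is not in the network")
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=float)
            if p.shape != (len(self.edges),):
                raise ValidationError(
                    f"probability vector has length {p.shape}, expected {len(self.edges)}"
                )
            if np.any(~np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
                raise ValidationError("edge probabilities must lie in [0, 1]")
            object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "edge_index", index)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def with_probabilities(self, probabilities: Sequence[float]) -> "ProbabilisticNetwork":
        """Return a copy carrying the given probability vector."""
        return replace(self, probabilities=np.asarray(probabilities, dtype=float))

    def with_terminals(
        self, sources: Iterable[str], targets: Iterable[str]
    ) -> "ProbabilisticNetwork":
        """Return a copy with the source and target sets replaced."""
        return replace(self, sources=tuple(sources), targets=tuple(targets))

    def require_terminals(self) -> None:
        if not self.sources or not self.targets:
            raise ValidationError("source and target sets must be non-empty")

    def require_probabilities(self) -> np.ndarray:
        if self.probabilities is None:
            raise ValidationError("network has no edge probabilities set")
        return self.probabilities


@dataclass(frozen=True)
class ReachabilityMatrix:
    """An |S| x |T| matrix of probabilities, labelled by source/target node."""

    sources: tuple[str, ...]
    targets: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.sources), len(self.targets)):
            raise ValidationError(
                f"matrix shape {vals.shape} does not match "
                f"{len(self.sources)} sources x {len(self.targets)} targets"
            )
        if np.any(~np.isfinite(vals)) or np.any(vals < 0.0) or np.any(vals > 1.0):
            raise ValidationError("reachability entries must lie in [0, 1]")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sources), columns=list(self.targets))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReachabilityMatrix":
        return cls(
            sources=tuple(str(s) for s in frame.index),
            targets=tuple(str(t) for t in frame.columns),
            values=frame.to_numpy(dtype=float),
        )


def _parse_edge_line(
    fields: list[str], lineno: int, sif: bool
) -> tuple[str, str, float | None]:
    if sif:
        if len(fields) != 3:
            raise ParseError(f"line {lineno}: SIF lines need 3 fields, got {len(fields)}")
        return fields[0], fields[2], None
    if len(fields) == 2:
        return fields[0], fields[1], None
    if len(fields) == 3:
        try:
            p = float(fields[2])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad probability {fields[2]!r}") from exc
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"line {lineno}: probability {p} outside [0, 1]")
        return fields[0], fields[1], p
    raise ParseError(f"line {lineno}: expected 2 or 3 fields, got {len(fields)}")


def read_network(
    path: str | Path,
    *,
    sif: bool = False,
    sources: Iterable[str] = (),
    targets: Iterable[str] = (),
) -> ProbabilisticNetwork:
    """Read a directed edge list.

    Lines are whitespace- or tab-delimited ``source target [probability]``;
    ``#`` starts a comment.  With ``sif=True`` the three-column SIF dialect
    ``source relation target`` is accepted and the relation token ignored.
    Self-loops are dropped with a warning (they cannot affect s->t
    reachability for s != t); duplicate edges and out-of-range probabilities
    are errors.  Edge order in memory follows file order.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    probs: list[float | None] = []
    nodes: dict[str, None] = {}
    seen: set[tuple[str, str]] = set()
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            u, v, p = _parse_edge_line(line.split(), lineno, sif)
            if u == v:
                logger.warning("%s line %d: dropping self-loop (%s, %s)", path, lineno, u, v)
                nodes.setdefault(u, None)
                continue
            if (u, v) in seen:
                raise ValidationError(f"line {lineno}: duplicate edge ({u}, {v})")
            seen.add((u, v))
            edges.append((u, v))
            probs.append(p)
            nodes.setdefault(u, None)
            nodes.setdefault(v, None)
    has_probs = [p is not None for p in probs]
    if any(has_probs) and not all(has_probs):
        raise ParseError(f"{path}: mix of 2- and 3-field edge lines")
    probabilities = np.array(probs, dtype=float) if edges and all(has_probs) else None
    for node in list(sources) + list(targets):
        nodes.setdefault(node, None)
    return ProbabilisticNetwork(
        nodes=tuple(nodes),
        edges=tuple(edges),
        probabilities=probabilities,
        sources=tuple(sources),
        targets=tuple(targets),
    )


def write_probabilities(network: ProbabilisticNetwork, path: str | Path) -> None:
    """Write the network as a 3-column edge list, in edge order.

    Probabilities are serialized with :data:`PROB_DECIMALS` digits, so the
    file round-trips through :func:`read_network` at that precision.
    """
    path = Path(path)
    if network.n_edges == 0:
        path.write_text("")
        return
    probs = network.require_probabilities()
    with path.open("w") as handle:
        for (u, v), p in zip(network.edges, probs):
            handle.write(f"{u}\t{v}\t{p:.{PROB_DECIMALS}f}\n")


def read_matrix(path: str | Path) -> ReachabilityMatrix:
    """Read a labelled matrix: first row target labels, first column sources."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=r"\s+", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if frame.isna().any().any():
        raise ParseError(f"{path}: ragged or non-numeric table")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ParseError(f"{path}: non-numeric entries")
    return ReachabilityMatrix.from_frame(frame)


def write_matrix(matrix: ReachabilityMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format=f"%.{PROB_DECIMALS}f")


def read_node_list(path: str | Path) -> tuple[str, ...]:
    """Read one node identifier per line; ``#`` comments and blanks ignored."""
    out: list[str] = []
    with Path(path).open() as handle:
        for raw in handle:
            line = raw.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return tuple(out)


def write_node_list(nodes: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for node in nodes:
            handle.write(f"{node}\n")
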