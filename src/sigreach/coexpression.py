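"""Empirical reachability from gene expression.

The observed proxy for signal reachability between a receptor gene s and a
reporter gene t is the absolute Pearson correlation of their expression
profiles across samples: C[s,t] = |r(expr_s, expr_t)|.  Strong coexpression
(of either sign) is read as evidence that a signal travels between the pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import ParseError, ReachabilityMatrix, ValidationError

__all__ = ["ExpressionMatrix", "read_expression", "coexpression_matrix"]

MIN_SAMPLES = 3


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples expression table with no missing values."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            bad = self.data.index[self.data.isna().any(axis=1)].tolist()
            raise ValidationError(f"missing expression values for genes: {bad}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate gene labels in expression matrix")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(str(g) for g in self.data.index)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_expression(path: str | Path, mapping: str | Path | None = None) -> ExpressionMatrix:
    """Read a delimited table: first column gene labels, first row samples.

    `mapping`, if given, is a two-column probe -> symbol file applied to the
    gene labels before validation.
    """
    try:
        frame = pd.read_csv(Path(path), sep=r"\s+", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    frame.index = frame.index.astype(str)
    if mapping is not None:
        pairs = pd.read_csv(Path(mapping), sep=r"\s+", header=None, dtype=str)
        if pairs.shape[1] != 2:
            raise ParseError(f"{mapping}: mapping file must have two columns")
        rename = dict(zip(pairs[0], pairs[1]))
        frame.index = [rename.get(g, g) for g in frame.index]
    return ExpressionMatrix(frame)


def coexpression_matrix(
    expr: ExpressionMatrix, sources: Sequence[str], targets: Sequence[str]
) -> ReachabilityMatrix:
    """C[s,t] = |Pearson r| between source and target expression profiles."""
    if expr.n_samples < MIN_SAMPLES:
        raise ValidationError(
            f"need >= {MIN_SAMPLES} samples for correlation, got {expr.n_samples}"
        )
    genes = set(expr.genes)
    missing = [g for g in list(sources) + list(targets) if g not in genes]
    if missing:
        raise ValidationError(f"genes missing from expression matrix: {sorted(set(missing))}")
    needed = list(dict.fromkeys(list(sources) + list(targets)))
    values = expr.data.loc[needed].to_numpy(dtype=float)
    sd = values.std(axis=1)
    flat = [g for g, s in zip(needed, sd) if s == 0.0]
    if flat:
        raise ValidationError(f"zero-variance genes (correlation undefined): {flat}")
    corr = np.corrcoef(values)
    pos = {g: i for i, g in enumerate(needed)}
    out = np.empty((len(sources), len(targets)))
    for i, s in enumerate(sources):
        for j, t in enumerate(targets):
            out[i, j] = abs(corr[pos[s], pos[t]])
    # |r| can exceed 1 by rounding in degenerate collinear cases
    out = np.clip(out, 0.0, 1.0)
    return ReachabilityMatrix(tuple(sources), tuple(targets), out)
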