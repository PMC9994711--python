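"""Pearson coexpression of candidate TFs with the target gene and with
per-CRE H3K27ac enrichment.

Correlations are computed on log2(CPM + 1) by default, the scale on which
the downstream selection filter (r > 0.3) is applied.  Constant vectors
raise rather than silently returning 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.stats

from .formats_io import ExpressionMatrix, LookupMissError


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (constant input vector)."""


class InsufficientDataError(ValueError):
    """Fewer than 3 shared observations."""


@dataclass(frozen=True)
class CorrelationResult:
    tf: str
    partner: str
    r: float
    n: int
    log_scale: bool

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| > 1: {self.r}")
        if self.n < 3:
            raise ValueError(f"n must be >= 3, got {self.n}")


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; raises on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise InsufficientDataError(f"need >= 3 observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant vector")
    return float(scipy.stats.pearsonr(x, y).statistic)


def log_cpm(values: np.ndarray) -> np.ndarray:
    return np.log2(np.asarray(values, dtype=float) + 1.0)


def correlate_tf_target(
    expr: ExpressionMatrix,
    tf_ids: Sequence[str],
    target_id: str,
    log_transform: bool = True,
) -> list[CorrelationResult]:
    """One CorrelationResult per TF against the target gene.

    Expression is log2(CPM + 1)-transformed unless ``log_transform`` is
    False.  Samples are intersected complete-case (the matrix is dense, so
    this is all shared columns).
    """
    if target_id not in expr.data.index:
        raise LookupMissError(f"target gene {target_id!r} absent from matrix")
    missing = [t for t in tf_ids if t not in expr.data.index]
    if missing:
        raise LookupMissError(f"TF(s) absent from matrix: {missing}")
    target = expr.data.loc[target_id].to_numpy(dtype=float)
    if log_transform:
        target = log_cpm(target)
    n = len(target)
    results = []
    for tf in tf_ids:
        v = expr.data.loc[tf].to_numpy(dtype=float)
        if log_transform:
            v = log_cpm(v)
        results.append(
            CorrelationResult(tf=tf, partner=target_id, r=pearson(v, target),
                              n=n, log_scale=log_transform)
        )
    return results


def correlate_tf_h3k27ac(
    tf_expression: ExpressionMatrix,
    cre_enrichment: Mapping[str, Mapping[str, float]] | "pd.DataFrame",
    log_transform: bool = True,
) -> list[CorrelationResult]:
    """Pearson r per (TF, CRE) pair across shared cell types.

    ``cre_enrichment`` maps CRE id -> cell type -> H3K27ac enrichment (or
    an equivalent DataFrame with CRE rows and cell-type columns).  TF
    expression is log-transformed; enrichment is used raw.
    """
    import pandas as pd

    if not isinstance(cre_enrichment, pd.DataFrame):
        cre_enrichment = pd.DataFrame(cre_enrichment).T
    shared = [c for c in tf_expression.data.columns if c in cre_enrichment.columns]
    if len(shared) < 3:
        raise InsufficientDataError(
            f"need >= 3 shared cell types, got {len(shared)}"
        )
    results = []
    for tf in tf_expression.data.index:
        v = tf_expression.data.loc[tf, shared].to_numpy(dtype=float)
        if log_transform:
            v = log_cpm(v)
        for cre_id in cre_enrichment.index:
            e = cre_enrichment.loc[cre_id, shared].to_numpy(dtype=float)
            results.append(
                CorrelationResult(tf=str(tf), partner=str(cre_id),
                                  r=pearson(v, e), n=len(shared),
                                  log_scale=log_transform)
            )
    return results


def fisher_z_interval(r: float, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Fisher z confidence interval for a Pearson correlation."""
    if n < 4:
        raise InsufficientDataError("Fisher z interval needs n >= 4")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = scipy.stats.norm.ppf(0.5 + confidence / 2)
    return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))
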