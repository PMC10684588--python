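"""Invariant-protein median normalization of log2 intensity matrices.

Per-sample sequencing-depth-like offsets are estimated from a small panel of
*invariant* proteins -- proteins quantified in every sample whose log2
intensity varies least across samples -- and subtracted on the log2 scale
(equivalent to raw-scale division).  The offset of a sample is the median of
its invariant-protein log2 values minus the grand median of those per-sample
medians, so the normalization is median-anchored and idempotent.

The invariance ranking is pluggable: the default scores proteins by
cross-sample variance, but any callable mapping a complete log2 sub-matrix to
per-protein scores (smaller = more invariant) can be supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable


import pandas as pd

from .matrix import LOG2, IntensityMatrix


@dataclass
class NormalizationResult:
    normalized: IntensityMatrix
    invariant_proteins: list[str]
    sample_offsets: pd.Series  # sample id -> log2 offset subtracted


def variance_ranking(complete: pd.DataFrame) -> pd.Series:
    """Default invariance score: sample variance of log2 intensity (ddof=1)."""
    return complete.var(axis=1, ddof=1)


def select_invariant(
    matrix: IntensityMatrix,
    n_invariant: int = 100,
    ranking: Callable[[pd.DataFrame], pd.Series] = variance_ranking,
) -> list[str]:
    """Pick the ``n_invariant`` most stable fully-quantified proteins.

    Only proteins with 100% valid values are eligible.  Ties in the invariance
    score break deterministically by protein id.  If fewer complete proteins
    exist than requested, all of them are returned with a warning.
    """
    if n_invariant < 1:
        raise ValueError("n_invariant must be >= 1")
    if matrix.scale != LOG2:
        raise ValueError("select_invariant expects a log2 matrix")
    complete = matrix.values.dropna(axis=0)
    if complete.shape[0] == 0:
        raise ValueError("no protein is quantified in all samples")
    scores = ranking(complete)
    order = sorted(complete.index, key=lambda p: (scores[p], p))
    if len(order) < n_invariant:
        warnings.warn(
            f"only {len(order)} complete proteins available; requested "
            f"{n_invariant} invariant proteins — returning all of them",
            stacklevel=2,
        )
        return order
    return order[:n_invariant]


def normalize_median(
    matrix: IntensityMatrix, invariant: list[str]
) -> NormalizationResult:
    """Subtract per-sample median offsets computed on the invariant panel.

    offset(s) = median over invariant proteins of log2 intensity in s,
    minus the grand median of those per-sample medians.  After normalization
    every sample's invariant-protein median equals the grand median.
    """
    if not invariant:
        raise ValueError("invariant protein list is empty")
    missing_ids = [p for p in invariant if p not in matrix.values.index]
    if missing_ids:
        raise KeyError(f"invariant proteins absent from matrix: {missing_ids}")
    if matrix.scale != LOG2:
        raise ValueError("normalize_median expects a log2 matrix")

    panel = matrix.values.loc[invariant]
    empty = panel.columns[panel.notna().sum(axis=0) == 0].tolist()
    if empty:
        raise ValueError(
            f"samples with all invariant proteins missing: {empty}"
        )
    sample_medians = panel.median(axis=0, skipna=True)
    grand = float(sample_medians.median())
    offsets = sample_medians - grand
    normalized = matrix.values.sub(offsets, axis=1)
    return NormalizationResult(
        normalized=IntensityMatrix(normalized, scale=LOG2),
        invariant_proteins=list(invariant),
        sample_offsets=offsets,
    )


def normalize(
    matrix: IntensityMatrix,
    n_invariant: int = 100,
    ranking: Callable[[pd.DataFrame], pd.Series] = variance_ranking,
) -> NormalizationResult:
    """Select the invariant panel and normalize in one step."""
    invariant = select_invariant(matrix, n_invariant, ranking)
    return normalize_median(matrix, invariant)
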