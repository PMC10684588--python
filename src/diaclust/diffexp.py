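"""Unpaired Mann-Whitney differential expression with volcano classification.

All metastases are pooled against all primaries; the unpaired test is the
conservative choice when patients contribute unequal numbers of metastases
(a paired test would weight patients unevenly).  Fold change is the
difference of per-group means of log2 intensities over valid values, with the
convention log2FC = mean(primary) - mean(metastasis): negative values mean
up-regulation in metastases.

P-values are exact (full enumeration of group-label assignments, midrank U,
ties handled) for small combined sample sizes and tie-corrected normal
approximation with continuity correction otherwise.  Benjamini-Hochberg
adjusted values are reported alongside; classification uses the unadjusted p
so it can be compared against the orthogonal unsupervised clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import LOG2, IntensityMatrix, SampleSheet

UP_PRIMARY = "up_primary"
UP_METASTASIS = "up_metastasis"
NOT_SIGNIFICANT = "not_significant"

#: combined sample size up to which the exact permutation p-value is used
EXACT_LIMIT = 12


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Midrank Mann-Whitney U for x against y (ties count 1/2)."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def _exact_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided permutation p by full enumeration of label assignments.

    The test statistic is |U - n1*n2/2|; every C(n1+n2, n1) relabelling is
    enumerated, so ties are handled exactly.
    """
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    mid = n1 * n2 / 2.0
    t_obs = abs(u_obs - mid)
    total = comb(n1 + n2, n1)
    hits = 0
    idx_all = np.arange(n1 + n2)
    for xi in combinations(idx_all, n1):
        xi = np.array(xi)
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[xi] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if abs(u - mid) >= t_obs - 1e-12:
            hits += 1
    return hits / total


def _asymptotic_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / sqrt(var)
    z = max(z, 0.0)
    return float(2.0 * stats.norm.sf(z))


def mann_whitney_u(x, y, exact: bool | None = None) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two independent samples.

    Returns ``(U, p)`` where U is the midrank statistic for ``x`` versus
    ``y``.  ``exact=None`` (default) enumerates all label assignments when
    ``len(x) + len(y) <= 12`` and falls back to the tie-corrected normal
    approximation with continuity correction otherwise; pass ``True`` or
    ``False`` to force a method.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    if exact is None:
        exact = (x.size + y.size) <= EXACT_LIMIT
    p = _exact_p(x, y, u) if exact else _asymptotic_p(x, y, u)
    return u, min(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DEThresholds:
    p_threshold: float = 0.05
    lfc_threshold: float = 0.5


def classify(log2fc: float, p: float, thresholds: DEThresholds) -> str:
    if np.isnan(p):
        return NOT_SIGNIFICANT
    if p <= thresholds.p_threshold:
        if log2fc >= thresholds.lfc_threshold:
            return UP_PRIMARY
        if log2fc <= -thresholds.lfc_threshold:
            return UP_METASTASIS
    return NOT_SIGNIFICANT


def run_diffexp(
    matrix: IntensityMatrix,
    sheet: SampleSheet,
    p_threshold: float = 0.05,
    lfc_threshold: float = 0.5,
    exact: bool | None = None,
) -> pd.DataFrame:
    """Per-protein Mann-Whitney DE table on an unimputed log2 matrix.

    Proteins with fewer than two valid values in either group are emitted
    with NaN statistics and excluded from BH adjustment and significance
    counting.  Columns: n_primary, n_metastasis, mean_log2_primary,
    mean_log2_metastasis, log2fc, u_statistic, p_value, p_bh, de_class.
    """
    if matrix.scale != LOG2:
        raise ValueError("run_diffexp expects a log2 matrix")
    unknown = set(matrix.sample_ids) - set(sheet.sample_ids)
    if unknown:
        raise KeyError(f"samples missing from sheet: {sorted(unknown)}")
    prim = [s for s in sheet.samples_of("primary") if s in matrix.values.columns]
    met = [s for s in sheet.samples_of("metastasis") if s in matrix.values.columns]
    if not prim or not met:
        raise ValueError("both tissue groups must be represented in the matrix")

    thresholds = DEThresholds(p_threshold, lfc_threshold)
    records = []
    for pid, row in matrix.values.iterrows():
        xs = row[prim].dropna().to_numpy(dtype=float)
        ys = row[met].dropna().to_numpy(dtype=float)
        mean_p = float(xs.mean()) if xs.size else np.nan
        mean_m = float(ys.mean()) if ys.size else np.nan
        log2fc = mean_p - mean_m
        if xs.size < 2 or ys.size < 2:
            u, p = np.nan, np.nan
        else:
            u, p = mann_whitney_u(xs, ys, exact=exact)
        records.append(
            (pid, xs.size, ys.size, mean_p, mean_m, log2fc, u, p)
        )
    table = pd.DataFrame(
        records,
        columns=[
            "protein_id", "n_primary", "n_metastasis", "mean_log2_primary",
            "mean_log2_metastasis", "log2fc", "u_statistic", "p_value",
        ],
    ).set_index("protein_id")

    table["p_bh"] = np.nan
    tested = table["p_value"].notna()
    if tested.any():
        table.loc[tested, "p_bh"] = bh_adjust(table.loc[tested, "p_value"])
    table["de_class"] = [
        classify(fc, p, thresholds)
        for fc, p in zip(table["log2fc"], table["p_value"])
    ]
    return table


def significant_ids(
    table: pd.DataFrame,
    p_threshold: float = 0.05,
    lfc_threshold: float | None = None,
) -> list[str]:
    """Proteins passing the p cut (and, optionally, the |log2FC| cut)."""
    mask = table["p_value"].notna() & (table["p_value"] <= p_threshold)
    if lfc_threshold is not None:
        mask &= table["log2fc"].abs() >= lfc_threshold
    return list(table.index[mask])
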