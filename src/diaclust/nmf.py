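"""Consensus non-negative matrix factorization with rank selection.

Stochastic NMF (multiplicative updates for the squared Frobenius loss) is
restarted many times per rank; run-to-run agreement of the sample clustering
is summarized in a consensus matrix whose cophenetic correlation and
dispersion coefficient guide rank selection.  Per-protein cluster relevance
is scored as one minus the normalized entropy of the basis-weight profile
(near 1 for cluster-specific proteins, 0 for uninformative ones).  A PCA
embedding of the samples is provided for visual comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from sklearn.decomposition import PCA

from .matrix import LOG2, IntensityMatrix

# ---------------------------------------------------------------------------
# Single NMF fit: Lee-Seung multiplicative updates, squared Frobenius loss.
# Hand-rolled (rather than a library call) so the per-iteration error path is
# observable; monotone non-increase of the error is a tested property.
# ---------------------------------------------------------------------------

_EPS = 1e-12


def nmf_fit(
    V: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Factor a nonnegative matrix V (features x samples) as W @ H.

    Multiplicative updates minimize ||V - WH||_F^2; the returned error list
    holds the Frobenius error after each iteration (non-increasing).  Stops
    when the relative improvement drops below ``tol`` or at ``max_iter``.
    """
    V = np.asarray(V, dtype=float)
    if np.isnan(V).any():
        raise ValueError("V contains missing values; impute before factoring")
    if (V < 0).any():
        raise ValueError(
            "V contains negative entries; shift or re-impute so V >= 0"
        )
    n, m = V.shape
    if not 1 <= k < min(n, m):
        raise ValueError(f"rank k={k} must satisfy 1 <= k < min{V.shape}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / k) if V.mean() > 0 else 1.0
    W = rng.uniform(0, 1, size=(n, k)) * scale
    H = rng.uniform(0, 1, size=(k, m)) * scale

    errors: list[float] = []
    prev = np.linalg.norm(V - W @ H)
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        err = np.linalg.norm(V - W @ H)
        errors.append(float(err))
        if prev > 0 and (prev - err) / prev < tol:
            break
        prev = err
    return W, H, errors


# ---------------------------------------------------------------------------
# Consensus clustering over restarts
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    rank: int
    consensus: pd.DataFrame          # sample x sample, entries in [0, 1]
    cophenetic: float
    dispersion: float
    labels: pd.Series                # sample id -> cluster (1..k)
    best_W: np.ndarray
    best_H: np.ndarray
    n_runs: int
    reconstruction_errors: list[float] = field(default_factory=list)


def _component_assignment(W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Dominant component per sample, invariant to factor rescaling.

    W columns are normalized to unit L2 norm with the scale absorbed into H
    before the argmax, so the diagonal rescaling freedom of (W, H) cannot
    flip assignments.
    """
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    return np.argmax(H * norms[:, None], axis=0)


def _connectivity(W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """1 where two samples share the dominant component, else 0."""
    assign = _component_assignment(W, H)
    return (assign[:, None] == assign[None, :]).astype(float)


def dispersion(consensus: np.ndarray | pd.DataFrame) -> float:
    """Dispersion coefficient (1/n^2) sum 4 (C_ij - 1/2)^2.

    Equals 1 when every entry is 0 or 1 (perfectly reproducible clustering)
    and 0 for the maximally ambiguous all-1/2 matrix.
    """
    C = np.asarray(consensus, dtype=float)
    n = C.shape[0]
    return float((4.0 * (C - 0.5) ** 2).sum() / (n * n))


def cophenetic_correlation(consensus: np.ndarray | pd.DataFrame) -> float:
    """Pearson correlation between consensus distances (1 - C) and the
    cophenetic distances of their average-linkage dendrogram.

    Returns NaN with a warning when the consensus distances are constant
    (degenerate: correlation undefined).
    """
    C = np.asarray(consensus, dtype=float)
    d = squareform(1.0 - C, checks=False)
    if np.allclose(d, d[0]) if d.size else True:
        warnings.warn("constant consensus distances; cophenetic correlation "
                      "undefined", stacklevel=2)
        return float("nan")
    Z = average(d)
    coph_d = cophenet(Z)
    if np.allclose(coph_d, coph_d[0]):
        warnings.warn("constant cophenetic distances; correlation undefined",
                      stacklevel=2)
        return float("nan")
    r, _ = pearsonr(d, coph_d)
    return float(r)


def consensus_cluster(
    V: np.ndarray,
    sample_ids: list[str],
    k: int,
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ConsensusResult:
    """Average the co-clustering indicator over ``n_runs`` seeded NMF restarts.

    Sample labels come from an average-linkage cut of the consensus
    dissimilarity (robust to run-to-run component label switching); the
    returned basis/coefficients are those of the lowest-error run.  Fewer
    than ``k`` distinct labels can occur when components collapse.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 for a meaningful consensus")
    n_samples = V.shape[1]
    consensus = np.zeros((n_samples, n_samples))
    best = None
    final_errors: list[float] = []
    for r in range(n_runs):
        W, H, errs = nmf_fit(V, k, seed=seed + r, max_iter=max_iter, tol=tol)
        consensus += _connectivity(W, H)
        final_errors.append(errs[-1])
        if best is None or errs[-1] < best[2]:
            best = (W, H, errs[-1])
    consensus /= n_runs
    np.fill_diagonal(consensus, 1.0)

    d = squareform(1.0 - consensus, checks=False)
    Z = average(d)
    labels = fcluster(Z, t=k, criterion="maxclust")

    C = pd.DataFrame(consensus, index=sample_ids, columns=sample_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coph = cophenetic_correlation(consensus)
    return ConsensusResult(
        rank=k,
        consensus=C,
        cophenetic=coph,
        dispersion=dispersion(consensus),
        labels=pd.Series(labels, index=sample_ids, name="cluster"),
        best_W=best[0],
        best_H=best[1],
        n_runs=n_runs,
        reconstruction_errors=final_errors,
    )


def sweep_ranks(
    V: np.ndarray,
    sample_ids: list[str],
    k_range: range | list[int] = range(2, 11),
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> list[ConsensusResult]:
    """Consensus-cluster at every rank in ``k_range`` (default 2..10)."""
    return [
        consensus_cluster(V, sample_ids, k, n_runs=n_runs, seed=seed,
                          max_iter=max_iter, tol=tol)
        for k in k_range
    ]


def select_rank(sweep: list[ConsensusResult]) -> int:
    """Pick the factorization rank from a contiguous sweep.

    Returns the smallest interior k that is a strict local maximum of BOTH
    the cophenetic-correlation and dispersion sequences; when no such k
    exists, the k with the highest cophenetic correlation (smallest on ties),
    with a warning.  Sweeps shorter than three ranks fall back to the global
    cophenetic maximum.
    """
    if not sweep:
        raise ValueError("empty sweep")
    ks = [r.rank for r in sweep]
    if ks != list(range(ks[0], ks[0] + len(ks))):
        raise ValueError("sweep must cover a contiguous k range")
    coph = np.array([r.cophenetic for r in sweep])
    disp = np.array([r.dispersion for r in sweep])
    if len(sweep) >= 3:
        for i in range(1, len(sweep) - 1):
            coph_peak = coph[i] > coph[i - 1] and coph[i] > coph[i + 1]
            disp_peak = disp[i] > disp[i - 1] and disp[i] > disp[i + 1]
            if coph_peak and disp_peak:
                return ks[i]
        warnings.warn("no joint local maximum of cophenetic correlation and "
                      "dispersion; falling back to the global cophenetic "
                      "maximum", stacklevel=2)
    else:
        warnings.warn("sweep shorter than 3 ranks; using the global "
                      "cophenetic maximum", stacklevel=2)
    return ks[int(np.nanargmax(coph))]


# ---------------------------------------------------------------------------
# Kim-Park feature relevance
# ---------------------------------------------------------------------------

@dataclass
class RelevanceScores:
    scores: pd.Series                # protein id -> score in [0, 1]
    percentile_threshold: float
    threshold_value: float
    selected: list[str]              # score strictly above the percentile


def relevance_scores(
    W: np.ndarray,
    protein_ids: list[str],
    percentile_threshold: float = 90.0,
) -> RelevanceScores:
    """Entropy-based cluster-relevance of each basis row.

    With p(i,q) = W_iq / sum_q' W_iq', the score of protein i is
    1 + (1/log2 k) * sum_q p(i,q) log2 p(i,q): 1 for a one-hot profile
    (fully cluster-specific), 0 for a uniform profile.  All-zero rows score 0
    with a warning.  ``selected`` holds proteins whose score is strictly
    above the linear-interpolation percentile of all scores.
    """
    W = np.asarray(W, dtype=float)
    if (W < 0).any():
        raise ValueError("W must be nonnegative")
    k = W.shape[1]
    if k < 2:
        raise ValueError("relevance scores need k >= 2 components")
    row_sums = W.sum(axis=1)
    zero_rows = row_sums == 0
    if zero_rows.any():
        warnings.warn(f"{int(zero_rows.sum())} all-zero basis rows scored 0",
                      stacklevel=2)
    p = np.zeros_like(W)
    nz = ~zero_rows
    p[nz] = W[nz] / row_sums[nz, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    scores = 1.0 + plogp.sum(axis=1) / np.log2(k)
    scores[zero_rows] = 0.0
    scores = np.clip(scores, 0.0, 1.0)

    series = pd.Series(scores, index=protein_ids, name="relevance")
    cut = float(np.percentile(scores, percentile_threshold))
    selected = list(series.index[series > cut])
    return RelevanceScores(
        scores=series,
        percentile_threshold=percentile_threshold,
        threshold_value=cut,
        selected=selected,
    )


# ---------------------------------------------------------------------------
# PCA embedding
# ---------------------------------------------------------------------------

def pca_embed(
    matrix: IntensityMatrix,
    impute: bool = True,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-space PCA of a log2 matrix.

    ``impute=False`` restricts to proteins quantified in every sample (the
    100%-valid-value variant); with ``impute=True`` the matrix must already be
    complete (mean-imputed upstream).  Component signs are fixed so the
    largest-magnitude loading of each component is positive, making the
    embedding deterministic.  Returns (scores indexed by sample, explained
    variance fractions).
    """
    if matrix.scale != LOG2:
        raise ValueError("pca_embed expects a log2 matrix")
    vals = matrix.values
    if impute:
        if vals.isna().any().any():
            raise ValueError("impute=True requires a complete (imputed) matrix")
        data = vals
    else:
        data = vals.dropna(axis=0)
        if data.shape[0] < 2:
            raise ValueError(
                "fewer than 2 complete proteins; cannot run unimputed PCA"
            )
    X = data.to_numpy(dtype=float).T  # samples x proteins
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    # deterministic sign: largest |loading| positive per component
    for j in range(n_components):
        comp = pca.components_[j]
        if comp[np.argmax(np.abs(comp))] < 0:
            scores[:, j] *= -1
    out = pd.DataFrame(
        scores,
        index=vals.columns,
        columns=[f"PC{j + 1}" for j in range(n_components)],
    )
    return out, pca.explained_variance_ratio_
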