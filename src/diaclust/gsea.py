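"""Weighted gene-set enrichment with phenotype-label permutation.

Genes (protein ids, unless a mapping is supplied) are ranked by a pooled
two-sample t statistic on the primary-vs-metastasis contrast; a weighted
Kolmogorov-Smirnov running sum yields the enrichment score (ES) per set; the
null distribution comes from re-ranking after shuffling the tissue labels.
Nominal p uses the (1+b)/(1+m) convention over same-sign permutation scores,
NES divides ES by the mean same-sign permuted magnitude, and FDR q follows
the standard positive/negative NES pooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import LOG2, IntensityMatrix, SampleSheet

_VAR_FLOOR = 1e-8


class GMTParseError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    descriptions: dict[str, str]

    def __len__(self) -> int:
        return len(self.sets)

    def filtered(self, genes: set[str], min_size: int, max_size: int
                 ) -> "GeneSetCollection":
        """Intersect with measured genes and apply the size window."""
        kept, desc = {}, {}
        for name, members in self.sets.items():
            inter = members & genes
            if min_size <= len(inter) <= max_size:
                kept[name] = inter
                desc[name] = self.descriptions.get(name, "")
        return GeneSetCollection(kept, desc)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: tab-separated name, description, members..."""
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GMTParseError(
                    f"line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            name = parts[0]
            if name in sets:
                raise GMTParseError(f"line {lineno}: duplicate set name {name!r}")
            members = {m for m in parts[2:] if m}
            if not members:
                raise GMTParseError(f"line {lineno}: set {name!r} has no members")
            sets[name] = members
            desc[name] = parts[1]
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Ranking metric
# ---------------------------------------------------------------------------

def _t_statistics(
    values: np.ndarray, is_primary: np.ndarray, is_met: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled-variance two-sample t per row (primary - metastasis).

    Rows with fewer than 2 valid values in either group get NaN.  A small
    variance floor keeps the statistic finite on (near-)constant rows.
    """
    valid = ~np.isnan(values)
    n1 = (valid & is_primary).sum(axis=1)
    n2 = (valid & is_met).sum(axis=1)

    def _group(mask):
        v = np.where(valid & mask, values, 0.0)
        n = (valid & mask).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = v.sum(axis=1) / n
            ss = np.where(valid & mask, (values - mean[:, None]) ** 2, 0.0).sum(axis=1)
        return mean, ss, n

    m1, ss1, f1 = _group(is_primary)
    m2, ss2, f2 = _group(is_met)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_var = (ss1 + ss2) / (f1 + f2 - 2)
        pooled_var = np.maximum(pooled_var, _VAR_FLOOR)
        t = (m1 - m2) / np.sqrt(pooled_var * (1.0 / f1 + 1.0 / f2))
    ok = (n1 >= 2) & (n2 >= 2)
    t = np.where(ok, t, np.nan)
    return t, ok


def rank_by_t(
    matrix: IntensityMatrix, sheet: SampleSheet
) -> pd.Series:
    """Rank genes by the pooled two-sample t (primary minus metastasis).

    Returns a Series (gene -> t) sorted descending, ties broken by gene id.
    Genes with < 2 valid values in either group are dropped with a warning.
    """
    if matrix.scale != LOG2:
        raise ValueError("rank_by_t expects a log2 matrix")
    cols = matrix.sample_ids
    tissue = np.array([sheet.tissue_of(s) for s in cols])
    is_primary = tissue == "primary"
    is_met = tissue == "metastasis"
    if not is_primary.any() or not is_met.any():
        raise ValueError("both tissue groups must be present")
    t, ok = _t_statistics(
        matrix.values.to_numpy(dtype=float), is_primary[None, :], is_met[None, :]
    )
    genes = np.asarray(matrix.protein_ids)
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} genes dropped from ranking (<2 valid values "
            "in a group)", stacklevel=2)
    series = pd.Series(t[ok], index=genes[ok])
    order = sorted(series.index, key=lambda g: (-series[g], g))
    return series.loc[order]


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

def enrichment_score(
    ranked: pd.Series, members: set[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS running-sum enrichment score of one set.

    Hits add |t|^weight normalized by the total hit weight; misses subtract
    1/(N - N_hits).  ES is the running-sum value of largest magnitude.
    """
    genes = ranked.index.to_numpy()
    stats = ranked.to_numpy(dtype=float)
    hit = np.isin(genes, list(members))
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("gene set shares no genes with the ranking")
    n = len(genes)
    w = np.abs(stats) ** weight
    hit_weight = w[hit].sum()
    step = np.where(hit, np.where(hit_weight > 0, w / max(hit_weight, _VAR_FLOOR), 0.0),
                    0.0)
    if n == n_hits:
        miss_step = 0.0
    else:
        miss_step = 1.0 / (n - n_hits)
    increments = np.where(hit, step, -miss_step)
    running = np.cumsum(increments)
    es = running[int(np.argmax(np.abs(running)))]
    return float(es), running


# ---------------------------------------------------------------------------
# Phenotype permutation
# ---------------------------------------------------------------------------

def _es_per_set(
    values: np.ndarray,
    genes: np.ndarray,
    is_primary: np.ndarray,
    is_met: np.ndarray,
    sets: dict[str, set[str]],
    weight: float,
) -> dict[str, float]:
    t, ok = _t_statistics(values, is_primary[None, :], is_met[None, :])
    series = pd.Series(t[ok], index=genes[ok])
    order = sorted(series.index, key=lambda g: (-series[g], g))
    ranked = series.loc[order]
    out = {}
    for name, members in sets.items():
        try:
            es, _ = enrichment_score(ranked, members, weight)
        except ValueError:
            es = np.nan
        out[name] = es
    return out


def permutation_gsea(
    matrix: IntensityMatrix,
    sheet: SampleSheet,
    collection: GeneSetCollection,
    n_perm: int = 100,
    seed: int = 7,
    min_size: int = 5,
    max_size: int = 500,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Phenotype-permutation GSEA on the primary-vs-metastasis contrast.

    Tissue labels are shuffled ``n_perm`` times; the t ranking and every
    set's ES are recomputed per shuffle.  Nominal p = (1 + b) / (1 + m) over
    same-sign permutation scores; NES = ES / mean(|same-sign permuted ES|);
    FDR q compares the observed NES against the pooled permuted NES of the
    same sign.  Columns: es, nes, p_nominal, fdr_q, size, leading_edge.
    """
    if n_perm < 10:
        raise ValueError("n_perm < 10 gives an unusably unstable null")
    if matrix.scale != LOG2:
        raise ValueError("permutation_gsea expects a log2 matrix")
    cols = matrix.sample_ids
    tissue = np.array([sheet.tissue_of(s) for s in cols])
    is_primary = tissue == "primary"
    is_met = tissue == "metastasis"
    if not is_primary.any() or not is_met.any():
        raise ValueError("both tissue groups must be present")

    values = matrix.values.to_numpy(dtype=float)
    genes = np.asarray(matrix.protein_ids)
    filtered = collection.filtered(set(genes), min_size, max_size)
    if not filtered.sets:
        raise ValueError("no gene set survives the size filter")

    observed = _es_per_set(values, genes, is_primary, is_met,
                           filtered.sets, weight)

    # leading edge on the observed ranking
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ranked = rank_by_t(matrix, sheet)
    leading: dict[str, list[str]] = {}
    for name, members in filtered.sets.items():
        es, running = enrichment_score(ranked, members, weight)
        peak = int(np.argmax(np.abs(running)))
        genes_arr = ranked.index.to_numpy()
        if es >= 0:
            edge = [g for g in genes_arr[: peak + 1] if g in members]
        else:
            edge = [g for g in genes_arr[peak:] if g in members]
        leading[name] = edge

    rng = np.random.default_rng(seed)
    n_samples = len(cols)
    n_primary = int(is_primary.sum())
    perm_scores = {name: [] for name in filtered.sets}
    for _ in range(n_perm):
        idx = rng.permutation(n_samples)
        perm_primary = np.zeros(n_samples, dtype=bool)
        perm_primary[idx[:n_primary]] = True
        perm_met = ~perm_primary
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            es_map = _es_per_set(values, genes, perm_primary, perm_met,
                                 filtered.sets, weight)
        for name, es in es_map.items():
            if not np.isnan(es):
                perm_scores[name].append(es)

    # NES for observed and permuted scores (normalize by same-sign mean |ES|)
    def _nes(es: float, null: np.ndarray) -> float:
        same = null[null * es >= 0] if es != 0 else null
        denom = np.abs(same).mean() if same.size else np.nan
        return es / denom if denom and denom > 0 else np.nan

    records = []
    all_perm_nes: list[float] = []
    per_set_null_nes: dict[str, np.ndarray] = {}
    for name in filtered.sets:
        null = np.asarray(perm_scores[name], dtype=float)
        null_nes = np.array([_nes(e, null) for e in null])
        per_set_null_nes[name] = null_nes
        all_perm_nes.extend(null_nes[~np.isnan(null_nes)])
    all_perm_nes = np.asarray(all_perm_nes, dtype=float)

    for name, members in filtered.sets.items():
        es = observed[name]
        null = np.asarray(perm_scores[name], dtype=float)
        same_sign = null[null * es >= 0] if es != 0 else null
        b = int((np.abs(same_sign) >= abs(es) - 1e-12).sum())
        p_nom = (1 + b) / (1 + len(same_sign))
        nes = _nes(es, null)
        records.append((name, es, nes, p_nom, len(members),
                        ",".join(leading[name])))

    table = pd.DataFrame(
        records,
        columns=["set_name", "es", "nes", "p_nominal", "size", "leading_edge"],
    ).set_index("set_name")

    # FDR q: fraction of pooled same-sign permuted NES at least as extreme,
    # over the fraction of observed same-sign NES at least as extreme
    obs_nes = table["nes"].to_numpy(dtype=float)
    q = np.full(len(table), np.nan)
    for i, nes in enumerate(obs_nes):
        if np.isnan(nes):
            continue
        if nes >= 0:
            null_pool = all_perm_nes[all_perm_nes >= 0]
            obs_pool = obs_nes[obs_nes >= 0]
            num = (null_pool >= nes).mean() if null_pool.size else np.nan
            den = (obs_pool >= nes).mean() if obs_pool.size else np.nan
        else:
            null_pool = all_perm_nes[all_perm_nes < 0]
            obs_pool = obs_nes[obs_nes < 0]
            num = (null_pool <= nes).mean() if null_pool.size else np.nan
            den = (obs_pool <= nes).mean() if obs_pool.size else np.nan
        if den and not np.isnan(num):
            q[i] = min(num / den, 1.0)
    table["fdr_q"] = q
    return table.sort_values(["fdr_q", "nes"], ascending=[True, False])


def apply_gene_mapping(
    matrix: IntensityMatrix, mapping: pd.DataFrame | None
) -> IntensityMatrix:
    """Rename protein ids to gene symbols via a two-column mapping table.

    With ``mapping=None`` the identity is used (protein ids double as gene
    symbols).  Duplicate target symbols keep the first occurrence.
    """
    if mapping is None:
        return matrix
    if mapping.shape[1] < 2:
        raise ValueError("mapping needs two columns: protein_id, gene_symbol")
    lut = dict(zip(mapping.iloc[:, 0].astype(str), mapping.iloc[:, 1].astype(str)))
    renamed = matrix.values.rename(index=lambda p: lut.get(p, p))
    renamed = renamed[~renamed.index.duplicated(keep="first")]
    return IntensityMatrix(renamed, matrix.scale)
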