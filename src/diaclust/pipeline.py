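"""End-to-end pipeline: filter -> log2 -> normalize -> {DE, GSEA} on
unimputed data and {impute -> PCA, consensus NMF -> rank -> relevance} ->
candidate intersection.

Every run writes its tables plus a JSON manifest echoing the resolved
configuration, stage record counts and timings, so a run can be reproduced
from its manifest alone.  Imputation happens only on the branch feeding PCA
and clustering; the differential-expression and GSEA branch always consumes
unimputed values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import candidates as cand
from . import diffexp as de
from . import gsea as gs
from . import matrix as mio
from . import nmf
from .normalize import NormalizationResult, normalize as normalize_matrix

log = logging.getLogger("diaclust")


@dataclass
class PipelineConfig:
    """Resolved settings of one analysis run (defaults = study settings)."""

    matrix_path: str = ""
    sheet_path: str = ""
    gmt_path: str = ""
    output_dir: str = "diaclust_run"
    min_valid_fraction: float = 0.5
    n_invariant: int = 100
    p_threshold: float = 0.05
    lfc_threshold: float = 0.5
    k_min: int = 2
    k_max: int = 10
    n_runs: int = 50
    nmf_max_iter: int = 500
    relevance_percentile: float = 90.0
    n_perm: int = 100
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    seed: int = 7
    impute_per_protein: bool = True
    candidate_use_lfc_gate: bool = False

    # per-stage seeds fan out from the root seed by fixed offsets so each
    # stage is independently reproducible
    @property
    def nmf_seed(self) -> int:
        return self.seed + 100

    @property
    def gsea_seed(self) -> int:
        return self.seed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RunResult:
    """In-memory handles to everything a full run produced."""

    config: PipelineConfig
    filtered: mio.IntensityMatrix
    normalized: mio.IntensityMatrix
    sample_offsets: pd.Series
    invariant_proteins: list[str]
    de_table: pd.DataFrame
    sweep: list[nmf.ConsensusResult]
    selected_k: int
    consensus: nmf.ConsensusResult
    relevance: nmf.RelevanceScores
    pca_scores: pd.DataFrame
    pca_variance: np.ndarray
    pca_unimputed_scores: pd.DataFrame | None
    n_complete_proteins: int
    candidates: pd.DataFrame
    gsea_table: pd.DataFrame | None
    manifest: dict


def prepare_nmf_input(matrix: mio.IntensityMatrix) -> tuple[np.ndarray, float]:
    """Anchor an imputed log2 matrix at zero minimum for NMF.

    NMF needs V >= 0, and its parts-based decomposition is only
    well-identified when the nonnegativity constraint binds -- a large shared
    offset (log2 intensities sit far above zero) leaves rotational freedom
    that destabilizes run-to-run cluster assignment.  Subtracting the global
    minimum preserves every between-sample and between-protein difference
    while anchoring the scale at zero.  Returns (V, shift subtracted).
    """
    vals = matrix.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("NMF input must be imputed (no missing values)")
    shift = float(vals.min())
    return vals - shift, shift


def preprocess(
    matrix: mio.IntensityMatrix,
    config: PipelineConfig,
) -> tuple[mio.IntensityMatrix, NormalizationResult]:
    """Filter by valid fraction, log2-transform, normalize. Returns
    (normalized unimputed log2 matrix, normalization details)."""
    filtered = mio.filter_valid(matrix, config.min_valid_fraction)
    logged = mio.log2_transform(filtered) if filtered.scale == mio.RAW else filtered
    result = normalize_matrix(logged, n_invariant=config.n_invariant)
    return result.normalized, result


def run_all(
    config: PipelineConfig,
    matrix: mio.IntensityMatrix | None = None,
    sheet: mio.SampleSheet | None = None,
    collection: gs.GeneSetCollection | None = None,
    write: bool = True,
) -> RunResult:
    """Execute the full matched-cohort analysis.

    Inputs may be passed in memory or read from the configured paths.  With
    ``write=True`` all tables land under ``config.output_dir`` along with a
    manifest; numeric outputs are byte-identical across reruns of the same
    config and seed.
    """
    t0 = time.time()
    stages: list[dict] = []

    def _stage(name: str, **info):
        entry = {"stage": name, "elapsed_s": round(time.time() - t0, 3), **info}
        stages.append(entry)
        log.info("stage %s done: %s", name, info)

    if matrix is None:
        matrix = mio.read_matrix(config.matrix_path)
    if sheet is None:
        sheet = mio.read_sample_sheet(config.sheet_path)
    if collection is None and config.gmt_path:
        collection = gs.read_gmt(config.gmt_path)

    counts, median_cov = mio.coverage_summary(matrix)
    filtered = mio.filter_valid(matrix, config.min_valid_fraction)
    _stage("filter", n_input=matrix.n_proteins, n_retained=filtered.n_proteins,
           median_coverage=median_cov)

    logged = (mio.log2_transform(filtered) if filtered.scale == mio.RAW
              else filtered)
    norm_result = normalize_matrix(logged, n_invariant=config.n_invariant)
    normalized = norm_result.normalized
    _stage("normalize", n_invariant=len(norm_result.invariant_proteins))

    de_table = de.run_diffexp(
        normalized, sheet,
        p_threshold=config.p_threshold, lfc_threshold=config.lfc_threshold,
    )
    sig = de.significant_ids(de_table, config.p_threshold)
    sig_fc = de.significant_ids(de_table, config.p_threshold,
                                config.lfc_threshold)
    _stage("diffexp", n_tested=int(de_table["p_value"].notna().sum()),
           n_significant=len(sig), n_fc_qualified=len(sig_fc))

    gsea_table = None
    if collection is not None:
        gsea_table = gs.permutation_gsea(
            normalized, sheet, collection,
            n_perm=config.n_perm, seed=config.gsea_seed,
            min_size=config.gsea_min_size, max_size=config.gsea_max_size,
        )
        _stage("gsea", n_sets=len(gsea_table))

    imputed = mio.impute_mean(normalized, per_protein=config.impute_per_protein)
    V, shift = prepare_nmf_input(imputed)
    sweep = nmf.sweep_ranks(
        V, imputed.sample_ids, range(config.k_min, config.k_max + 1),
        n_runs=config.n_runs, seed=config.nmf_seed,
        max_iter=config.nmf_max_iter,
    )
    selected_k = nmf.select_rank(sweep)
    consensus = sweep[selected_k - config.k_min]
    relevance = nmf.relevance_scores(
        consensus.best_W, imputed.protein_ids,
        percentile_threshold=config.relevance_percentile,
    )
    _stage("cluster", selected_k=selected_k, nmf_shift=shift,
           n_relevant=len(relevance.selected))

    pca_scores, pca_var = nmf.pca_embed(imputed, impute=True)
    complete = normalized.values.dropna(axis=0)
    n_complete = int(complete.shape[0])
    pca_unimp = None
    if n_complete >= 2:
        pca_unimp, _ = nmf.pca_embed(normalized, impute=False)
    _stage("pca", n_complete_proteins=n_complete)

    pool = sig_fc if config.candidate_use_lfc_gate else sig
    cand_table = cand.intersect_candidates(
        de_table, pool, relevance.selected, relevance.scores
    )
    _stage("candidates", n_candidates=len(cand_table))

    manifest = {
        "config": config.to_dict(),
        "stages": stages,
        "coverage_median": median_cov,
        "nmf_input_shift": shift,
        "selected_k": selected_k,
        "complete_protein_count_unimputed_pca": n_complete,
    }

    result = RunResult(
        config=config, filtered=filtered, normalized=normalized,
        sample_offsets=norm_result.sample_offsets,
        invariant_proteins=norm_result.invariant_proteins,
        de_table=de_table, sweep=sweep, selected_k=selected_k,
        consensus=consensus, relevance=relevance,
        pca_scores=pca_scores, pca_variance=pca_var,
        pca_unimputed_scores=pca_unimp, n_complete_proteins=n_complete,
        candidates=cand_table, gsea_table=gsea_table, manifest=manifest,
    )
    if write:
        write_run(result, Path(config.output_dir))
    return result


def sweep_table(sweep: list[nmf.ConsensusResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "k": [r.rank for r in sweep],
            "cophenetic": [r.cophenetic for r in sweep],
            "dispersion": [r.dispersion for r in sweep],
            "mean_reconstruction_error": [
                float(np.mean(r.reconstruction_errors)) for r in sweep
            ],
        }
    ).set_index("k")


def write_run(result: RunResult, outdir: Path) -> None:
    """Write all tables, the manifest and a log to the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_matrix(result.normalized, outdir / "normalized_matrix.tsv")
    result.sample_offsets.rename("log2_offset").to_csv(
        outdir / "sample_offsets.tsv", sep="\t", header=True,
        index_label="sample_id")
    pd.Series(result.invariant_proteins, name="protein_id").to_csv(
        outdir / "invariant_proteins.tsv", sep="\t", index=False)
    result.de_table.to_csv(outdir / "diffexp.tsv", sep="\t")
    sweep_table(result.sweep).to_csv(outdir / "nmf_sweep.tsv", sep="\t")
    result.consensus.consensus.to_csv(
        outdir / f"consensus_k{result.selected_k}.tsv", sep="\t")
    result.consensus.labels.to_csv(
        outdir / "cluster_labels.tsv", sep="\t", header=True,
        index_label="sample_id")
    rel = result.relevance.scores.to_frame()
    rel["selected"] = rel.index.isin(result.relevance.selected).astype(int)
    rel.to_csv(outdir / "relevance_scores.tsv", sep="\t",
               index_label="protein_id")
    result.pca_scores.to_csv(outdir / "pca_scores.tsv", sep="\t",
                             index_label="sample_id")
    if result.pca_unimputed_scores is not None:
        result.pca_unimputed_scores.to_csv(
            outdir / "pca_scores_unimputed.tsv", sep="\t",
            index_label="sample_id")
    result.candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    if result.gsea_table is not None:
        result.gsea_table.to_csv(outdir / "gsea.tsv", sep="\t")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=float)
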