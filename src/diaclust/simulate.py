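"""Synthetic FFPE-DIA cohort generator with known ground truth.

Emulates a matched primary/metastasis cohort: each patient contributes one
primary tumor sample and one or more distant metastases.  Protein log2
abundances are Gaussian (log-normal on the raw scale) with per-sample depth
offsets; differential-expression effects are planted additively on the log2
scale for metastasis samples, and cluster structure on a disjoint protein
block.  Missingness combines a random (MAR) component with an
intensity-dependent logistic dropout (MNAR), applied after effect planting so
dropout interacts with group differences as it does in degraded FFPE
material.

Defaults reproduce the regime of a 14-patient / 38-sample cohort with ~1405
proteins and a median of ~1000 quantified per sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .matrix import RAW, IntensityMatrix, SampleSheet

LOCALIZATIONS = ("ADR", "HEP", "KID", "OSS", "OTH")


class SimConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    All effect sizes and scales are in log2 units.  ``de_effect`` is the shift
    applied to metastasis samples of planted DE proteins (positive = higher in
    metastases).  ``mnar_midpoint`` is the log2 intensity at which the
    intensity-dependent dropout probability is 0.5; ``-inf`` disables the MNAR
    component entirely.
    """

    n_patients: int = 14
    metastases_per_patient: tuple[int, int] = (1, 4)
    total_metastases: int | None = 24
    n_proteins: int = 1405
    n_de_proteins: int = 100
    de_effect: float = 1.0
    n_cluster_proteins: int = 60
    n_clusters: int = 3
    cluster_effect: float = 2.0
    base_mean: float = 20.0
    base_sd: float = 2.0
    sample_offset_sd: float = 0.3
    mnar_midpoint: float = 18.7
    mnar_slope: float = 2.5
    mar_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_proteins", "n_de_proteins",
                     "n_cluster_proteins", "n_clusters"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        lo, hi = self.metastases_per_patient
        if lo < 0 or hi < lo:
            raise SimConfigError(
                "metastases_per_patient must be a (min, max) range with 0 <= min <= max"
            )
        if self.n_de_proteins + self.n_cluster_proteins > self.n_proteins:
            raise SimConfigError(
                "n_de_proteins + n_cluster_proteins must not exceed n_proteins"
            )
        if not 0 <= self.mar_rate <= 1:
            raise SimConfigError("mar_rate must be in [0, 1]")
        if self.mnar_slope < 0:
            raise SimConfigError("mnar_slope must be >= 0")
        if self.total_metastases is not None:
            if not (lo * self.n_patients <= self.total_metastases
                    <= hi * self.n_patients):
                raise SimConfigError(
                    "total_metastases is unreachable from metastases_per_patient range"
                )


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    de_effects: dict[str, float]            # protein id -> signed log2 effect
    cluster_labels: dict[str, int]          # sample id -> cluster index
    sample_offsets: dict[str, float]        # sample id -> log2 depth offset
    cluster_proteins: dict[str, int] = field(default_factory=dict)  # protein -> block
    missing_mask: pd.DataFrame | None = None

    @property
    def de_proteins(self) -> set[str]:
        return set(self.de_effects)

    def to_json(self, path) -> None:
        payload = {
            "de_effects": self.de_effects,
            "cluster_labels": self.cluster_labels,
            "sample_offsets": self.sample_offsets,
            "cluster_proteins": self.cluster_proteins,
        }
        if self.missing_mask is not None:
            payload["missing_mask"] = {
                "proteins": list(self.missing_mask.index),
                "samples": list(self.missing_mask.columns),
                "mask": self.missing_mask.to_numpy().astype(int).tolist(),
            }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _metastasis_counts(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-patient metastasis counts drawn uniformly in range, nudged to the
    configured total by single-step adjustments (keeps counts inside range)."""
    lo, hi = cfg.metastases_per_patient
    counts = rng.integers(lo, hi + 1, size=cfg.n_patients)
    if cfg.total_metastases is not None:
        while counts.sum() != cfg.total_metastases:
            if counts.sum() > cfg.total_metastases:
                candidates = np.flatnonzero(counts > lo)
                counts[rng.choice(candidates)] -= 1
            else:
                candidates = np.flatnonzero(counts < hi)
                counts[rng.choice(candidates)] += 1
    return counts


def generate_cohort(
    config: SimConfig,
) -> tuple[IntensityMatrix, SampleSheet, SyntheticTruth]:
    """Simulate a complete (no-missing) raw-intensity cohort with truth.

    Returns the raw-scale matrix (exp2 of the simulated log2 values), the
    sample sheet, and the planted truth.  Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)

    counts = _metastasis_counts(config, rng)
    rows = []
    for p in range(config.n_patients):
        pid = f"P{p + 1:02d}"
        rows.append((f"{pid}_T", pid, "primary", ""))
        for m in range(counts[p]):
            loc = LOCALIZATIONS[rng.integers(0, len(LOCALIZATIONS))]
            rows.append((f"{pid}_M{m + 1}", pid, "metastasis", loc))
    sheet = SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "patient_id", "tissue_type",
                                    "localization"])
    )
    sample_ids = sheet.sample_ids
    n_samples = len(sample_ids)
    is_met = np.array(
        [t == "metastasis" for t in sheet.table["tissue_type"]], dtype=bool
    )

    protein_ids = [f"PROT{i + 1:05d}" for i in range(config.n_proteins)]
    de_ids = protein_ids[: config.n_de_proteins]
    cluster_ids = protein_ids[
        config.n_de_proteins: config.n_de_proteins + config.n_cluster_proteins
    ]

    base = rng.normal(config.base_mean, config.base_sd, size=config.n_proteins)
    offsets = rng.normal(0.0, config.sample_offset_sd, size=n_samples)
    noise = rng.normal(0.0, 0.5, size=(config.n_proteins, n_samples))

    log2_vals = base[:, None] + offsets[None, :] + noise

    # planted DE: metastasis samples shifted by +de_effect on the DE block
    de_effects = {pid: float(config.de_effect) for pid in de_ids}
    if de_ids:
        log2_vals[: len(de_ids), is_met] += config.de_effect

    # planted clusters: balanced random sample assignment; each cluster gets an
    # exclusive slice of the cluster-protein block shifted by +cluster_effect
    cluster_labels = {}
    cluster_proteins: dict[str, int] = {}
    if config.n_clusters > 0:
        perm = rng.permutation(n_samples)
        assign = np.empty(n_samples, dtype=int)
        assign[perm] = np.arange(n_samples) % config.n_clusters
        cluster_labels = {s: int(c) for s, c in zip(sample_ids, assign)}
        if cluster_ids:
            blocks = np.array_split(np.arange(len(cluster_ids)), config.n_clusters)
            row0 = config.n_de_proteins
            for c, block in enumerate(blocks):
                for b in block:
                    cluster_proteins[cluster_ids[b]] = c
                log2_vals[np.ix_(row0 + block, assign == c)] += config.cluster_effect

    matrix = IntensityMatrix(
        pd.DataFrame(np.exp2(log2_vals), index=protein_ids, columns=sample_ids),
        scale=RAW,
    )
    truth = SyntheticTruth(
        de_effects=de_effects,
        cluster_labels=cluster_labels,
        sample_offsets={s: float(o) for s, o in zip(sample_ids, offsets)},
        cluster_proteins=cluster_proteins,
    )
    return matrix, sheet, truth


def dropout_probability(log2_intensity: np.ndarray, config: SimConfig) -> np.ndarray:
    """p(missing) = mar + (1 - mar) * logistic(-slope * (x - midpoint))."""
    x = np.asarray(log2_intensity, dtype=float)
    if np.isneginf(config.mnar_midpoint):
        p_mnar = np.zeros_like(x)
    else:
        p_mnar = expit(-config.mnar_slope * (x - config.mnar_midpoint))
    return config.mar_rate + (1.0 - config.mar_rate) * p_mnar


def inject_missingness(
    matrix: IntensityMatrix,
    config: SimConfig,
    truth: SyntheticTruth | None = None,
    rng: np.random.Generator | None = None,
) -> IntensityMatrix:
    """Apply MAR + MNAR dropout to a complete raw matrix.

    Each entry is set missing independently with the probability from
    :func:`dropout_probability` evaluated at its log2 intensity.  The realized
    mask is recorded on ``truth`` when given.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("inject_missingness expects a complete matrix")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    p = dropout_probability(np.log2(vals), config)
    mask = rng.random(size=vals.shape) < p
    out = vals.copy()
    out[mask] = np.nan
    mask_df = pd.DataFrame(mask, index=matrix.values.index,
                           columns=matrix.values.columns)
    if truth is not None:
        truth.missing_mask = mask_df
    return IntensityMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        scale=matrix.scale,
    )


def simulate(config: SimConfig) -> tuple[IntensityMatrix, SampleSheet, SyntheticTruth]:
    """Generate a cohort and apply the configured missingness in one call."""
    matrix, sheet, truth = generate_cohort(config)
    noisy = inject_missingness(matrix, config, truth=truth)
    return noisy, sheet, truth


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["metastases_per_patient"] = list(d["metastases_per_patient"])
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "metastases_per_patient" in d:
        d["metastases_per_patient"] = tuple(d["metastases_per_patient"])
    return SimConfig(**d)
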