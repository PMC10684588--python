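"""Candidate nomination and immunoblot validation statistics.

Candidates are the intersection of the significant differential-expression
set with the cluster-relevant set (top relevance percentile from the
consensus NMF basis) -- proteins that both move between primaries and
metastases and carry the unsupervised cluster structure.

Densitometric immunoblot quantification is made cross-gel comparable by
dividing each band by the mean of its gel's bridging standards before
dividing by the loading control; group comparison then reuses the same
Mann-Whitney machinery as the discovery analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import mann_whitney_u
from .matrix import SampleSheet


def intersect_candidates(
    de_table: pd.DataFrame,
    significant: list[str],
    relevant: list[str],
    relevance: pd.Series | None = None,
) -> pd.DataFrame:
    """Intersect DE-significant proteins with the cluster-relevant set.

    Returns one row per protein in both sets, carrying the DE annotations
    (log2fc, p, class, direction) plus the relevance score when provided,
    ordered by ascending p-value then protein id.  Empty overlap is allowed.
    """
    overlap = sorted(set(significant) & set(relevant))
    cols = ["log2fc", "p_value", "p_bh", "de_class"]
    rows = []
    for pid in overlap:
        if pid in de_table.index:
            rec = de_table.loc[pid, cols].to_dict()
        else:
            rec = {c: np.nan for c in cols}
        rec["protein_id"] = pid
        rec["relevance"] = (
            float(relevance[pid]) if relevance is not None and pid in relevance
            else np.nan
        )
        fc = rec.get("log2fc", np.nan)
        rec["direction"] = (
            "up_primary" if fc > 0 else "up_metastasis" if fc < 0 else "none"
        )
        rows.append(rec)
    table = pd.DataFrame(
        rows,
        columns=["protein_id", "log2fc", "p_value", "p_bh", "de_class",
                 "relevance", "direction"],
    )
    if not table.empty:
        table = table.sort_values(
            ["p_value", "protein_id"], na_position="last"
        ).reset_index(drop=True)
    return table


@dataclass(frozen=True)
class BlotMeasurement:
    """One quantified band: densitometry of a sample on a specific gel."""

    sample_id: str
    gel_id: str
    raw_density: float
    loading_control_density: float
    tissue_type: str = ""


def blot_normalize(
    measurements: list[BlotMeasurement],
    standards: dict[str, list[float]],
) -> pd.Series:
    """Cross-gel normalized intensity per sample.

    normalized = (raw / mean(same-gel standard densities)) / loading control.
    Dividing by the gel's bridging standards first makes samples from
    different gels directly comparable.  Technical replicates of a sample
    (several bands) are averaged after normalization.
    """
    per_sample: dict[str, list[float]] = {}
    for m in measurements:
        if m.gel_id not in standards or not standards[m.gel_id]:
            raise ValueError(f"gel {m.gel_id!r} has no bridging standards")
        std_mean = float(np.mean(standards[m.gel_id]))
        if std_mean <= 0:
            raise ValueError(f"gel {m.gel_id!r}: standard mean must be > 0")
        if m.raw_density <= 0:
            raise ValueError(
                f"sample {m.sample_id!r} on gel {m.gel_id!r}: raw density "
                "must be > 0"
            )
        if m.loading_control_density <= 0:
            raise ValueError(
                f"sample {m.sample_id!r} on gel {m.gel_id!r}: loading "
                "control must be > 0"
            )
        value = (m.raw_density / std_mean) / m.loading_control_density
        per_sample.setdefault(m.sample_id, []).append(value)
    return pd.Series(
        {s: float(np.mean(v)) for s, v in per_sample.items()},
        name="normalized_intensity",
    )


def blot_compare(
    normalized: pd.Series, sheet: SampleSheet
) -> tuple[float, float]:
    """Mann-Whitney comparison of normalized blot intensities by tissue type.

    Delegates to the same U test used for the discovery differential
    expression.  Returns (U, two-sided p).
    """
    groups: dict[str, list[float]] = {"primary": [], "metastasis": []}
    for sid, value in normalized.items():
        groups[sheet.tissue_of(sid)].append(float(value))
    if not groups["primary"] or not groups["metastasis"]:
        raise ValueError("both tissue groups must be represented")
    return mann_whitney_u(groups["primary"], groups["metastasis"])


def read_blot_table(path, sep: str = "\t") -> tuple[list[BlotMeasurement],
                                                    dict[str, list[float]]]:
    """Read a long-format blot table.

    Columns: sample_id, gel_id, raw_density, loading_control_density,
    is_standard (0/1).  Standard rows contribute raw_density to their gel's
    standard pool and need no loading control.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "gel_id", "raw_density", "is_standard"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"blot table missing columns: {sorted(missing)}")
    standards: dict[str, list[float]] = {}
    measurements: list[BlotMeasurement] = []
    for _, row in df.iterrows():
        gel = str(row["gel_id"])
        if int(row["is_standard"]):
            standards.setdefault(gel, []).append(float(row["raw_density"]))
        else:
            measurements.append(BlotMeasurement(
                sample_id=str(row["sample_id"]),
                gel_id=gel,
                raw_density=float(row["raw_density"]),
                loading_control_density=float(row["loading_control_density"]),
            ))
    return measurements, standards
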