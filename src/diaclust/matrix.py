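"""Intensity-matrix and sample-sheet containers with IO and preprocessing.

The central object is a protein x sample table of label-free quantitative
intensities with explicit missingness (NaN) and a scale tag (``raw`` linear
intensities or ``log2``).  Preprocessing follows the usual FFPE-DIA recipe:
valid-value filtering, log2 transform, and per-protein mean imputation --
imputation is reserved for PCA and unsupervised clustering; tests on group
differences always run on unimputed values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RAW = "raw"
LOG2 = "log2"

#: cell tokens interpreted as missing on read
DEFAULT_NA_TOKENS = ("", "NA", "NaN", "nan")


class MatrixParseError(ValueError):
    """Malformed matrix or sample-sheet file (coordinates in the message)."""


@dataclass(frozen=True)
class MatrixDialect:
    """Text-format conventions for wide matrix files."""

    sep: str = "\t"
    na_tokens: tuple[str, ...] = DEFAULT_NA_TOKENS
    scale: str = RAW


@dataclass
class IntensityMatrix:
    """Protein x sample quantitative table.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with sample-id columns; NaN encodes a
        missing (unquantified) measurement.
    scale
        ``"raw"`` for linear intensities (strictly positive where present) or
        ``"log2"`` for log2-transformed values.
    """

    values: pd.DataFrame
    scale: str = RAW

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise MatrixParseError(f"duplicate protein ids: {dups}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise MatrixParseError(f"duplicate sample ids: {dups}")
        if self.scale not in (RAW, LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == RAW:
            vals = self.values.to_numpy(dtype=float)
            bad = (vals <= 0) & ~np.isnan(vals)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"raw-scale intensity must be positive; found "
                    f"{vals[i, j]!r} at protein {idx[i]!r}, sample {cols[j]!r}"
                )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.scale)


@dataclass
class SampleSheet:
    """Per-sample annotations: patient, tissue type, metastasis localization.

    ``tissue_type`` is ``"primary"`` or ``"metastasis"``; ``localization`` is a
    short site code (ADR adrenal gland, HEP liver, KID kidney, OSS bone,
    OTH other) and is empty for primaries.
    """

    table: pd.DataFrame  # columns: sample_id, patient_id, tissue_type, localization

    REQUIRED = ("sample_id", "patient_id", "tissue_type")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise MatrixParseError(f"sample sheet missing column {col!r}")
        if "localization" not in self.table.columns:
            self.table = self.table.assign(localization="")
        sid = self.table["sample_id"]
        if sid.duplicated().any():
            raise MatrixParseError(
                f"duplicate sample ids in sheet: {sid[sid.duplicated()].tolist()}"
            )
        tt = set(self.table["tissue_type"])
        bad = tt - {"primary", "metastasis"}
        if bad:
            raise MatrixParseError(f"unknown tissue_type values: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_of(self, tissue_type: str) -> list[str]:
        mask = self.table["tissue_type"] == tissue_type
        return list(self.table.loc[mask, "sample_id"])

    def tissue_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in sheet")
        return row["tissue_type"].iloc[0]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_matrix(path, dialect: MatrixDialect | None = None) -> IntensityMatrix:
    """Read a wide matrix file (first column protein id, then sample columns)."""
    dialect = dialect or MatrixDialect()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(dialect.sep)
    dup = [c for c in header[1:] if header[1:].count(c) > 1]
    if dup:
        raise MatrixParseError(f"duplicate sample columns: {sorted(set(dup))}")
    df = pd.read_csv(
        path,
        sep=dialect.sep,
        index_col=0,
        na_values=list(dialect.na_tokens),
        keep_default_na=False,
        dtype=str,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise MatrixParseError(
                f"non-numeric cell {df.loc[row, col]!r} at protein {row!r}, "
                f"sample {col!r}"
            )
        numeric[col] = converted
    return IntensityMatrix(numeric, scale=dialect.scale)


def write_matrix(matrix: IntensityMatrix, path, dialect: MatrixDialect | None = None) -> None:
    dialect = dialect or MatrixDialect()
    out = matrix.values.copy()
    out.index.name = "protein_id"
    # repr-precision floats so read_matrix round-trips bit-for-bit
    out.to_csv(path, sep=dialect.sep, na_rep=dialect.na_tokens[0], float_format=None)


def read_sample_sheet(path, sep: str = "\t") -> SampleSheet:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path, sep: str = "\t") -> None:
    sheet.table.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def filter_valid(matrix: IntensityMatrix, min_valid_fraction: float = 0.5) -> IntensityMatrix:
    """Keep proteins quantified in at least ``min_valid_fraction`` of samples.

    The comparison is inclusive ("at least"): a protein valid in exactly half
    the samples survives a 0.5 threshold.  Protein order is preserved.
    """
    if not 0 < min_valid_fraction <= 1:
        raise ValueError("min_valid_fraction must be in (0, 1]")
    frac = matrix.values.notna().mean(axis=1)
    keep = frac >= min_valid_fraction
    return IntensityMatrix(matrix.values.loc[keep].copy(), matrix.scale)


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """log2 every present value; missing cells stay missing."""
    if matrix.scale != RAW:
        raise ValueError("log2_transform expects a raw-scale matrix")
    vals = matrix.values.to_numpy(dtype=float)
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"cannot log2 nonpositive value {vals[i, j]} at protein "
            f"{matrix.protein_ids[i]!r}, sample {matrix.sample_ids[j]!r}"
        )
    out = pd.DataFrame(
        np.log2(vals), index=matrix.values.index, columns=matrix.values.columns
    )
    return IntensityMatrix(out, scale=LOG2)


def impute_mean(matrix: IntensityMatrix, per_protein: bool = True) -> IntensityMatrix:
    """Replace missing cells by the mean of valid values.

    Default is the per-protein mean (each protein's missing entries get that
    protein's own mean over quantified samples), which preserves protein-level
    structure; ``per_protein=False`` switches to the global matrix mean for
    sensitivity analysis.  Imputation is intended only for PCA and consensus
    clustering; group tests must consume the unimputed matrix.
    """
    vals = matrix.values
    if per_protein:
        n_valid = vals.notna().sum(axis=1)
        if (n_valid == 0).any():
            empty = vals.index[n_valid == 0].tolist()
            raise ValueError(
                f"proteins with zero valid values cannot be mean-imputed: "
                f"{empty}; apply filter_valid first"
            )
        row_means = vals.mean(axis=1)
        out = vals.T.fillna(row_means).T
    else:
        if vals.notna().sum().sum() == 0:
            raise ValueError("matrix has no valid values to average")
        out = vals.fillna(float(np.nanmean(vals.to_numpy(dtype=float))))
    return IntensityMatrix(out, matrix.scale)


def coverage_summary(matrix: IntensityMatrix) -> tuple[pd.Series, float]:
    """Valid-value count per sample and the median of those counts."""
    counts = matrix.values.notna().sum(axis=0)
    return counts, float(counts.median())
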