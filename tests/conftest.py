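import numpy as np
import pandas as pd
import pytest

from diaclust.matrix import LOG2, IntensityMatrix, SampleSheet


@pytest.fixture
def tiny_log2_matrix():
    """4 proteins x 4 samples, log2 scale, one missing cell."""
    data = pd.DataFrame(
        {
            "S1": [10.0, 12.0, 8.0, 20.0],
            "S2": [10.5, np.nan, 8.2, 20.1],
            "S3": [9.8, 12.1, 7.9, 19.9],
            "S4": [10.2, 11.9, 8.1, 20.0],
        },
        index=["A", "B", "C", "D"],
    )
    return IntensityMatrix(data, scale=LOG2)


@pytest.fixture
def two_group_sheet():
    return SampleSheet(pd.DataFrame({
        "sample_id": ["S1", "S2", "S3", "S4"],
        "patient_id": ["P1", "P1", "P2", "P2"],
        "tissue_type": ["primary", "metastasis", "primary", "metastasis"],
        "localization": ["", "HEP", "", "OSS"],
    }))


@pytest.fixture
def cohort_sheet():
    """14 primaries + 24 metastases across 14 patients."""
    rows = []
    n_mets = [1, 2, 4, 1, 1, 1, 3, 2, 3, 1, 1, 1, 2, 1]
    for i, nm in enumerate(n_mets, start=1):
        pid = f"P{i:02d}"
        rows.append((f"{pid}_T", pid, "primary", ""))
        for m in range(nm):
            rows.append((f"{pid}_M{m + 1}", pid, "metastasis", "HEP"))
    return SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "tissue_type", "localization"]
    ))
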