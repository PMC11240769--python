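import numpy as np
import pandas as pd
import pytest

from liqtrace.core_data import (
    CountMatrix,
    Phase,
    SampleRecord,
    StudyTable,
    Tissue,
    validate_study,
)


def make_matrix(values, feature_ids=None, sample_ids=None, kind="generic") -> CountMatrix:
    arr = np.asarray(values, dtype=np.int64)
    feature_ids = feature_ids or [f"g{i}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=feature_ids, columns=sample_ids), kind)


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """3 features x 2 samples where the second column is double the first."""
    return make_matrix([[10, 20], [20, 40], [30, 60]])


def worked_example_study(n_background: int = 30) -> StudyTable:
    """A single patient realizing the published worked-example trajectories.

    Feature 'mrna_like' has pre-surgery 100, post-surgery 60 and 9, recurrence
    300 (fold changes 0.6, 0.09, 3.0); 'mirna_like' has 100, 40, 10, 290
    (0.4, 0.1, 2.9).  Constant background features pin all size factors to 1,
    so normalized counts equal raw counts.
    """
    samples = [
        SampleRecord("pre", "p1", Tissue.BLOOD, Phase.PRE_SURGERY, -1),
        SampleRecord("post_early", "p1", Tissue.BLOOD, Phase.POST_SURGERY, 5),
        SampleRecord("post_late", "p1", Tissue.BLOOD, Phase.POST_SURGERY, 84),
        SampleRecord("rec", "p1", Tissue.BLOOD, Phase.RECURRENCE, 260, day_rel_recurrence=3),
        SampleRecord("tumor", "p1", Tissue.TUMOR, Phase.PRE_SURGERY, 0),
    ]
    rows = [[100, 60, 9, 300, 150], [100, 40, 10, 290, 150]]
    ids = ["mrna_like", "mirna_like"]
    for i in range(n_background):
        rows.append([50] * 5)
        ids.append(f"bg{i}")
    matrix = make_matrix(rows, feature_ids=ids, sample_ids=[s.sample_id for s in samples])
    return validate_study(matrix, samples)


@pytest.fixture
def worked_study() -> StudyTable:
    return worked_example_study()
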