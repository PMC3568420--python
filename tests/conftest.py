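import numpy as np
import pandas as pd
import pytest

from xmerge import ExpressionStudy, merge, simulate_studies, worked_fixture


def make_study(study_id, values, sample_prefix="S", annotations=None):
    """Build a study from a plain matrix; samples get a Disease label."""
    values = np.asarray(values, dtype=float)
    genes = [f"G{i:03d}" for i in range(1, values.shape[0] + 1)]
    samples = [f"{sample_prefix}{j:03d}" for j in range(1, values.shape[1] + 1)]
    frame = pd.DataFrame(values, index=genes, columns=samples)
    if annotations is None:
        half = max(1, len(samples) // 2)
        annotations = pd.DataFrame(
            {"Disease": ["control"] * half + ["case"] * (len(samples) - half)},
            index=samples,
        )
    return ExpressionStudy(study_id, frame, annotations)


def duplicate_study(study, new_id="COPY", prefix="C"):
    """Same values under fresh sample IDs (identical empirical distributions)."""
    values = study.values.rename(columns=lambda c: prefix + c)
    ann = study.annotations.rename(index=lambda c: prefix + c)
    return ExpressionStudy(new_id, values, ann)


@pytest.fixture
def fixture_pair():
    return worked_fixture()


@pytest.fixture(scope="session")
def default_sim():
    """The default simulation scenario: 500 genes, 2 studies x 50 samples,
    additive batch shift sd 2, seed 0."""
    return simulate_studies(seed=0)


@pytest.fixture(scope="session")
def none_merged(default_sim):
    studies, _ = default_sim
    return merge(studies, "NONE")
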