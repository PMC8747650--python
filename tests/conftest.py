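import numpy as np
import pytest

from rooibosml import (
    AssayDataset,
    SampleMeasurements,
    default_paper_params,
    generate_dataset,
)
from rooibosml.data import FEATURE_COLUMNS


def make_sample(sample_id, label, values):
    """Build a SampleMeasurements from six values in canonical column order."""
    return SampleMeasurements(
        sample_id=sample_id, label=label, **dict(zip(FEATURE_COLUMNS, map(float, values)))
    )


def dataset_from_matrix(X, labels, prefix="s"):
    """n x 6 matrix + label list -> AssayDataset."""
    samples = [
        make_sample(f"{prefix}{i}", lab, row) for i, (row, lab) in enumerate(zip(X, labels))
    ]
    return AssayDataset(tuple(samples))


def two_feature_dataset(x_fr, x_ufr, rng=None):
    """Dataset whose (tpc_water, teac_water) columns carry the given 2-D
    class clouds; remaining columns are filled with a constant."""
    rows = []
    labels = []
    for lab, X in (("FR", np.asarray(x_fr)), ("UFR", np.asarray(x_ufr))):
        for p in X:
            rows.append([p[0], p[1], 1.0, 1.0, 1.0, 1.0])
            labels.append(lab)
    return dataset_from_matrix(np.array(rows), labels)


@pytest.fixture(scope="session")
def default_params():
    return default_paper_params(seed=0)


@pytest.fixture(scope="session")
def default_dataset(default_params):
    """The study conditions: 51 FR + 47 UFR synthetic samples, seed 0."""
    return generate_dataset(default_params)
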