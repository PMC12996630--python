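import numpy as np
import pytest

from dpas import (
    AnomalyPipeline,
    PeptideRecord,
    PeptideSet,
    SyntheticSpec,
    assemble_feature_matrix,
    generate_dataset,
)


@pytest.fixture(scope="session")
def planted_dataset():
    """The default planted-anomaly fixture: 100 inliers + 5 outliers, seed 7."""
    return generate_dataset(SyntheticSpec())


@pytest.fixture(scope="session")
def planted_features(planted_dataset):
    pset, _ = planted_dataset
    return assemble_feature_matrix(pset)


@pytest.fixture(scope="session")
def outlier_mask(planted_dataset):
    _, truth = planted_dataset
    return (truth["label"] == -1).to_numpy()


@pytest.fixture(scope="session")
def fitted_pipelines(planted_features):
    """One fitted pipeline per one-class model, on the planted fixture."""
    return {
        model: AnomalyPipeline(model=model, seed=0).fit(planted_features)
        for model in ("ocsvm", "iforest", "autoencoder")
    }


@pytest.fixture()
def tiny_set():
    return PeptideSet(
        [
            PeptideRecord("p1", "ACDE"),
            PeptideRecord("p2", "qRWmEDL"),
            PeptideRecord("p3", "KKSPKK"),
        ]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
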