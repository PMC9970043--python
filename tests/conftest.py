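import numpy as np
import pytest

import bgmm_oce as bo
from bgmm_oce.fixtures import table_to_dataframe


@pytest.fixture(scope="session")
def cohort_csv(tmp_path_factory):
    """Default emulated clinical cohort written to CSV once per session."""
    path = tmp_path_factory.mktemp("data") / "cohort.csv"
    raw, ann = bo.make_clinical_table(bo.ClinicalTableSpec(seed=42))
    table_to_dataframe(raw).to_csv(path, index=False)
    return path, raw, ann


@pytest.fixture(scope="session")
def blob_data():
    """Three well-separated unit-covariance blobs (n=1500, d=2)."""
    mix = bo.GroundTruthMixture(
        weights=[1 / 3, 1 / 3, 1 / 3],
        means=np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]]),
        covariances=np.stack([np.eye(2)] * 3),
        n=1500,
        seed=0,
    )
    return bo.sample_mixture(mix)


@pytest.fixture(scope="session")
def single_component_posterior():
    """A converged T=1 fit on anisotropic Gaussian data."""
    rng = np.random.default_rng(0)
    X = rng.standard_normal((400, 3)) * np.array([1.0, 2.0, 0.5]) + np.array(
        [5.0, -2.0, 0.0]
    )
    priors = bo.make_priors(X, 1)
    return X, bo.fit_variational(X, priors, seed=0)
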