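import numpy as np
import pytest

from misclasscal import (
    RegressionTruth,
    attach_logistic_outcome,
    sample_mixture,
    two_class_mixture,
)


@pytest.fixture(scope="session")
def balanced_mixture():
    """The study's balanced two-class bivariate mixture."""
    return two_class_mixture(0.5)


@pytest.fixture(scope="session")
def logistic_truth():
    return RegressionTruth(np.array([-1.0, 2.0]), "logistic")


@pytest.fixture(scope="session")
def balanced_dataset(balanced_mixture, logistic_truth):
    """One n=1000 draw from the balanced scenario with a logistic outcome."""
    data = sample_mixture(balanced_mixture, 1000, seed=42)
    return attach_logistic_outcome(data, logistic_truth, seed=43)


@pytest.fixture(scope="session")
def separable_features():
    """Two Gaussian blobs far apart: any clustering recovers them exactly."""
    rng = np.random.default_rng(7)
    labels = rng.integers(1, 3, size=400)
    means = np.array([[-10.0, 0.0], [10.0, 0.0]])
    feats = means[labels - 1] + rng.standard_normal((400, 2))
    return feats, labels
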