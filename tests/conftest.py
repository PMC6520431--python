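import numpy as np
import pytest

from attnbci.features import FeatureMatrix
from attnbci.montage import default_montage
from attnbci.synth import default_effects


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def effects():
    return default_effects()


def null_feature_matrix(
    seed: int,
    n_subjects: int = 14,
    n_epochs: int = 120,
    n_features: int = 20,
    classes: tuple[str, ...] = ("easy", "hard"),
) -> FeatureMatrix:
    """Balanced cohort of iid standard-normal features with no class effect."""
    rng = np.random.default_rng(seed)
    rows = n_subjects * n_epochs
    X = rng.standard_normal((rows, n_features))
    labels = np.tile(np.repeat(classes, n_epochs // len(classes)), n_subjects)
    subjects = np.repeat([f"S{i:02d}" for i in range(n_subjects)], n_epochs)
    names = [f"f{j}" for j in range(n_features)]
    return FeatureMatrix(X, names, labels, subjects, 5.0)
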