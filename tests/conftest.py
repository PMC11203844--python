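import numpy as np
import pytest

from conformxplain.classifier import ModelConfig, split_data, train_cnn
from conformxplain.featurize import LabelingConfig, label_ensemble
from conformxplain.synthdata import SynthConfig, generate_ensemble


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic study conditions: 282 residues, 10/80/10 imbalance,
    8 planted H1 residues."""
    ensemble, truth = generate_ensemble(SynthConfig(seed=11))
    data = label_ensemble(
        ensemble, LabelingConfig(marker_pair=truth.marker_pair))
    return ensemble, truth, data


@pytest.fixture(scope="session")
def default_split(default_dataset):
    _, _, data = default_dataset
    return split_data(data.X, data.y, val_fraction=0.2, seed=11)


@pytest.fixture(scope="session")
def trained_cnn(default_split):
    """Default CNN trained on the training split of the default dataset."""
    (X_tr, y_tr), _ = default_split
    return train_cnn((X_tr, y_tr), ModelConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A lighter ensemble for fast unit tests."""
    ensemble, truth = generate_ensemble(
        SynthConfig(seed=5, n_residues=30, n_frames=120,
                    n_informative=3))
    data = label_ensemble(
        ensemble, LabelingConfig(marker_pair=truth.marker_pair))
    return ensemble, truth, data


class LinearProbaModel:
    """Tiny deterministic stand-in classifier for explainer tests.

    Two-class linear model over flattened residue coordinates; exposes the
    predict_proba / class_index surface the model-agnostic explainers need.
    """

    def __init__(self, w, classes=("active", "intermediate")):
        self.w = np.asarray(w, dtype=float)
        self.classes_ = np.asarray(classes)

    def class_index(self, label):
        return int(np.where(self.classes_ == label)[0][0])

    def decision_function(self, X):
        return np.atleast_2d(X) @ self.w

    def predict_proba(self, X):
        z = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([p1, 1.0 - p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 0] < 0.5).astype(int)]


@pytest.fixture
def linear_model_factory():
    return LinearProbaModel
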