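import numpy as np
import pytest

from semgbench.preprocessing import DatasetSplit, ScalingParams, Subset
from semgbench.synthetic import (AcquisitionConfig, default_profile,
                                 generate_session)


def make_split(X_tr, y_tr, X_cv=None, y_cv=None, X_ts=None, y_ts=None):
    """Assemble a DatasetSplit from raw arrays (classifier unit tests)."""
    def subset(X, y):
        if X is None:
            return Subset(X=np.empty((0, np.asarray(X_tr).shape[1])),
                          y=np.empty(0, np.int64), indices=np.empty(0, np.int64))
        X = np.asarray(X, float)
        return Subset(X=X, y=np.asarray(y, np.int64),
                      indices=np.arange(len(X)))

    scaling = ScalingParams(mean=np.zeros(np.asarray(X_tr).shape[1]),
                            range=np.ones(np.asarray(X_tr).shape[1]))
    return DatasetSplit(TR=subset(X_tr, y_tr), CV=subset(X_cv, y_cv),
                        TS=subset(X_ts, y_ts), GS=subset(None, None),
                        scaling=scaling)


def gaussian_blobs(rng, means, n_per_class, scale=0.5):
    """Simple labelled Gaussian clusters for classifier tests."""
    means = np.asarray(means, float)
    X = np.concatenate([rng.normal(m, scale, size=(n_per_class, means.shape[1]))
                        for m in means])
    y = np.repeat(np.arange(len(means)), n_per_class)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


@pytest.fixture(scope="session")
def default_session():
    """One full-protocol synthetic session (5 classes x 10 reps x 2 s @1 kHz)."""
    return generate_session(AcquisitionConfig(), default_profile(), seed=123)


@pytest.fixture()
def small_config():
    """Scaled-down acquisition for fast structural tests."""
    return AcquisitionConfig(reps_per_gesture=2, duration_per_rep=0.2)


@pytest.fixture()
def small_profile():
    return default_profile()
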