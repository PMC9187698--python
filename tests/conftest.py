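import numpy as np
import pandas as pd
import pytest

from icpforecast import (
    CohortConfig,
    ICPForecaster,
    WindowedDataset,
    clean_series,
    generate_cohort,
    make_intervals,
    make_windows,
)
from icpforecast.model import CLASSES, CategoricalLagNB


def windows_from_arrays(X, y, horizon=1, patient="p0"):
    """Build a WindowedDataset from raw (levels, classes) arrays."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d1 = X.shape[1]
    frame = pd.DataFrame(X, columns=[f"x{j}" for j in range(1, d1 + 1)])
    frame.insert(0, "patient_id", patient)
    frame.insert(1, "anchor", np.arange(len(frame)))
    frame.insert(2, "horizon", horizon)
    frame.insert(3, "y", np.asarray(y, dtype=int))
    return WindowedDataset(frame, d1=d1, m=int(horizon))


@pytest.fixture
def hand_windows_d1_2():
    """Eight hand-written rows with d1 = 2, countable by eye.

    Class 1 histories: (1,1), (1,2), (2,1), (1,1); class 2: (3,3), (2,3),
    (3,2), (3,3). Unsmoothed per-lag tables: lag frequencies (3/4, 1/4, 0)
    per lag for class 1 and (0, 1/4, 3/4) for class 2; prior (1/2, 1/2).
    """
    X = [(1, 1), (1, 2), (2, 1), (1, 1), (3, 3), (2, 3), (3, 2), (3, 3)]
    y = [1, 1, 1, 1, 2, 2, 2, 2]
    return windows_from_arrays(X, y)


def manual_forecaster_d1_1(prior=(0.5, 0.5), cond1=(0.6, 0.3, 0.1), cond2=(0.4, 0.3, 0.3)):
    """A d1 = 1 forecaster with hand-set tables, so posteriors are known:

    with the defaults, history level 1 -> posterior (0.6, 0.4), level 2 ->
    (0.5, 0.5), level 3 -> (0.25, 0.75).
    """
    model = ICPForecaster(d1=1, m=1, mode="per_lag", smoothing=0.0, alpha=1.0)
    est = CategoricalLagNB(mode="per_lag", smoothing=0.0, alpha=1.0)
    est.classes_ = CLASSES.copy()
    est.n_features_in_ = 1
    est.class_count_ = np.array([1.0, 1.0])
    est.class_prior_ = np.asarray(prior, dtype=float)
    est.feature_prob_ = np.array([[cond1], [cond2]], dtype=float)
    model.estimators_ = {1: est}
    return model


def simulate_windows(seed, n_patients=6, hours=60.0, d1=6, m=6):
    """Cohort -> cleaned series -> intervals -> pooled windows."""
    cfg = CohortConfig(n_patients=n_patients, hours_per_patient=hours, seed=seed)
    tables = [make_intervals(clean_series(s)) for s in generate_cohort(cfg)]
    return tables, WindowedDataset.concat([make_windows(t, d1=d1, m=m) for t in tables])
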