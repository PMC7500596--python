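import numpy as np
import pytest

import enrichsurv as es


@pytest.fixture(scope="session")
def strong_marker_cohort():
    """n = 5000 cohort with a strongly prognostic marker (HR 2.8/SD), constant
    hazards, 18% population event rate by 48 months, censored at 48."""
    spec = es.SimulationSpec(
        n=5000, shape_k=1.0, anchor_p=0.82, anchor_T=48.0,
        biomarker_hr=2.8, biomarker_dist="normal", seed=20240,
    )
    return es.simulate_dataset(spec)


@pytest.fixture(scope="session")
def hand_km_curve():
    """Four subjects, times (5, 8, 12, 20), events (1, 1, 0, 1):
    S = 0.75 on [5, 8), 0.50 on [8, 20), 0 from 20."""
    d = es.BiomarkerSurvivalDataset(
        np.zeros(4), np.array([5.0, 8.0, 12.0, 20.0]), np.array([1, 1, 0, 1])
    )
    return es.kaplan_meier(d)


def make_dataset(time, event, biomarker=None):
    time = np.asarray(time, dtype=float)
    if biomarker is None:
        biomarker = np.zeros_like(time)
    return es.BiomarkerSurvivalDataset(np.asarray(biomarker, float), time,
                                       np.asarray(event))


def exponential_curve(rate, max_time=60.0, n_points=2000):
    """Dense step-function approximation to S(t) = exp(-rate t)."""
    times = np.linspace(max_time / n_points, max_time, n_points)
    surv = np.exp(-rate * times)
    return es.SurvivalCurve(
        times=times, surv=surv, se=np.zeros(n_points),
        n_at_risk=np.arange(n_points, 0, -1), max_time=max_time,
    )
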