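import numpy as np
import pandas as pd
import pytest

import verpmark as v
from verpmark.data import EpochSet, ParticipantMeta, VERP
from verpmark.montage import Montage, standard_montage
from verpmark.pipeline import RunConfig, cohort_features


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


def make_toy_montage(n: int = 2) -> Montage:
    names = tuple(f"E{i}" for i in range(n))
    positions = np.column_stack(
        [np.linspace(-1, 1, n), np.zeros(n), np.zeros(n)]
    )
    mirror = {f"E{i}": f"E{n - 1 - i}" for i in range(n)}
    return Montage(names=names, positions=positions, mirror=mirror,
                   posterior=(), midline=())


def make_epochs(data, sfreq=1000.0, montage=None, events=None, tmin_ms=None):
    """EpochSet from a raw (trials, electrodes, times) array."""
    data = np.asarray(data, dtype=float)
    n_trials, n_elec, n_times = data.shape
    if montage is None:
        montage = make_toy_montage(n_elec)
    step = 1000.0 / sfreq
    if tmin_ms is None:
        tmin_ms = -step * (n_times // 2)
    k0 = int(round(tmin_ms / step))
    times = np.arange(k0, k0 + n_times) * step
    if events is None:
        events = pd.DataFrame(
            {
                "field": ["upper"] * n_trials,
                "side": ["right"] * n_trials,
                "target": [False] * n_trials,
                "response_ms": [np.nan] * n_trials,
            }
        )
    return EpochSet(data=data, times=times, sfreq=sfreq, montage=montage,
                    events=events, pid="toy")


def make_verp(data, sfreq=1000.0, montage=None, tmin_ms=-250.0,
              condition="upper", pid="toy"):
    data = np.asarray(data, dtype=float)
    if montage is None:
        montage = standard_montage()
    step = 1000.0 / sfreq
    k0 = int(round(tmin_ms / step))
    times = np.arange(k0, k0 + data.shape[1]) * step
    return VERP(data=data, times=times, condition=condition,
                n_trials=10, montage=montage, pid=pid)


def control_meta(pid="ctl", age=20.0):
    return ParticipantMeta(pid=pid, group="Control", age_years=age)


def cc_meta(pid="cc", age=20.0):
    return ParticipantMeta(
        pid=pid, group="CC", age_years=age, age_at_surgery_months=24.0,
        time_since_surgery_months=age * 12 - 24.0,
    )


@pytest.fixture(scope="session")
def fast_cohort():
    """One scaled development cohort, shared across tests."""
    return v.simulate_cohort(v.fast_design("exp1"), seed=11)


@pytest.fixture(scope="session")
def fast_features(fast_cohort):
    return cohort_features(fast_cohort, RunConfig(scaled=True))
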