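import numpy as np
import pandas as pd
import pytest

from accmirror import cells, synth
from accmirror.mua import MuaEpochSet


@pytest.fixture(scope="session")
def dataset():
    """One full synthetic three-session experiment (default composition)."""
    return synth.simulate_experiment(seed=1)


@pytest.fixture(scope="session")
def stats_list(dataset):
    return [
        cells.cell_stats(dataset.trains_for(u.unit_id), dataset.schedules)
        for u in dataset.units
    ]


def make_epoch_set(
    n_channels,
    trial_conditions,
    amplitudes=None,
    session_id="ShockObs",
    fs=200.0,
    span=(-2.0, 3.0),
    response=(0.0, 1.0),
    noise_sd=1.0,
    seed=0,
    decay=1.0,
):
    """Directly constructed z-MUA epoch set with planted response bumps.

    ``amplitudes`` maps condition -> added z in the response window; the
    bump decays by ``decay`` per trial within its condition.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(span[0], span[1], 1 / fs) + 0.5 / fs
    n_trials = len(trial_conditions)
    z = rng.normal(0.0, noise_sd, (n_channels, n_trials, len(times)))
    counter = {}
    for j, cond in enumerate(trial_conditions):
        k = counter.get(cond, 0)
        counter[cond] = k + 1
        amp = (amplitudes or {}).get(cond, 0.0) * decay**k
        z[:, j, (times >= response[0]) & (times < response[1])] += amp
    codes = {"Ctrl": 0, "Low": 1, "High": 2}
    trials = pd.DataFrame(
        {
            "trial_index": np.arange(n_trials),
            "condition": list(trial_conditions),
            "intensity_code": pd.array(
                [codes.get(c, pd.NA) for c in trial_conditions], dtype="Int64"
            ),
            "onset_s": 10.0 + 60.0 * np.arange(n_trials),
            "duration_s": 1.0,
        }
    )
    sched = synth.TrialSchedule(session_id, trials)
    return MuaEpochSet(z=z, times=times, schedule=sched)
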