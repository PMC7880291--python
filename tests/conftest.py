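import numpy as np
import pytest

from ventrilab.simulate import SimulationParams, simulate_subject


@pytest.fixture(scope="session")
def strong_subject():
    """One LT subject with a strong, low-noise neural signal (snr=4)."""
    params = SimulationParams(seed=7, n_channels=16, snr=4.0, coupling=0.3)
    return simulate_subject("LT", params, 0), params


@pytest.fixture(scope="session")
def st_cohort_small():
    """Six ST subjects with moderate signal and active coupling (AV epochs only)."""
    params = SimulationParams(seed=11, n_channels=16, snr=1.5, coupling=0.3)
    subs = [simulate_subject("ST", params, s, trial_types=("AV",)) for s in range(6)]
    return subs, params


def av_epochs_and_dva(subject_data):
    """AV-trial epochs and their discrepancies for a simulated subject."""
    trials = subject_data.trials
    av = trials[trials.trial_type == "AV"].set_index("trial_index")
    ep = subject_data.epochs.select(np.isin(subject_data.epochs.trial_index, av.index))
    return ep, av.loc[ep.trial_index, "delta_va"].to_numpy()
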