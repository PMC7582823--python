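import numpy as np
import pytest

import hybridbci as hb
from hybridbci.experiments import run_offline


@pytest.fixture(scope="session")
def default_config():
    return hb.SignalModelConfig()


@pytest.fixture(scope="session")
def small_trained():
    """A decoder trained end-to-end on a small synthetic set.

    2 subjects × 8 tasks × 8 trials (128 epochs) at the default SNR —
    enough capacity/data to decode clean epochs, small enough to train in
    seconds.  Shared across end-to-end tests.
    """
    trials = hb.make_dataset(hb.SignalModelConfig(), n_subjects=2,
                             n_trials_per_task=8, rng=123)
    result, report = run_offline(trials, hb.TrainConfig(seed=123))
    return {"model": result.model, "report": report, "trials": trials}


def count_suprathreshold_intervals(x, threshold, min_samples=5, merge_gap=50):
    """Independent pulse-counting oracle: runs of |x| > threshold.

    Runs separated by fewer than ``merge_gap`` samples are one pulse
    (noise can briefly dip a flank below threshold); merged runs shorter
    than ``min_samples`` are ignored as isolated noise excursions.
    Returns the list of pulse-center indices.
    """
    above = np.abs(np.asarray(x)) > threshold
    runs = []
    run_start = None
    for i, flag in enumerate(above):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            runs.append((run_start, i - 1))
            run_start = None
    if run_start is not None:
        runs.append((run_start, len(above) - 1))
    merged = []
    for start, end in runs:
        if merged and start - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return [(s + e) / 2.0 for s, e in merged if e - s + 1 >= min_samples]
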