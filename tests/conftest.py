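import numpy as np
import pytest

import fearcond as fc


@pytest.fixture(scope="session")
def schedule():
    """Standard 6-trial conditioning session: 5-min baseline, 30-s tones, 2-s shocks."""
    return fc.make_schedule("conditioning", n_trials=6, iti=60.0, seed=0)


@pytest.fixture(scope="session")
def behavior(schedule):
    return fc.simulate_behavior(schedule, freeze_prob_post_shock=0.4, seed=1)


@pytest.fixture(scope="session")
def speed_binned(schedule, behavior):
    return fc.bin_activity(behavior.speed, schedule.bin_width, behavior.sampling_rate)[: schedule.n_bins]


@pytest.fixture(scope="session")
def encoder(schedule, speed_binned):
    return fc.PopulationEncoder(schedule, speed_binned, trial_tests=True)


@pytest.fixture(scope="session")
def null_truth():
    def make(n, ar_coef=0.6, noise_sd=1.0, kernel_length=5):
        return [fc.GroundTruthTuning.null(kernel_length, ar_coef=ar_coef, noise_sd=noise_sd)
                for _ in range(n)]
    return make
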