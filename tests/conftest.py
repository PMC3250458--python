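import numpy as np
import pandas as pd
import pytest

from frontostriatal import synthetic as syn
from frontostriatal.designs import EventSchedule, build_task1_schedule


@pytest.fixture(scope="session")
def task1_schedule():
    return build_task1_schedule(40, seed=123)


@pytest.fixture(scope="session")
def clean_physio():
    """Noiseless, jitter-free 60 s physio recording at 1 Hz / 0.25 Hz."""
    return syn.simulate_physio(60.0, cardiac_hz=1.0, resp_hz=0.25, seed=0,
                               beat_jitter_frac=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def tiny_truth_factory():
    """GroundTruth on a 2x2x2 grid with one voxel region, configurable noise."""

    def make(noise=None, physio=None, amps=None):
        m = np.zeros((2, 2, 2), dtype=bool)
        m[0, 0, 0] = True
        return syn.GroundTruth(
            region_masks={"r": m},
            effect_amplitudes={"r": amps} if amps else {},
            noise=noise if noise is not None else syn.NoiseParams(),
            physio=physio if physio is not None else syn.PhysioParams(),
            shape=(2, 2, 2),
        )

    return make


def single_condition_schedule(onsets, label="target_L_small_pro", run_duration=None):
    """Schedule with one event type at explicit onsets (test helper)."""
    rows = [{"onset": float(o), "nominal_onset": float(o), "duration": 0.0,
             "trial_type": label, "jitter": 0.0} for o in onsets]
    if run_duration is None:
        run_duration = float(max(onsets)) + 12.0
    return EventSchedule(events=pd.DataFrame(rows), run_duration=run_duration)
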