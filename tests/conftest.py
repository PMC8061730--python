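import warnings

import numpy as np
import pytest

import ocumotor as om
from ocumotor.peri import TrialEvents


@pytest.fixture(scope="session")
def short_cfg():
    """A small but fully default-structured simulation config for unit tests."""
    return om.SimConfig(seed=7, trial_duration_s=60.0)


@pytest.fixture(scope="session")
def rendered_trial(short_cfg):
    """One rendered test trial with its ground truth."""
    gt = om.simulate_trial(short_cfg, participant=0, trial_index=0)
    rec = om.render_recording(gt, short_cfg)
    return gt, rec


def make_null_cohort(seed, n_participants=19, trials=8, duration=180.0):
    """Cohort of homogeneous-Poisson sessions (no rate modulation)."""
    cfg = om.null_config(
        seed=seed,
        n_participants=n_participants,
        trials_per_participant=trials,
        n_blank_trials=0,
        n_microshift_trials=0,
        trial_duration_s=duration,
    )
    return {
        p: [TrialEvents.from_ground_truth(gt) for gt in om.simulate_session(cfg, p)]
        for p in range(n_participants)
    }


def make_modulated_cohort(seed, n_participants=19, trials=8, duration=180.0):
    """Cohort with the default switch-locked dip/peak kernels."""
    cfg = om.SimConfig(
        seed=seed,
        n_participants=n_participants,
        trials_per_participant=trials,
        n_blank_trials=0,
        n_microshift_trials=0,
        trial_duration_s=duration,
    )
    return {
        p: [TrialEvents.from_ground_truth(gt) for gt in om.simulate_session(cfg, p)]
        for p in range(n_participants)
    }


def paired_series(cohort, event_type="blink", anchor_type="switch_to_coherent", cfg=None):
    from ocumotor.peri import PeriEventConfig, condition_timecourses

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return condition_timecourses(cohort, event_type, anchor_type, cfg or PeriEventConfig())
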