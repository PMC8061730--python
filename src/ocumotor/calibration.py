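"""Cohort-level simulation studies of the switch-locked analysis pipeline.

These routines drive the full generator -> peri-event -> cluster-test chain
over many simulated cohorts, either with no rate modulation (to measure the
family-wise false-positive rate of the cluster permutation test) or with
the default dip/peak kernels (to measure recovery of the injected
modulation).  They are used by the validation suite and the reproduction
script.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cluster import ClusterConfig, cluster_permutation_test
from .peri import PeriEventConfig, TrialEvents, condition_timecourses
from .synth import SimConfig, null_config, simulate_session


def _build_cohort(cfg: SimConfig) -> dict[int, list[TrialEvents]]:
    return {
        p: [TrialEvents.from_ground_truth(gt) for gt in simulate_session(cfg, p)]
        for p in range(cfg.n_participants)
    }


def _cohort_seed(seed: int, index: int) -> int:
    # distinct, reproducible per-cohort seeds below 2^31
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


@dataclass
class CohortOutcome:
    any_significant: bool
    dip_flagged: bool
    mean_switch_series: np.ndarray
    n_participants: int


def run_cohort(
    seed: int,
    modulated: bool,
    n_participants: int = 19,
    trials_per_participant: int = 8,
    trial_duration_s: float = 180.0,
    event_type: str = "blink",
    anchor_type: str = "switch_to_coherent",
    dip_window_s: tuple[float, float] = (-0.8, -0.2),
) -> CohortOutcome:
    """Simulate one cohort and run the paired cluster test.

    ``dip_flagged`` is True when a significant negative cluster overlaps
    the pre-switch dip window.
    """
    make = SimConfig if modulated else null_config
    cfg = make(
        seed=seed,
        n_participants=n_participants,
        trials_per_participant=trials_per_participant,
        n_blank_trials=0,
        n_microshift_trials=0,
        trial_duration_s=trial_duration_s,
    )
    cohort = _build_cohort(cfg)
    pcfg = PeriEventConfig()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a, b, kept = condition_timecourses(cohort, event_type, anchor_type, pcfg)
    res = cluster_permutation_test(a, b, ClusterConfig(seed=seed))
    centers = pcfg.bin_centers_s
    lo, hi = dip_window_s
    dip = any(
        c.p_value <= res.alpha
        and c.sign < 0
        and centers[c.first_bin] <= hi
        and centers[c.last_bin] >= lo
        for c in res.clusters
    )
    return CohortOutcome(
        any_significant=any(c.p_value <= res.alpha for c in res.clusters),
        dip_flagged=dip,
        mean_switch_series=a.mean(axis=0),
        n_participants=len(kept),
    )


def false_positive_rate(seed: int, n_cohorts: int = 200, **kwargs) -> float:
    """Fraction of null cohorts (no modulation) with any significant cluster."""
    hits = 0
    for i in range(n_cohorts):
        hits += run_cohort(_cohort_seed(seed, i), modulated=False, **kwargs).any_significant
    return hits / n_cohorts


def dip_recovery(
    seed: int, n_cohorts: int = 100, **kwargs
) -> tuple[float, np.ndarray, np.ndarray]:
    """Dip-detection rate plus the per-cohort times of the series extrema.

    Returns (flag_rate, argmin_times_s, argmax_times_s) over modulated
    cohorts simulated with the default dip/peak kernels.
    """
    centers = PeriEventConfig().bin_centers_s
    flags = 0
    tmins, tmaxs = [], []
    for i in range(n_cohorts):
        out = run_cohort(_cohort_seed(seed, 10_000 + i), modulated=True, **kwargs)
        flags += out.dip_flagged
        tmins.append(centers[int(np.argmin(out.mean_switch_series))])
        tmaxs.append(centers[int(np.argmax(out.mean_switch_series))])
    return flags / n_cohorts, np.asarray(tmins), np.asarray(tmaxs)
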