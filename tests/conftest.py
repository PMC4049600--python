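"""Shared fixtures: small simulated cohorts with known ground truth.

Everything is generated at test time from fixed seeds; the expensive
group-ICA decompositions are session-scoped so several test modules can
share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from nback_ica.ica import GroupDataset, run_group_ica
from nback_ica.simulate import (SimulationConfig, build_schedule_for,
                                generate_ground_truth, generate_subject_bold)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(grid_dims=(14, 14, 10), n_sources=8,
                            n_subjects_per_group=6, trials_per_block=20,
                            scans_per_condition=40, noise_sd=1.0,
                            drift_amplitude=0.5, seed=11)


@pytest.fixture(scope="session")
def noiseless_config() -> SimulationConfig:
    return SimulationConfig(grid_dims=(14, 14, 10), n_sources=8,
                            n_subjects_per_group=6, trials_per_block=20,
                            scans_per_condition=40, noise_sd=0.0,
                            drift_amplitude=0.0, hrf_delay_jitter_sd=0.0,
                            seed=11)


def _simulate(config):
    schedule = build_schedule_for(config)
    truth = generate_ground_truth(config)
    vols = [generate_subject_bold(truth, schedule, i, config)[0]
            for i in range(config.n_subjects)]
    dataset = GroupDataset.from_volumes(vols)
    return schedule, truth, dataset


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return _simulate(small_config)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config):
    return _simulate(noiseless_config)


@pytest.fixture(scope="session")
def noiseless_decomposition(noiseless_cohort):
    _, _, dataset = noiseless_cohort
    return run_group_ica(dataset, 8, n_runs=4, seed=5)


@pytest.fixture(scope="session")
def noisy_decomposition(small_cohort):
    _, _, dataset = small_cohort
    # two extra components absorb drift and noise structure
    return run_group_ica(dataset, 10, n_runs=4, seed=5)


def match_components(true_maps: np.ndarray, est_maps: np.ndarray):
    """(best |corr| per true source, matched component index)."""
    n = true_maps.shape[0]
    c = np.corrcoef(np.vstack([true_maps, est_maps]))[:n, n:]
    return np.abs(c).max(axis=1), np.abs(c).argmax(axis=1)
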