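"""Shared fixtures: the default synthetic subject and pre-computed bands.

Band fixtures are session-scoped because they drive several statistics
tests; everything derives from fixed seeds so the suite is reproducible.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from solband import (SolverOptions, SyntheticConfig, default_model,
                     make_gait_trial, run_band, sample_weight_chain)

TRIAL_SEED = 42
CHAIN_SEED = 2025


@pytest.fixture(scope="session")
def model12():
    return default_model()


@pytest.fixture(scope="session")
def noisy_trial(model12):
    """Default 12-muscle trial, EMG noise sd 0.03."""
    trial, truth = make_gait_trial(
        SyntheticConfig(seed=TRIAL_SEED, emg_noise_sd=0.03), model12)
    return trial, truth


@pytest.fixture(scope="session")
def clean_trial(model12):
    """Same trial with noiseless EMG (envelopes equal true activations)."""
    trial, truth = make_gait_trial(
        SyntheticConfig(seed=TRIAL_SEED, emg_noise_sd=0.0), model12)
    return trial, truth


@pytest.fixture(scope="session")
def band_pair_500(model12, noisy_trial):
    """500-sample unconstrained + EMG-constrained bands on the same chain."""
    trial, _ = noisy_trial
    chain = sample_weight_chain(model12.m, 500, model12.weight_levels,
                                seed=CHAIN_SEED)
    uncon = run_band(model12, trial, chain, "unconstrained", SolverOptions())
    emg = run_band(model12, trial, chain, "emg_constrained",
                   SolverOptions(emg_tolerance=0.05, reserve_enabled=True))
    return uncon, emg


@pytest.fixture(scope="session")
def band_1000(model12, noisy_trial):
    """1000-sample unconstrained band for equilibrium sweeps."""
    trial, _ = noisy_trial
    chain = sample_weight_chain(model12.m, 1000, model12.weight_levels,
                                seed=CHAIN_SEED + 1)
    return run_band(model12, trial, chain, "unconstrained", SolverOptions(),
                    keep_solutions=True)
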