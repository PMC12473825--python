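"""Shared fixtures: compact synthetic cohorts reused across the suite.

The compact plan keeps the four stages and activity mix of the full
acquisition protocol but shortens blocks so a subject lasts 3 minutes
instead of 30; session scope amortizes the simulation cost.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from tribp.pipeline import cohort_features
from tribp.preprocess import preprocess_record
from tribp.synth import (NoiseConfig, PhaseBlock, SynthConfig, TimingWander,
                         simulate_record)


def compact_plan() -> tuple[PhaseBlock, ...]:
    """Same stage/activity structure as the full protocol, 30 s labels."""
    blocks = [PhaseBlock(1, "rest", 4.0, 30.0, 110.0, 70.0, 70.0)]
    for stage in (2, 3, 4):
        blocks += [
            PhaseBlock(stage, "cycling", 4.0, 30.0, 135.0, 82.0, 100.0),
            PhaseBlock(stage, "recovery", 4.0, 30.0, 118.0, 74.0, 80.0),
            PhaseBlock(stage, "slow_breathing", 4.0, 30.0, 105.0, 68.0, 62.0),
        ]
    return tuple(blocks)


@pytest.fixture(scope="session")
def compact_config() -> SynthConfig:
    return SynthConfig(n_subjects=4, phase_plan=compact_plan(), seed=11)


@pytest.fixture(scope="session")
def silent_config(compact_config) -> SynthConfig:
    """Compact cohort with all noise amplitudes zero."""
    return dataclasses.replace(compact_config, noise=NoiseConfig.silent())


@pytest.fixture(scope="session")
def noiseless_clean_record(silent_config):
    """One noiseless record, preprocessed, with its ground truth."""
    record, gt = simulate_record(silent_config, 0)
    return preprocess_record(record), gt


@pytest.fixture(scope="session")
def compact_record(compact_config):
    record, gt = simulate_record(compact_config, 0)
    return record, gt


@pytest.fixture(scope="session")
def compact_features(compact_config) -> pd.DataFrame:
    """Feature table of the 4-subject compact cohort (112 segments)."""
    return cohort_features(compact_config)
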