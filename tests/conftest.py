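"""Shared fixtures.

The heavyweight session fixtures (a 30-phantom cohort with models trained
on the first 20 subjects) back both the end-to-end tests and the learned-
stage quality checks, so the expensive training happens exactly once per
session.
"""

import warnings

import numpy as np
import pytest

from autoknee import synthetic as syn
from autoknee.config import PipelineConfig
from autoknee.pipeline import train_models

warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")

COHORT_SEED = 11
N_TRAIN = 20
N_TEST = 10


@pytest.fixture(scope="session")
def cohort():
    """30 phantoms at default population parameters (fixed seed)."""
    params = syn.PopulationParams(n_subjects=N_TRAIN + N_TEST, seed=COHORT_SEED)
    return syn.generate_bone_population(params)


@pytest.fixture(scope="session")
def trained(cohort):
    """Models (classifier/detector/segmenters/SSMs) trained on 20 subjects."""
    models, fixtures = train_models(cohort[:N_TRAIN], PipelineConfig(), seed=COHORT_SEED)
    return models, fixtures


@pytest.fixture(scope="session")
def test_subjects(cohort):
    return cohort[N_TRAIN:]


@pytest.fixture(scope="session")
def phantom(test_subjects):
    """One held-out phantom voxelised with ground truth."""
    s = test_subjects[0]
    ct, gt = syn.voxelize_subject(s, seed=500, center_jitter_mm=4.0)
    return s, ct, gt


@pytest.fixture(scope="session")
def tiny_population():
    """Small noiseless population for fast shape-model unit tests."""
    params = syn.PopulationParams(n_subjects=8, seed=3, noise_sd_mm=0.0)
    return syn.generate_bone_population(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
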