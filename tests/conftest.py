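"""Shared fixtures.

The expensive fixture is ``desk_cohort``: an 8-subject cohort at the
desk profile (16 channels, 256 Hz, 120 trials per class) pushed through
the full cleaning/onset/epoching pipeline once per session and reused
by the parameter-recovery and trial-reduction tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from mrcperd.config import MCConfig, RunConfig, desk_profile
from mrcperd.testing import make_epochs  # noqa: F401  (fixture helper for tests)


def pytest_configure(config):
    warnings.filterwarnings("ignore", message="SOBI joint diagonalization")


DESK_SEED = 20230911  # cohort seed for the recovery/reduction fixtures
MC_REALIZATIONS = 100


@pytest.fixture(scope="session")
def desk_run_config() -> RunConfig:
    return RunConfig(
        gen=desk_profile(n_subjects=8, seed=DESK_SEED),
        mc=MCConfig(n_realizations=MC_REALIZATIONS, seed=DESK_SEED + 1),
        seed=DESK_SEED,
    )


@pytest.fixture(scope="session")
def desk_cohort(desk_run_config):
    """Desk cohort pushed through the full pipeline, one subject at a time.

    Only the result tables and ground truths are retained (a subject's
    band-filtered epoch sets are sizeable); returns a dict with
    ``features``, ``mc`` (Monte Carlo feature table), ``truths``
    (subject -> condition -> GroundTruth) and ``counts``.
    """
    from mrcperd.features import extract_features
    from mrcperd.montecarlo import mc_features
    from mrcperd.pipeline import process_subject
    from mrcperd.synth import generate_cohort

    cfg = desk_run_config
    feat_frames, mc_frames, count_frames, truths = [], [], [], {}
    for data in generate_cohort(cfg.gen):
        cells, counts = process_subject(data, cfg)
        feat_frames.append(extract_features(cells, cfg.mrcp, cfg.erd_mu, cfg.erd_beta))
        mc_frames.append(mc_features(cells, cfg.mc, cfg.mrcp, cfg.erd_mu, cfg.erd_beta))
        count_frames.append(counts)
        truths[data.subject] = data.truth
        del cells
    return {
        "features": pd.concat(feat_frames, ignore_index=True),
        "mc": pd.concat(mc_frames, ignore_index=True),
        "counts": pd.concat(count_frames, ignore_index=True),
        "truths": truths,
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
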