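"""Shared fixtures: one fully synthesized session reused across modules."""

import numpy as np
import pytest

import dyadphys as dp


@pytest.fixture(scope="session")
def default_config():
    return dp.SynthesisConfig(seed=11)


@pytest.fixture(scope="session")
def pc_session(default_config):
    """One personal-communication session with ground truth (full length)."""
    rng = np.random.default_rng(2024)
    return dp.synthesize_session(default_config, "PC", "proposer", rng,
                                 subject_id="PC01")


@pytest.fixture(scope="session")
def pc_alignment(pc_session):
    session, _ = pc_session
    return dp.align_session(session)


@pytest.fixture(scope="session")
def pc_features(pc_session, pc_alignment):
    session, _ = pc_session
    return dp.extract_features(session, pc_alignment)


@pytest.fixture(scope="session")
def small_cohort_features():
    """Extracted features of a reduced two-condition cohort (4 + 4)."""
    cfg = dp.SynthesisConfig(seed=5, n_per_condition=4)
    cohort = dp.generate_cohort(cfg)
    feats = dp.extract_cohort_features([s for s, _ in cohort])
    truths = [t for _, t in cohort]
    return feats, truths
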