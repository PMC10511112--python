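"""Shared fixtures.

The expensive artifacts (a trained declarative memory, a full simulated
participant) are session-scoped and built lazily, so unit-test runs that do
not touch them stay fast.
"""

import numpy as np
import pytest

from neurocog.config import RunConfig
from neurocog.runner import (mini_study_list, simulate_participant,
                             train_memories_for_design, pair_name)
from neurocog.spa import Vocabulary


@pytest.fixture(scope="session")
def participant():
    """One simulated participant at desk scale (20 balanced trials)."""
    cfg = RunConfig()
    cfg.n_trials = 20
    return simulate_participant(cfg, seed=1)


@pytest.fixture(scope="session")
def trained_memories():
    """Trained familiarity + declarative modules on a mini study list."""
    cfg = RunConfig()
    study = mini_study_list(3)
    vocab, fam, dec, pair_vectors = train_memories_for_design(
        study, cfg.model, seed=3)
    return dict(study=study, vocab=vocab, familiarity=fam,
                declarative=dec, pair_vectors=pair_vectors)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def vocab64():
    v = Vocabulary(64, rng_seed=7)
    v.make_pointer("ITEM1")
    v.make_pointer("ITEM2")
    return v
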