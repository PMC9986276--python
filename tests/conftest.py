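"""Shared fixtures: synthetic datasets and trained models reused across
test modules.  Heavy artifacts (the full-size trained classifier) are
session-scoped so the expensive training runs once."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from emotifre.model import Hyperparams, train
from emotifre.simulate import SimConfig, make_motif_db, simulate_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


QUICK_HP = Hyperparams(n_filters=16, kernel_size=12, dense_units=16,
                       max_epochs=60, patience=8, seed=11)


@pytest.fixture(scope="session")
def separable_dataset():
    """The reference study conditions: 2,000+2,000 x 200 bp, GC 0.55/0.45,
    ASCL1-like core implanted in 40% of positives, seed 1."""
    pos, neg, truth = simulate_dataset(SimConfig(seed=1))
    return pos, neg, truth


@pytest.fixture(scope="session")
def separable_model(separable_dataset):
    """Classifier trained on the reference synthetic conditions."""
    pos, neg, _ = separable_dataset
    model, report = train(pos, neg, Hyperparams(seed=1))
    return model, report


@pytest.fixture(scope="session")
def small_dataset():
    """A small, strongly separable set for fast unit tests: 300+300 x 100 bp
    with the motif in 70% of positives."""
    from emotifre.simulate import ImplantSpec

    cfg = SimConfig(n_pos=300, n_neg=300, length=100, gc_pos=0.55, gc_neg=0.45,
                    implants=[ImplantSpec("CAGCTGC", "positive", 0.7)], seed=11)
    pos, neg, truth = simulate_dataset(cfg)
    return pos, neg, truth


@pytest.fixture(scope="session")
def small_model(small_dataset):
    pos, neg, _ = small_dataset
    model, report = train(pos, neg, QUICK_HP)
    return model, report


@pytest.fixture(scope="session")
def toy_db():
    return make_motif_db(seed=0)
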