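"""Shared fixtures: montage, a cached simulated subject and its decompositions.

The simulated subject is session-scoped because ICA on a full session is the
expensive step; every test that needs a realistic session shares it.
"""

from __future__ import annotations

import numpy as np
import pytest

from rest2task.decomposition import apply_filters, decompose_state
from rest2task.forward import default_montage
from rest2task.io import state_segments
from rest2task.motor_ic import canonical_motor_template
from rest2task.simulate import SimConfig, default_scene, simulate_session

SUBJECT_SEED = 101


@pytest.fixture(scope="session")
def montage():
    labels, pos = default_montage()
    return labels, pos


@pytest.fixture(scope="session")
def sim_subject():
    """One default-scene subject: 50 trials/class, seeded."""
    cfg = SimConfig(default_scene(), n_trials_per_class=50, seed=SUBJECT_SEED)
    ts, truth = simulate_session(cfg)
    return cfg, ts, truth


@pytest.fixture(scope="session")
def rest_decomposition(sim_subject):
    cfg, ts, _ = sim_subject
    X = state_segments(ts, "rest")
    dec = decompose_state(X, seed=SUBJECT_SEED, state_tag="rest")
    tc = apply_filters(dec, X)
    tc.fs = ts.fs
    return dec, tc


@pytest.fixture(scope="session")
def imagery_decomposition(sim_subject):
    cfg, ts, _ = sim_subject
    X = state_segments(ts, "imagery")
    dec = decompose_state(X, seed=SUBJECT_SEED, state_tag="imagery")
    tc = apply_filters(dec, X)
    tc.fs = ts.fs
    return dec, tc


@pytest.fixture(scope="session")
def motor_template(montage):
    labels, pos = montage
    return canonical_motor_template(labels, pos)


@pytest.fixture(scope="session")
def rest_selection(sim_subject, rest_decomposition, motor_template):
    from rest2task.motor_ic import select_motor_ics

    cfg, ts, _ = sim_subject
    dec, tc = rest_decomposition
    return select_motor_ics(dec, tc, motor_template, cfg.montage)


@pytest.fixture(scope="session")
def imagery_selection(sim_subject, imagery_decomposition, motor_template):
    from rest2task.motor_ic import select_motor_ics

    cfg, ts, _ = sim_subject
    dec, tc = imagery_decomposition
    return select_motor_ics(dec, tc, motor_template, cfg.montage)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
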