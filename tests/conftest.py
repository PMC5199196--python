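"""Shared fixtures: expensive synthetic sessions computed once per run."""

from __future__ import annotations

import numpy as np
import pytest

import nmlock as nl
from nmlock.experiments import whitenoise_phases


@pytest.fixture(scope="session")
def coupled_kuramoto_100s():
    """Coupled 1:5 Kuramoto pair (8/43 Hz natural, eps=10), 100 s."""
    params = nl.KuramotoParams()
    return nl.simulate_kuramoto_pair(params, 100.0, seed=11)


@pytest.fixture(scope="session")
def uncoupled_kuramoto_100s():
    params = nl.KuramotoParams(epsilon=0.0)
    return nl.simulate_kuramoto_pair(params, 100.0, seed=12)


@pytest.fixture(scope="session")
def whitenoise_theta_gammas_100s():
    """100 s white-noise session: Hilbert phases in theta (4-12 Hz) and
    slow-gamma (30-50 Hz) bands, filter edges dropped."""
    return whitenoise_phases(100.0, seed=13)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
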