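"""Shared fixtures: default parameters and fast, coarse solver settings.

The coarse settings (h = 0.05, IMEX dt = 2e-4, short horizons) keep the
suite fast while exercising every code path; the few tests that need the
production resolution (h = 0.02, dt = 1e-4, t_max = 5) build it themselves
and share results through module-scoped fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

from decoychemo import (
    DimensionalParameters,
    build_grid,
    nondimensionalize,
)

# Global memo for expensive full-resolution runs shared across test modules.
_RUN_CACHE: dict = {}


@pytest.fixture(scope="session")
def params():
    """Default dimensional parameter set."""
    return DimensionalParameters()


@pytest.fixture(scope="session")
def dimless(params):
    return nondimensionalize(params)


@pytest.fixture(scope="session")
def coarse():
    """Fast solver controls used by most spatial tests."""
    return dict(h=0.05, dt=2e-4, stepper="imex")


@pytest.fixture(scope="session")
def grid(dimless):
    return build_grid(dimless, h=0.02)


@pytest.fixture(scope="session")
def coarse_grid(dimless):
    return build_grid(dimless, h=0.05)


def cached_run(key, builder):
    """Memoize expensive simulations across test modules (deterministic)."""
    if key not in _RUN_CACHE:
        _RUN_CACHE[key] = builder()
    return _RUN_CACHE[key]


@pytest.fixture(scope="session")
def default_run(params):
    """Full-resolution default run to t=5 (shared by several tests)."""
    from decoychemo import simulate

    return cached_run(
        "default_full",
        lambda: simulate(params, h=0.02, dt=1e-4, t_max=5.0,
                         snapshot_times=(1.0, 3.0, 5.0)),
    )
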