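"""Shared fixtures.

The expensive tensile-run pool is session-scoped and shared by the
mechanistic acceptance tests; everything else is cheap and rebuilt per test.
"""

from __future__ import annotations

import pytest

from fibrilmd.builder import MINI_SPEC, make_fixture
from fibrilmd.crosslinker import CrosslinkConfig
from fibrilmd.engine import Protocol, minimize, run_protocol
from fibrilmd.forcefield import ForceFieldParams


@pytest.fixture(scope="session")
def params() -> ForceFieldParams:
    return ForceFieldParams.default()


@pytest.fixture(scope="session")
def mini_minimized(params):
    """Mini fibril after energy minimization (positions only, no dynamics)."""
    system, topology = make_fixture("mini-fibril")
    system, _ = minimize(system, topology, params)
    return system, topology


def mini_protocol(seed: int, **overrides) -> Protocol:
    """Desk-scale protocol used by every mini tensile run in the suite."""
    kwargs = dict(
        equil_duration=1.0e5,
        reequil_duration=5.0e4,
        equil_timestep=10.0,
        tensile_timestep=20.0,
        pulling_speed=1.0e-4,
        sample_interval=2000.0,
        max_strain=1.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return Protocol(**kwargs)


_RUN_CACHE: dict = {}


def mini_run(n_age: float, ecl: float, seed: int, valence: str = "divalent"):
    """Cached full-protocol mini run for the given cross-link conditions."""
    key = (n_age, ecl, seed, valence)
    if key not in _RUN_CACHE:
        cc = CrosslinkConfig(
            ecl_content=ecl, ecl_valence=valence, n_age=n_age, seed=seed + 1
        )
        _RUN_CACHE[key] = run_protocol(MINI_SPEC, cc, mini_protocol(seed))
    return _RUN_CACHE[key]


#: seeds used for the mechanistic (scaled-down) acceptance checks
POOL_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def pool_no_ecl():
    """Mini tensile runs without enzymatic cross-links over the AGE-density
    sweep {0.5, 2, 10, 40}, two seeds each."""
    return {
        (n_age, seed): mini_run(n_age, 0.0, seed)
        for n_age in (0.5, 2.0, 10.0, 40.0)
        for seed in (1, 2)
    }


@pytest.fixture(scope="session")
def pool_ecl25():
    """Mini tensile runs at 25% divalent ECL content, N_AGE ∈ {1, 40},
    three seeds each (the failure-statistics conditions)."""
    return {
        (n_age, seed): mini_run(n_age, 25.0, seed)
        for n_age in (1.0, 40.0)
        for seed in POOL_SEEDS
    }
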