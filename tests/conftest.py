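"""Shared fixtures: small and full-scale simulated studies.

The homology maps are deterministic in (catalog, panel), so they are built
once per session and reused across the many-seed simulation tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from mirspike.homology import build_homology_map
from mirspike.simulate import (
    default_catalogs,
    default_profiles,
    make_panel,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_panel():
    return make_panel(n_pool_a=18, n_pool_b=16, seed=11)


@pytest.fixture(scope="session")
def small_catalogs(small_panel):
    return default_catalogs(small_panel, seed=11)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_homology(small_catalogs, small_panel):
    return {
        name: build_homology_map(cat, small_panel)
        for name, cat in small_catalogs.items()
    }


@pytest.fixture(scope="session")
def small_study(small_panel, small_catalogs, profiles, small_homology):
    return simulate_study(
        small_panel, small_catalogs, profiles, seed=5,
        n_endogenous=15, homology=small_homology,
    )


@pytest.fixture(scope="session")
def small_study_factory(small_panel, small_catalogs, small_homology):
    """Callable: (seed, profiles) -> study, reusing the cached homology maps."""

    def build(seed, profiles_, **kwargs):
        kwargs.setdefault("n_endogenous", 15)
        return simulate_study(
            small_panel, small_catalogs, profiles_, seed=seed,
            homology=small_homology, **kwargs,
        )

    return build


@pytest.fixture(scope="session")
def full_panel():
    return make_panel(seed=7)


@pytest.fixture(scope="session")
def full_catalogs(full_panel):
    return default_catalogs(full_panel, seed=7)


@pytest.fixture(scope="session")
def full_study(full_panel, full_catalogs, profiles):
    return simulate_study(full_panel, full_catalogs, profiles, seed=17)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
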