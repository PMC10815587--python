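"""Shared fixtures: desk-scale scenario objects reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from spatialcontact.fragment_map import FragmentMap
from spatialcontact.synthetic_data import (
    SyntheticScenario,
    default_scenario,
    simulate_fragment_map,
)


@pytest.fixture(scope="session")
def scenario() -> SyntheticScenario:
    return default_scenario(seed=0)


@pytest.fixture(scope="session")
def fragmap(scenario):
    return simulate_fragment_map(scenario)


@pytest.fixture(scope="session")
def null_scenario() -> SyntheticScenario:
    """No planted 4C domains, flat expression profiles."""
    return SyntheticScenario(
        seed=0,
        cluster_profiles={i: (0.0,) * 5 for i in range(1, 5)},
    )


def make_fragment_map(
    site_positions: dict[str, list[int]], chrom_lengths: dict[str, int]
) -> FragmentMap:
    """Hand-built map from explicit site positions (test helper)."""
    fragments = {}
    sites = {}
    for chrom, length in chrom_lengths.items():
        pos = np.asarray(site_positions.get(chrom, []), dtype=np.int64)
        bounds = np.concatenate(([0], pos, [length]))
        fragments[chrom] = np.column_stack((bounds[:-1], bounds[1:]))
        sites[chrom] = pos
    return FragmentMap(dict(chrom_lengths), fragments, sites)


@pytest.fixture
def ten_site_map() -> FragmentMap:
    """One chromosome, 10 sites at 100..1000, length 1100."""
    return make_fragment_map(
        {"chrT": list(range(100, 1100, 100))}, {"chrT": 1100}
    )
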