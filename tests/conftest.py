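"""Shared fixtures: small simulated populations and maps, all seeded."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from abqtl import simpop

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_map() -> simpop.GeneticMap:
    """21-chromosome map, 10 loci per chromosome, real-panel ~1 cM spacing."""
    return simpop.uniform_map(210, chromosome_length_cM=9.0)


@pytest.fixture(scope="session")
def small_population(small_map):
    """SW84-scheme population at reduced scale: 60 + 80 lines, no missing calls."""
    scheme = simpop.CrossingScheme(
        family_sizes={"D84": 60, "T84": 80}, n_bc1_plants={"D84": 27, "T84": 18}
    )
    genotypes, families = simpop.simulate_population(scheme, small_map, rng=7)
    return genotypes, families


@pytest.fixture(scope="session")
def toy_phenotypes() -> pd.DataFrame:
    """Three lines x two environments x two N levels, fixed values."""
    rows = []
    vals = iter(
        [10.0, 12.0, 11.0, 13.0, 20.0, 22.0, 21.0, 23.0, 30.0, 32.0, 31.0, 33.0]
    )
    for line in ("L1", "L2", "L3"):
        for env in ("E1", "E2"):
            for nl in ("N0", "N1"):
                rows.append((line, env, nl, "T", next(vals)))
    return pd.DataFrame(rows, columns=["line_id", "environment", "n_level", "trait", "value"])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_101)
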