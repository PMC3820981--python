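import numpy as np
import pytest

from coretrace import load_expedition_table
from coretrace.screen import MudType
from coretrace.simulate import (
    GUAR_GUM_DOMINANCE,
    CommunitySpec,
    LibrarySpec,
    make_library,
    make_mud_library,
    make_taxa,
)


@pytest.fixture(scope="session")
def expedition_table():
    return load_expedition_table()


@pytest.fixture(scope="session")
def community():
    """Default two-pool community at full amplicon length."""
    return make_taxa(CommunitySpec(seed=42, dominance=GUAR_GUM_DOMINANCE))


@pytest.fixture(scope="session")
def small_community():
    """Short-sequence community for cheap property sweeps."""
    return make_taxa(
        CommunitySpec(seed=7, n_mud_taxa=5, n_indigenous_taxa=5, seq_length=100)
    )


@pytest.fixture(scope="session")
def mud_library(community):
    return make_mud_library(community, 50, "guar_mud", MudType.GUAR_GUM, seed=101)


@pytest.fixture(scope="session")
def small_mud_library(small_community):
    return make_mud_library(small_community, 12, "small_mud", MudType.SEAWATER_GEL, seed=5)


@pytest.fixture(scope="session")
def core_library_52(community, mud_library):
    return make_library(
        community,
        LibrarySpec(n_clones=100, contamination_fraction=0.52, seed=11),
        sample_id="core_52",
        mud_library=mud_library,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
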