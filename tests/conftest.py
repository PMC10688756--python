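import dendropy
import numpy as np
import pandas as pd
import pytest

from anurasem import synthetic as syn
from anurasem.data_io import CommunityMatrix


def tree_from_newick(newick: str) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    t.is_rooted = True
    return t


@pytest.fixture
def three_tip_tree():
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four_tip_tree():
    return tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")


def community_from_sets(site_species: dict[str, list[str]], species: list[str]):
    inc = pd.DataFrame(
        [[1 if s in members else 0 for s in species] for members in site_species.values()],
        index=pd.Index(list(site_species), name="site"),
        columns=pd.Index(species, name="species"),
        dtype="int8",
    )
    rng = np.random.default_rng(abs(hash(tuple(site_species))) % 2**31)
    coords = pd.DataFrame(
        {
            "longitude": rng.uniform(-50, -40, len(inc)),
            "latitude": rng.uniform(-25, -10, len(inc)),
        },
        index=inc.index,
    )
    return CommunityMatrix(incidence=inc, coordinates=coords)


@pytest.fixture(scope="session")
def small_scenario():
    """A 40-species, 80-site synthetic study system shared across tests."""
    cfg = syn.ScenarioConfig(
        n_species=40,
        n_sites=80,
        dd_fraction=0.2,
        dd_clade_count=2,
        missing_fraction={"head_width": 0.25, "tibia_length": 0.25},
        seed=42,
    )
    return syn.make_scenario(cfg)


@pytest.fixture(scope="session")
def study_scenario():
    """The full-size study-conditions scenario (766 sites × 464 species)."""
    return syn.make_scenario(syn.ScenarioConfig(seed=1))
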