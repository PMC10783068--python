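import numpy as np
import pandas as pd
import pytest

from hadal.io_formats import AbundanceTable, tree_from_newick
from hadal.synthetic_community import SimulationConfig, simulate_neutral, simulate_niche


@pytest.fixture
def toy_table():
    """3 taxa x 2 samples with counts [[5,0],[0,7],[1,1]]."""
    counts = pd.DataFrame(
        [[5, 0], [0, 7], [1, 1]], index=["t1", "t2", "t3"], columns=["s1", "s2"]
    )
    return AbundanceTable(counts)


@pytest.fixture
def cherry_tree():
    """((A:1,B:1):1,C:2); patristic: A-B 2, A-C 4, B-C 4."""
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    """Rooted star: every tip at distance 1 from the root, all pairs at 2."""
    return tree_from_newick("((A:1,B:1):0,(C:1,D:1):0);")


def random_table(rng, n_taxa=6, n_samples=4, prefix="t"):
    counts = rng.integers(0, 20, size=(n_taxa, n_samples))
    # keep every sample and taxon nonzero so all metrics are defined
    counts[rng.integers(0, n_taxa), :] += 1
    counts[:, counts.sum(axis=0) == 0] += 1
    counts[counts.sum(axis=1) == 0, 0] += 1
    return AbundanceTable(
        pd.DataFrame(
            counts,
            index=[f"{prefix}{i}" for i in range(n_taxa)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )


@pytest.fixture(scope="session")
def small_neutral():
    """A modest neutral community reused across tests (deterministic)."""
    cfg = SimulationConfig(
        n_taxa=120,
        m=0.5,
        local_size=2000,
        sequencing_depth=4000,
        generations=20,
        seed=42,
    )
    return simulate_neutral(cfg)


@pytest.fixture(scope="session")
def small_niche():
    """Strongly filtered, phylogenetically conserved community."""
    cfg = SimulationConfig(
        n_taxa=120,
        mode="niche",
        sigma=0.3,
        conservatism=1.0,
        sequencing_depth=4000,
        seed=7,
    )
    return simulate_niche(cfg)
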