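import numpy as np
import pytest

from microniche import (OtuTable, SampleMetadata, SyntheticSpec,
                        generate_community, infer_network)


@pytest.fixture
def tiny_table():
    return OtuTable(
        ["otu1", "otu2", "otu3"],
        ["s1", "s2", "s3", "s4"],
        np.array([[5, 5, 5, 5],
                  [10, 0, 0, 0],
                  [1, 3, 0, 2]]),
    )


@pytest.fixture
def tiny_metadata():
    return SampleMetadata(region={"s1": "north", "s2": "north",
                                  "s3": "south", "s4": "south"})


def random_table(rng, max_otus=50, max_samples=20):
    p = rng.integers(2, max_otus + 1)
    n = rng.integers(2, max_samples + 1)
    counts = rng.integers(0, 50, size=(p, n))
    # keep every column non-empty
    for j in np.flatnonzero(counts.sum(axis=0) == 0):
        counts[rng.integers(p), j] = 1
    return OtuTable([f"o{i}" for i in range(p)],
                    [f"s{j}" for j in range(n)], counts)


@pytest.fixture(scope="session")
def default_community():
    """The planted recovery community: 3 regions x 60 samples, 20
    generalists (16 in correlated blocks), 30 specialists/region, 320
    medium OTUs, depth 10,000."""
    return generate_community(SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def default_community_network(default_community):
    """Ensemble network of the recovery community (200 perms/boots)."""
    table, _, _ = default_community
    return infer_network(table, n_permutations=200, n_bootstraps=200,
                         random_state=11, apply_prevalence_filter=True)
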