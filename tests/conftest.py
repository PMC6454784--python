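import numpy as np
import pytest

from rflpdelta import (
    PRIMER_799F,
    PRIMER_U1492R,
    PoolSpec,
    generate_pool,
    profile_otu,
)


@pytest.fixture(scope="session")
def pool20():
    """A 20-OTU default-structure pool (multi-operon OTUs included)."""
    return generate_pool(PoolSpec(n_otus=20, seed=7))


@pytest.fixture(scope="session")
def pool20_profiles(pool20):
    return {
        r.otu_id: profile_otu(r, PRIMER_799F, PRIMER_U1492R)
        for r in pool20.records
    }


@pytest.fixture(scope="session")
def distinct_pool():
    """Small pool with pool-wide distinct fragment lengths: 4 in-window
    fragments per OTU, no cross-OTU band collisions."""
    spec = PoolSpec(
        n_otus=10,
        fragments_per_amplicon=(4, 4),
        multi_operon_fraction=0.0,
        distinct_across_otus=True,
        seed=5,
    )
    return generate_pool(spec)


@pytest.fixture(scope="session")
def distinct_profiles(distinct_pool):
    return {
        r.otu_id: profile_otu(r, PRIMER_799F, PRIMER_U1492R)
        for r in distinct_pool.records
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
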