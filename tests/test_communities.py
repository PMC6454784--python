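"""Randomized and stepwise-nested mock-community assembly."""

import math

import numpy as np
import pytest

from rflpdelta import (
    DEFAULT_CRITERIA,
    FragmentProfile,
    GelModel,
    MockCommunity,
    RandomizationDesign,
    assemble_nested_mbcs,
    assemble_random_mbcs,
    summarize_groups,
    theoretical_count,
)
from rflpdelta.communities import MissingProfileError

GEL = GelModel(5, None, None, "strict")


def _ids(n):
    return [f"O{i:03d}" for i in range(n)]


def test_randomized_design_structure():
    design = RandomizationDesign.multiples_of_five(50, replicates_per_group=10, seed=1)
    comms = assemble_random_mbcs(_ids(50), design)
    # 9 partial groups x 10 replicates + the single full-pool community
    assert len(comms) == 9 * 10 + 1
    sizes = {c.group_size for c in comms}
    assert sizes == set(range(5, 51, 5))
    full = [c for c in comms if c.group_size == 50]
    assert len(full) == 1 and full[0].members == set(_ids(50))
    for c in comms:
        assert len(c.members) == c.group_size  # no duplicate members


def test_single_group_equal_to_pool():
    design = RandomizationDesign(5, (5,), replicates_per_group=3000, seed=0)
    comms = assemble_random_mbcs(_ids(5), design)
    assert len(comms) == 1 and comms[0].members == set(_ids(5))


def test_group_larger_than_pool_rejected():
    with pytest.raises(ValueError):
        RandomizationDesign(10, (15,))


def test_randomization_reproducible_and_substream_stable():
    base = RandomizationDesign(30, (5, 10), replicates_per_group=20, seed=42)
    a = assemble_random_mbcs(_ids(30), base)
    b = assemble_random_mbcs(_ids(30), base)
    assert [c.member_otu_ids for c in a] == [c.member_otu_ids for c in b]
    # adding a group size must not perturb draws of existing groups
    wider = RandomizationDesign(30, (5, 10, 15), replicates_per_group=20, seed=42)
    c = assemble_random_mbcs(_ids(30), wider)
    small_a = [x.member_otu_ids for x in a if x.group_size == 5]
    small_c = [x.member_otu_ids for x in c if x.group_size == 5]
    assert small_a == small_c


@pytest.fixture(scope="module")
def nested72():
    tags = {f"B{i:02d}": "focal" for i in range(45)}
    tags.update({f"N{i:02d}": "other" for i in range(27)})
    return tags, assemble_nested_mbcs(tags, DEFAULT_CRITERIA, seed=3)


def test_nested_design_counts_and_types(nested72):
    _, comms = nested72
    assert len(comms) == 30  # 5 types x 6 sizes
    assert {c.mbc_type for c in comms} == {"I", "II", "III", "IV", "V"}


def test_nested_composition_criteria(nested72):
    tags, comms = nested72

    def n_focal(c):
        return sum(1 for o in c.member_otu_ids if tags[o] == "focal")

    for c in comms:
        if c.mbc_type == "V":
            assert n_focal(c) == c.group_size
        elif c.mbc_type in ("III", "IV"):
            assert n_focal(c) == round(0.2 * c.group_size)
        elif c.mbc_type == "II" and c.group_size < 30:
            assert n_focal(c) == 0
    # only 27 non-focal OTUs exist: the 30-OTU no-focal community needs 3
    (t2_30,) = [c for c in comms if c.mbc_type == "II" and c.group_size == 30]
    assert n_focal(t2_30) == 3


def test_nested_chains_are_strict_supersets(nested72):
    _, comms = nested72
    for t in "I II III IV V".split():
        chain = sorted(
            (c for c in comms if c.mbc_type == t), key=lambda c: c.group_size
        )
        for small, big in zip(chain, chain[1:]):
            assert small.members < big.members


def test_types_iii_and_iv_draw_distinct_compositions(nested72):
    _, comms = nested72
    m3 = {c.group_size: c.members for c in comms if c.mbc_type == "III"}
    m4 = {c.group_size: c.members for c in comms if c.mbc_type == "IV"}
    assert any(m3[g] != m4[g] for g in m3)


def test_theoretical_count_merging_rule():
    profiles = {
        "a": FragmentProfile("a", [100, 250]),
        "b": FragmentProfile("b", [102, 400]),
    }
    c = MockCommunity("c", ("a", "b"), 2)
    bs = theoretical_count(c, profiles, GEL)
    assert bs.n_bands == 3
    assert bs.bands == [100, 250, 400]
    assert bs.contributing(0) == {"a", "b"}

    single = MockCommunity("s", ("a",), 1)
    assert theoretical_count(single, profiles, GEL).n_bands == 2


def test_missing_profile_names_the_otu():
    c = MockCommunity("c", ("a", "zz"), 2)
    with pytest.raises(MissingProfileError, match="zz"):
        theoretical_count(c, {"a": FragmentProfile("a", [100])}, GEL)


def test_subadditivity_and_nested_monotonicity(pool20_profiles):
    ids = sorted(pool20_profiles)
    a = MockCommunity("a", tuple(ids[:6]), 6)
    b = MockCommunity("b", tuple(ids[6:12]), 6)
    ab = MockCommunity("ab", tuple(ids[:12]), 12)
    na = theoretical_count(a, pool20_profiles, GEL).n_bands
    nb = theoretical_count(b, pool20_profiles, GEL).n_bands
    nab = theoretical_count(ab, pool20_profiles, GEL).n_bands
    assert nab <= na + nb
    # nested growth is monotone
    counts = [
        theoretical_count(
            MockCommunity(f"n{k}", tuple(ids[:k]), k), pool20_profiles, GEL
        ).n_bands
        for k in range(2, 20, 3)
    ]
    assert counts == sorted(counts)


def test_saturation_bound_under_windowed_gel(pool20_profiles):
    gel = GelModel(5, 50, 500, "strict")
    ceiling = math.floor((500 - 50) / 5) + 1
    ids = sorted(pool20_profiles)
    c = MockCommunity("all", tuple(ids), len(ids))
    assert theoretical_count(c, pool20_profiles, gel).n_bands <= ceiling


def test_summarize_groups_closed_forms():
    comms = [
        MockCommunity("a", ("x",), 1),
        MockCommunity("b", ("y",), 1),
        MockCommunity("c", ("z",), 1),
        MockCommunity("d", ("x", "y"), 2),
        MockCommunity("e", ("y", "z"), 2),
    ]
    counts = {"a": 3, "b": 3, "c": 3, "d": 2, "e": 4}
    df = summarize_groups(comms, counts).set_index("group_size")
    assert df.loc[1, "mean_bands"] == 3 and df.loc[1, "sd_bands"] == 0
    assert df.loc[2, "mean_bands"] == 3
    assert df.loc[2, "sd_bands"] == pytest.approx(np.sqrt(2))


def test_collision_free_pool_counts_are_exact(distinct_pool, distinct_profiles):
    """Every OTU contributes 4 distinct in-window fragments with no
    cross-OTU collisions, so theoretical counts are 4 x group size."""
    ids = sorted(distinct_profiles)
    gel = GelModel(5, 50, 500, "strict")
    for k in (2, 5, 10):
        c = MockCommunity(f"k{k}", tuple(ids[:k]), k)
        assert theoretical_count(c, distinct_profiles, gel).n_bands == 4 * k
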