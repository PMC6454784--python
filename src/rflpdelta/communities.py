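"""Mock bacterial community (MBC) assembly and theoretical band counting.

Two assembly designs are provided, mirroring the two arms of the study:

* **Randomized** — groups of "multiple-of-five" OTUs drawn uniformly
  without replacement from a registered pool, many replicates per group
  size (default 3000), plus the single full-pool community when the pool
  size itself is a group size. A 50-OTU pool with sizes 5-50 therefore
  yields 3000 x 9 + 1 = 27,001 communities.
* **Stepwise nested** — five composition types built by adding five new
  members at each size step, so each community is a strict superset of the
  previous size of its type. Composition criteria constrain the fraction
  of "focal"-tagged members (e.g. a dominant genus): type I unconstrained,
  II none, III/IV 20% with distinct draws, V only focal.

The *theoretical* band count of a community pools the members' individual
digestion profiles — obtained before any co-amplification — and merges
them at gel resolution; it is the maximum number of bands the community
could show.

Randomness is consumed from a dedicated PRNG sub-stream per (group size,
replicate) or (type, size step), derived from the design seed via
``numpy.random.SeedSequence`` spawn keys, so enlarging the design never
perturbs earlier draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .digestion import BandSet, FragmentProfile, GelModel, merge_bands

logger = logging.getLogger(__name__)

__all__ = [
    "RandomizationDesign",
    "MockCommunity",
    "CompositionCriteria",
    "DEFAULT_CRITERIA",
    "MissingProfileError",
    "assemble_random_mbcs",
    "assemble_nested_mbcs",
    "theoretical_count",
    "summarize_groups",
]


class MissingProfileError(KeyError):
    """A community member has no digestion profile."""

    def __init__(self, otu_id: str):
        self.otu_id = otu_id
        super().__init__(f"no fragment profile for OTU {otu_id!r}")


@dataclass(frozen=True)
class RandomizationDesign:
    """Randomized-assembly design: group sizes, replicates, seed."""

    pool_size: int
    group_sizes: tuple[int, ...]
    replicates_per_group: int = 3000
    seed: int = 0

    def __post_init__(self):
        if self.replicates_per_group < 1:
            raise ValueError("replicates_per_group must be >= 1")
        if any(g < 1 or g > self.pool_size for g in self.group_sizes):
            raise ValueError(
                f"group sizes must lie in [1, pool_size={self.pool_size}]"
            )

    @classmethod
    def multiples_of_five(
        cls, pool_size: int, replicates_per_group: int = 3000, seed: int = 0
    ) -> "RandomizationDesign":
        """The conventional design: sizes 5, 10, ... up to the pool size."""
        return cls(
            pool_size,
            tuple(range(5, pool_size + 1, 5)),
            replicates_per_group,
            seed,
        )

    @property
    def n_communities(self) -> int:
        return sum(
            1 if g == self.pool_size else self.replicates_per_group
            for g in self.group_sizes
        )


@dataclass
class MockCommunity:
    """A defined OTU mixture: members, size, and design label."""

    community_id: str
    member_otu_ids: tuple[str, ...]
    group_size: int
    mbc_type: str = "random"

    def __post_init__(self):
        if len(set(self.member_otu_ids)) != len(self.member_otu_ids):
            raise ValueError(f"{self.community_id}: duplicate members")
        if len(self.member_otu_ids) != self.group_size:
            raise ValueError(
                f"{self.community_id}: {len(self.member_otu_ids)} members "
                f"!= group_size {self.group_size}"
            )

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.member_otu_ids)


@dataclass(frozen=True)
class CompositionCriteria:
    """Required focal-taxon fraction for one nested-MBC type.

    ``focal_fraction=None`` means unconstrained (fully random draws).
    """

    mbc_type: str
    focal_fraction: float | None

    def __post_init__(self):
        if self.focal_fraction is not None and not 0 <= self.focal_fraction <= 1:
            raise ValueError("focal_fraction must lie in [0, 1]")


#: The five classical composition types: I random, II no focal members,
#: III/IV 20% focal with independent draws, V only focal members.
DEFAULT_CRITERIA: tuple[CompositionCriteria, ...] = (
    CompositionCriteria("I", None),
    CompositionCriteria("II", 0.0),
    CompositionCriteria("III", 0.2),
    CompositionCriteria("IV", 0.2),
    CompositionCriteria("V", 1.0),
)


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def assemble_random_mbcs(
    otu_ids: Sequence[str], design: RandomizationDesign
) -> list[MockCommunity]:
    """Draw the full randomized design from a pool of unique OTU ids.

    Each community samples its members uniformly without replacement; the
    same composition may recur across replicates (with 3000 replicates of
    small groups this is combinatorially unavoidable). When a group size
    equals the pool size the group has exactly one community — the whole
    pool — regardless of the replicate count.
    """
    ids = list(otu_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("OTU ids must be unique")
    if design.pool_size != len(ids):
        raise ValueError(
            f"design pool_size {design.pool_size} != {len(ids)} OTUs supplied"
        )
    communities: list[MockCommunity] = []
    arr = np.asarray(ids, dtype=object)
    for gs in design.group_sizes:
        if gs == len(ids):
            communities.append(
                MockCommunity(f"rand_g{gs}_full", tuple(ids), gs)
            )
            continue
        for rep in range(design.replicates_per_group):
            rng = _substream(design.seed, gs, rep)
            members = arr[rng.choice(len(arr), size=gs, replace=False)]
            communities.append(
                MockCommunity(f"rand_g{gs}_r{rep}", tuple(members), gs)
            )
    return communities


def assemble_nested_mbcs(
    taxon_tags: Mapping[str, str],
    criteria: Sequence[CompositionCriteria] = DEFAULT_CRITERIA,
    group_sizes: Sequence[int] = (5, 10, 15, 20, 25, 30),
    seed: int = 0,
    focal_tag: str = "focal",
) -> list[MockCommunity]:
    """Build the stepwise-nested design: one community chain per type.

    Parameters
    ----------
    taxon_tags : mapping otu_id -> tag
        The registered pool; members whose tag equals *focal_tag* count
        toward the focal fraction.
    criteria : sequence of CompositionCriteria
    group_sizes : increasing sizes; each must extend the previous one.
    seed : master seed; each (type, size step) uses its own sub-stream.

    When a criterion cannot be met at some step (e.g. a no-focal type that
    outgrows the non-focal pool), the shortfall is topped up from the
    other stratum and logged — mirroring how a real collection with only
    27 non-focal isolates must admit 3 focal members into its 30-OTU
    no-focal community.
    """
    sizes = list(group_sizes)
    if sizes != sorted(sizes) or len(set(sizes)) != len(sizes):
        raise ValueError("group_sizes must be strictly increasing")
    if sizes and sizes[0] > len(taxon_tags):
        raise ValueError("pool smaller than the smallest group size")
    if sizes and sizes[-1] > len(taxon_tags):
        raise ValueError("pool smaller than the largest group size")

    focal_pool = sorted(o for o, t in taxon_tags.items() if t == focal_tag)
    other_pool = sorted(o for o, t in taxon_tags.items() if t != focal_tag)

    communities: list[MockCommunity] = []
    for ti, crit in enumerate(criteria):
        members: list[str] = []
        for gs in sizes:
            k = gs - len(members)
            if k <= 0:
                raise ValueError("group_sizes must each extend the previous size")
            rng = _substream(seed, ti, gs)
            avail_focal = [o for o in focal_pool if o not in members]
            avail_other = [o for o in other_pool if o not in members]
            if crit.focal_fraction is None:
                avail = sorted(avail_focal + avail_other)
                picks = [avail[i] for i in rng.choice(len(avail), k, replace=False)]
            else:
                n_focal = round(crit.focal_fraction * k)
                n_other = k - n_focal
                short_other = max(0, n_other - len(avail_other))
                short_focal = max(0, n_focal - len(avail_focal))
                n_focal += short_other - short_focal
                n_other += short_focal - short_other
                if short_other or short_focal:
                    logger.warning(
                        "type %s, size %d: criterion infeasible, topped up with "
                        "%d focal / %d non-focal members",
                        crit.mbc_type, gs, short_other, short_focal,
                    )
                if n_focal > len(avail_focal) or n_other > len(avail_other):
                    raise ValueError(
                        f"type {crit.mbc_type}: pool exhausted at size {gs}"
                    )
                picks = [
                    avail_focal[i]
                    for i in rng.choice(len(avail_focal), n_focal, replace=False)
                ] + [
                    avail_other[i]
                    for i in rng.choice(len(avail_other), n_other, replace=False)
                ]
            members = members + picks
            communities.append(
                MockCommunity(
                    f"nested_{crit.mbc_type}_g{gs}",
                    tuple(members),
                    gs,
                    mbc_type=crit.mbc_type,
                )
            )
    return communities


def theoretical_count(
    community: MockCommunity,
    profiles: Mapping[str, FragmentProfile],
    gel: GelModel,
) -> BandSet:
    """Pre-assembly (theoretical) band set of a community.

    Pools every member's individual fragment multiset and merges at gel
    resolution; the resulting ``n_bands`` is the maximum the community
    could display, since no member is lost to amplification competition.
    """
    fragments: list[int] = []
    sources: list[str] = []
    for otu_id in community.member_otu_ids:
        try:
            prof = profiles[otu_id]
        except KeyError:
            raise MissingProfileError(otu_id) from None
        fragments.extend(prof.fragments)
        sources.extend([otu_id] * len(prof.fragments))
    return merge_bands(fragments, gel, sources=sources)


def summarize_groups(
    communities: Sequence[MockCommunity],
    counts: Mapping[str, int],
) -> pd.DataFrame:
    """Per-group-size summary of band counts.

    Returns a DataFrame with columns ``group_size``, ``n_communities``,
    ``mean_bands``, ``sd_bands`` (sample SD, 0.0 for singleton groups),
    sorted by group size.
    """
    rows = [
        {"group_size": c.group_size, "n_bands": counts[c.community_id]}
        for c in communities
    ]
    df = pd.DataFrame(rows)
    out = (
        df.groupby("group_size")["n_bands"]
        .agg(n_communities="size", mean_bands="mean", sd_bands="std")
        .reset_index()
        .sort_values("group_size", ignore_index=True)
    )
    out["sd_bands"] = out["sd_bands"].fillna(0.0)
    return out
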