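"""In silico restriction digestion and gel-resolution band merging.

Two physical steps are emulated here. First, complete digestion of an
amplicon by a restriction enzyme (the pipeline's default is AluI, a 4-bp
cutter recognizing AGCT and cutting between G and C). Second, the
finite resolving power of the 5-11% polyacrylamide gradient gel used to
read the profiles: fragments closer together than the gel resolution
(default 5 bp) co-migrate and are counted as a single band, and fragments
outside the efficient sizing window (default 50-500 bp) are not counted
at all when the window is enabled.

Band merging is anchor-based greedy clustering on the ascending-sorted
lengths: a band is opened at the smallest unassigned length (the anchor)
and absorbs every following length whose difference from the anchor is
below the resolution (merge_rule ``"strict"``) or at most the resolution
(``"inclusive"``). This rule is deterministic and order-invariant, and the
anchor is the reported band size.
"""

from __future__ import annotations

from collections.abc import Hashable, Iterable, Sequence
from dataclasses import dataclass, field

from . import iupac
from .primers import AmpliconRegion, OtuRecord, PrimerDef, extract_amplicon

__all__ = [
    "RestrictionEnzyme",
    "FragmentProfile",
    "GelModel",
    "BandSet",
    "ALUI",
    "digest",
    "profile_otu",
    "merge_bands",
]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Recognition site plus top-strand cut offset (bases from the site's
    5' end)."""

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self):
        object.__setattr__(
            self,
            "recognition_site",
            iupac.validate_iupac(self.recognition_site, f"enzyme {self.name}"),
        )
        if not 0 <= self.cut_offset <= len(self.recognition_site):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside site of length "
                f"{len(self.recognition_site)}"
            )


#: AluI, AG/CT: the single frequent cutter used by the fingerprinting method.
ALUI = RestrictionEnzyme("AluI", "AGCT", 2)


@dataclass
class FragmentProfile:
    """Per-OTU digestion profile: fragment lengths pooled over operon copies.

    ``per_copy`` optionally retains the per-copy split (copy i's lengths
    sum to copy i's amplicon length); ``fragments`` is always the pooled
    multiset.
    """

    otu_id: str
    fragments: list[int]
    per_copy: list[list[int]] | None = None

    def __post_init__(self):
        if any(f < 1 for f in self.fragments):
            raise ValueError("fragment lengths must be >= 1")
        if self.per_copy is not None:
            pooled = sorted(f for c in self.per_copy for f in c)
            if pooled != sorted(self.fragments):
                raise ValueError("per_copy does not pool to fragments")

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


@dataclass(frozen=True)
class GelModel:
    """Resolution and detection window of the gel read-out.

    Parameters
    ----------
    resolution_bp : int
        Minimum size difference (bp) at which two fragments are counted
        separately.
    window_min_bp, window_max_bp : int or None
        Efficient sizing range; fragments outside it are dropped.
        ``None`` disables that bound (theoretical in silico counting
        conventionally disables both).
    merge_rule : {"strict", "inclusive"}
        ``"strict"``: differences >= resolution are distinguishable (two
        bands); ``"inclusive"``: differences <= resolution co-migrate.
    """

    resolution_bp: int = 5
    window_min_bp: int | None = 50
    window_max_bp: int | None = 500
    merge_rule: str = "strict"

    def __post_init__(self):
        if self.resolution_bp < 1:
            raise ValueError("resolution_bp must be >= 1")
        if (
            self.window_min_bp is not None
            and self.window_max_bp is not None
            and not self.window_min_bp < self.window_max_bp
        ):
            raise ValueError("window_min_bp must be < window_max_bp")
        if self.merge_rule not in ("strict", "inclusive"):
            raise ValueError(f"unknown merge_rule {self.merge_rule!r}")

    def windowless(self) -> "GelModel":
        """Copy of this model with the detection window disabled."""
        return GelModel(self.resolution_bp, None, None, self.merge_rule)

    def in_window(self, length: int) -> bool:
        if self.window_min_bp is not None and length < self.window_min_bp:
            return False
        if self.window_max_bp is not None and length > self.window_max_bp:
            return False
        return True

    def same_band(self, anchor: int, length: int) -> bool:
        """Does *length* co-migrate with a band anchored at *anchor*?"""
        diff = abs(length - anchor)
        if self.merge_rule == "strict":
            return diff < self.resolution_bp
        return diff <= self.resolution_bp


@dataclass
class BandSet:
    """Merged, detection-windowed bands of one lane.

    ``bands`` holds the anchor (smallest member) of each cluster, sorted
    ascending. ``provenance`` gives, per band, the sources (e.g. otu_ids)
    of every contributing fragment, with multiplicity, when sources were
    supplied to :func:`merge_bands`.
    """

    bands: list[int]
    provenance: list[tuple[Hashable, ...]] = field(default_factory=list)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def contributing(self, i: int) -> frozenset:
        """Distinct sources of band *i*."""
        return frozenset(self.provenance[i]) if self.provenance else frozenset()


def digest(region: AmpliconRegion | str, enzyme: RestrictionEnzyme = ALUI) -> list[int]:
    """Completely digest a region and return ordered fragment lengths.

    Cut positions are ``site_start + cut_offset`` for every occurrence of
    the recognition site, overlapping occurrences included. The returned
    lengths include the two terminal pieces and always sum to the region
    length; a region with no site yields one full-length fragment.
    """
    seq = region.sequence if isinstance(region, AmpliconRegion) else region
    seq = iupac.validate_iupac(seq)
    if not seq:
        raise ValueError("cannot digest an empty sequence")
    site = enzyme.recognition_site
    k = len(site)
    # A site position matches when every template base is concrete and lies
    # within the site symbol's base set; ambiguous template bases are never
    # cut (the enzyme only cuts real DNA). For an all-ACGT site such as
    # AluI's AGCT this reduces to exact substring matching.
    site_masks = [iupac.IUPAC_MASK[c] for c in site]
    seq_masks = [iupac.IUPAC_MASK[c] for c in seq]
    concrete = [m in (1, 2, 4, 8) for m in seq_masks]
    cuts = sorted(
        {
            i + enzyme.cut_offset
            for i in range(len(seq) - k + 1)
            if all(
                concrete[i + j] and (seq_masks[i + j] & site_masks[j])
                for j in range(k)
            )
        }
    )
    # cuts at the exact termini produce no fragment
    cuts = [c for c in cuts if 0 < c < len(seq)]
    edges = [0, *cuts, len(seq)]
    return [b - a for a, b in zip(edges, edges[1:])]


def profile_otu(
    record: OtuRecord,
    fwd: PrimerDef,
    rev: PrimerDef | None = None,
    enzyme: RestrictionEnzyme = ALUI,
    mode: str = "to_end",
    max_mismatch: int = 0,
) -> FragmentProfile:
    """Extract and digest every operon copy of an OTU, pooling the
    fragment multisets into one profile."""
    per_copy: list[list[int]] = []
    for region in extract_amplicon(record, fwd, rev, mode=mode, max_mismatch=max_mismatch):
        per_copy.append(digest(region, enzyme))
    return FragmentProfile(
        record.otu_id, [f for c in per_copy for f in c], per_copy=per_copy
    )


def merge_bands(
    fragments: Iterable[int],
    gel: GelModel,
    sources: Sequence[Hashable] | None = None,
) -> BandSet:
    """Merge a fragment multiset into gel-distinguishable bands.

    Fragments outside the detection window are dropped first. Survivors
    are sorted ascending and clustered greedily: each band's anchor is its
    smallest member and a new band opens at the first length that no
    longer co-migrates with the current anchor (see :class:`GelModel`).
    The result is invariant under permutation of the input.

    Parameters
    ----------
    fragments : iterable of int
    gel : GelModel
    sources : sequence, optional
        Per-fragment labels (e.g. otu_ids), aligned with *fragments*;
        carried into the band provenance.
    """
    frags = list(fragments)
    if sources is not None:
        if len(sources) != len(frags):
            raise ValueError("sources must align with fragments")
        tagged = [(f, s) for f, s in zip(frags, sources) if gel.in_window(f)]
    else:
        tagged = [(f, None) for f in frags if gel.in_window(f)]
    tagged.sort(key=lambda t: t[0])

    bands: list[int] = []
    prov: list[tuple[Hashable, ...]] = []
    current: list[Hashable] = []
    for length, src in tagged:
        if bands and gel.same_band(bands[-1], length):
            current.append(src)
        else:
            if bands:
                prov.append(tuple(current))
            bands.append(length)
            current = [src]
    if bands:
        prov.append(tuple(current))
    if sources is None:
        prov = [()] * len(bands)
    return BandSet(bands=bands, provenance=prov)
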