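"""Synthetic 16S rDNA pool generator with known ground truth.

The real study inputs — database 16S entries and culturable-isolate
amplicons — are not shipped with the package. This module generates OTU
pools with the same statistical structure, so every downstream stage can
be exercised and verified against a planted ground truth:

* each OTU sequence is a 5' flank, an exact (randomly expanded) 799F
  primer footprint, and a ~700 bp amplicon body whose AluI sites are
  planted to yield a drawn number of fragments (default 3-5 per
  amplicon, matching what a V5-V9 region typically shows);
* a configurable minority of OTUs carries extra operon copies so the
  pooled profile reaches 6-11 detectable fragments (intragenomic 16S
  heterogeneity, the explanation for unexpectedly rich single-isolate
  profiles);
* fragment lengths within an OTU are pairwise separated by at least the
  gel resolution, and accidental AGCT sites or extra primer matches are
  removed by local resampling, so digesting the emitted sequences
  reproduces the ground truth exactly;
* a U1492R footprint is planted at the amplicon 3' end, so extraction
  modes ``to_end`` and ``to_reverse_primer`` agree on these records.

An optional strict mode (``distinct_across_otus``) allocates fragment
lengths from a pool-wide grid so *no* two OTUs share a band; it is meant
for small fixture pools where exact band arithmetic is asserted.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd

from . import iupac
from .digestion import GelModel, merge_bands
from .primers import PRIMER_799F, PRIMER_U1492R, OtuRecord, match_primer

__all__ = [
    "PoolSpec",
    "OtuGroundTruth",
    "GroundTruth",
    "SyntheticPool",
    "generate_pool",
    "plant_collisions",
    "generate_competitor",
]

_BASES = np.array(list("ACGT"))
_FWD_FOOTPRINT_LEN = len(PRIMER_799F)
_REV_FOOTPRINT = iupac.reverse_complement(PRIMER_U1492R.sequence)


@dataclass(frozen=True)
class PoolSpec:
    """Parameters of a synthetic OTU pool.

    Defaults mimic the cacao-endophyte collection: 72 OTUs of which 45
    carry the focal taxon tag, ~700 bp amplicons with 3-5 AluI fragments,
    and 20% multi-operon OTUs with 6-11 total detectable fragments.
    """

    n_otus: int = 72
    amplicon_length_bp: int = 700
    fragments_per_amplicon: tuple[int, int] = (3, 5)
    multi_operon_fraction: float = 0.2
    multi_operon_total: tuple[int, int] = (6, 11)
    focal_fraction: float = 45 / 72
    gc_content: float = 0.5
    flank_length_bp: int = 100
    min_fragment_bp: int = 50
    max_fragment_bp: int = 500
    resolution_bp: int = 5
    distinct_across_otus: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_otus < 1:
            raise ValueError("n_otus must be >= 1")
        lo, hi = self.fragments_per_amplicon
        if not 1 <= lo <= hi:
            raise ValueError("bad fragments_per_amplicon range")
        if not 0 <= self.multi_operon_fraction <= 1:
            raise ValueError("multi_operon_fraction must lie in [0, 1]")
        if not 0 <= self.focal_fraction <= 1:
            raise ValueError("focal_fraction must lie in [0, 1]")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.min_fragment_bp < _FWD_FOOTPRINT_LEN + 2:
            raise ValueError(
                f"min_fragment_bp must be >= {_FWD_FOOTPRINT_LEN + 2} to hold "
                "the primer footprints"
            )
        # sanity: hi fragments of >= min each must fit the amplicon
        if hi * self.min_fragment_bp > self.amplicon_length_bp and not self.distinct_across_otus:
            raise ValueError(
                f"{hi} fragments of >= {self.min_fragment_bp} bp do not fit "
                f"in {self.amplicon_length_bp} bp"
            )


@dataclass
class OtuGroundTruth:
    """Planted digestion truth for one OTU."""

    otu_id: str
    taxon_tag: str
    amplicon_start: int
    fragment_lengths_per_copy: list[list[int]]
    expected_band_count: int  # merged at the spec resolution, no window

    @property
    def all_fragments(self) -> list[int]:
        return [f for copy in self.fragment_lengths_per_copy for f in copy]


GroundTruth = dict[str, OtuGroundTruth]


@dataclass
class SyntheticPool:
    """A generated pool: records, tabular manifest, and ground truth."""

    spec: PoolSpec
    records: list[OtuRecord]
    manifest: pd.DataFrame
    ground_truth: GroundTruth

    @property
    def taxon_tags(self) -> dict[str, str]:
        return {r.otu_id: r.taxon_tag for r in self.records}


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _expand_degenerate(rng: np.random.Generator, primer_seq: str) -> str:
    """One concrete random expansion of a degenerate primer."""
    out = []
    for ch in primer_seq:
        mask = iupac.IUPAC_MASK[ch]
        choices = [b for b, m in zip("ACGT", (1, 2, 4, 8)) if mask & m]
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _find_agct(seq: np.ndarray) -> list[int]:
    s = "".join(seq)
    hits, start = [], 0
    while True:
        i = s.find("AGCT", start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def _scrub(
    rng: np.random.Generator,
    seq: np.ndarray,
    protected: list[tuple[int, int]],
    allowed_sites: set[int],
    gc: float,
    max_rounds: int = 200,
) -> np.ndarray:
    """Remove accidental AGCT sites and stray primer matches by local
    resampling, leaving protected intervals untouched."""

    def is_protected(pos: int) -> bool:
        return any(a <= pos < b for a, b in protected)

    for _ in range(max_rounds):
        dirty = False
        # accidental restriction sites
        for i in _find_agct(seq):
            if i in allowed_sites:
                continue
            free = [p for p in range(i, i + 4) if not is_protected(p)]
            if not free:
                raise RuntimeError("accidental site fully inside protected region")
            p = free[rng.integers(len(free))]
            seq[p] = _random_bases(rng, 1, gc)[0]
            dirty = True
        # stray primer matches (planted footprints live in protected spans)
        s = "".join(seq)
        for primer in (PRIMER_799F, PRIMER_U1492R):
            for pos, _strand in match_primer(s, primer, 0):
                span = range(pos, pos + len(primer))
                if all(is_protected(p) for p in span):
                    continue  # the planted footprint itself
                free = [p for p in span if not is_protected(p)]
                p = free[rng.integers(len(free))]
                seq[p] = _random_bases(rng, 1, gc)[0]
                dirty = True
        if not dirty:
            return seq
    raise RuntimeError("scrubbing did not converge; sequence too constrained")


def _compose_lengths(
    rng: np.random.Generator,
    k: int,
    target_len: int,
    spec: PoolSpec,
    taken: list[int],
    max_tries: int = 5000,
) -> list[int]:
    """Draw k fragment lengths summing to ~target_len, each within the
    configured bounds and >= resolution away from everything in *taken*."""
    res = spec.resolution_bp
    for attempt in range(max_tries):
        L = target_len if attempt < max_tries // 2 else int(
            rng.normal(target_len, 20)
        )
        L = max(L, k * spec.min_fragment_bp + k)
        if k == 1:
            lengths = [L]
        else:
            cuts = np.sort(rng.choice(np.arange(1, L), size=k - 1, replace=False))
            edges = np.concatenate(([0], cuts, [L]))
            lengths = list(np.diff(edges).astype(int))
        if any(
            not spec.min_fragment_bp <= f <= spec.max_fragment_bp for f in lengths
        ):
            continue
        pool = list(taken)
        ok = True
        for f in lengths:
            if any(abs(f - t) < res for t in pool):
                ok = False
                break
            pool.append(f)
        if ok:
            return lengths
    raise ValueError(
        f"could not place {k} fragments of {spec.min_fragment_bp}-"
        f"{spec.max_fragment_bp} bp, pairwise >= {res} bp apart, in "
        f"{target_len} bp — specification infeasible"
    )


def _pick_slots(
    rng: np.random.Generator, k: int, available: list[int]
) -> list[int]:
    if k > len(available):
        raise ValueError(
            "pool-wide distinct fragment lengths exhausted — specification "
            "infeasible at this pool size"
        )
    idx = rng.choice(len(available), size=k, replace=False)
    picks = [available[i] for i in sorted(idx, reverse=True)]
    for i in sorted(idx, reverse=True):
        del available[i]
    return picks


def _build_copy(
    rng: np.random.Generator,
    lengths: Sequence[int],
    spec: PoolSpec,
) -> str:
    """Assemble one operon copy: flank + 799F footprint + planted-cut body
    + U1492R footprint, scrubbed of accidental motifs."""
    flank = _random_bases(rng, spec.flank_length_bp, spec.gc_content)
    fwd = np.array(list(_expand_degenerate(rng, PRIMER_799F.sequence)))
    amp_parts: list[np.ndarray] = []
    for ci, f in enumerate(lengths):
        body = _random_bases(rng, f, spec.gc_content)
        if ci == 0:
            body[: len(fwd)] = fwd
        if ci == len(lengths) - 1:
            body[-len(_REV_FOOTPRINT):] = np.array(list(_REV_FOOTPRINT))
        if ci > 0:  # fragment opens with CT (second half of AG|CT)
            body[0], body[1] = "C", "T"
        if ci < len(lengths) - 1:  # fragment closes with AG
            body[-2], body[-1] = "A", "G"
        amp_parts.append(body)
    seq = np.concatenate([flank, *amp_parts])

    amp_start = spec.flank_length_bp
    amp_len = int(sum(lengths))
    cut_sites = []  # AGCT site starts: 2 bases before each internal boundary
    pos = amp_start
    for f in lengths[:-1]:
        pos += f
        cut_sites.append(pos - 2)
    protected = [
        (amp_start, amp_start + _FWD_FOOTPRINT_LEN),
        (amp_start + amp_len - len(_REV_FOOTPRINT), amp_start + amp_len),
    ] + [(c, c + 4) for c in cut_sites]
    seq = _scrub(rng, seq, protected, set(cut_sites), spec.gc_content)
    return "".join(seq)


def _copy_partition(rng: np.random.Generator, total: int) -> list[int]:
    """Split a multi-operon fragment total into per-copy counts of 3-5."""
    ks: list[int] = []
    rem = total
    while rem > 0:
        if rem <= 5:
            ks.append(rem)
            break
        k = int(rng.integers(3, 6))
        if rem - k in (1, 2):
            k = rem - 3
        ks.append(k)
        rem -= k
    return ks


def generate_pool(spec: PoolSpec) -> SyntheticPool:
    """Generate a seeded OTU pool with planted digestion ground truth.

    Returns a :class:`SyntheticPool`; re-running with the same spec is
    byte-identical. The manifest has one row per operon copy with columns
    ``otu_id``, ``copy_index``, ``taxon_tag``, ``n_fragments``,
    ``sequence_length``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    lo, hi = spec.fragments_per_amplicon
    n_focal = round(spec.focal_fraction * spec.n_otus)
    n_multi = round(spec.multi_operon_fraction * spec.n_otus)
    multi_ids = set(rng.choice(spec.n_otus, size=n_multi, replace=False).tolist())

    slots: list[int] | None = None
    if spec.distinct_across_otus:
        slots = list(
            range(spec.min_fragment_bp, spec.max_fragment_bp + 1, 2 * spec.resolution_bp)
        )

    records: list[OtuRecord] = []
    truth: GroundTruth = {}
    rows = []
    width = len(str(spec.n_otus))
    for i in range(spec.n_otus):
        otu_id = f"OTU{i + 1:0{width}d}"
        tag = "focal" if i < n_focal else "other"
        if i in multi_ids:
            total = int(rng.integers(spec.multi_operon_total[0],
                                     spec.multi_operon_total[1] + 1))
            per_copy_k = _copy_partition(rng, total)
        else:
            per_copy_k = [int(rng.integers(lo, hi + 1))]

        taken: list[int] = []
        copies: list[str] = []
        per_copy_lengths: list[list[int]] = []
        for k in per_copy_k:
            if slots is not None:
                lengths = _pick_slots(rng, k, slots)
            else:
                lengths = _compose_lengths(rng, k, spec.amplicon_length_bp, spec, taken)
            taken.extend(lengths)
            copies.append(_build_copy(rng, lengths, spec))
            per_copy_lengths.append(list(lengths))

        rec = OtuRecord(otu_id, copies, taxon_tag=tag)
        records.append(rec)
        gel = GelModel(spec.resolution_bp, None, None, "strict")
        expected = merge_bands(
            [f for c in per_copy_lengths for f in c], gel
        ).n_bands
        truth[otu_id] = OtuGroundTruth(
            otu_id, tag, spec.flank_length_bp, per_copy_lengths, expected
        )
        for ci, (s, ls) in enumerate(zip(copies, per_copy_lengths)):
            rows.append(
                {
                    "otu_id": otu_id,
                    "copy_index": ci,
                    "taxon_tag": tag,
                    "n_fragments": len(ls),
                    "sequence_length": len(s),
                }
            )
    return SyntheticPool(spec, records, pd.DataFrame(rows), truth)


def plant_collisions(pool: SyntheticPool, n_pairs: int, seed: int = 0) -> SyntheticPool:
    """Introduce exactly *n_pairs* cross-OTU band collisions.

    Picks disjoint OTU pairs; in each pair, one fragment of the second OTU
    is re-planted at a length within the gel resolution of a fragment of
    the first, so merging the pair loses exactly one band relative to the
    sum of the individual counts. The affected sequences are rebuilt and
    the ground truth updated. Intended for pools generated with
    ``distinct_across_otus=True``, where no accidental collision exists.
    """
    if 2 * n_pairs > len(pool.records):
        raise ValueError("not enough OTUs for the requested collision pairs")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    spec = pool.spec
    res = spec.resolution_bp
    order = rng.permutation(len(pool.records))
    records = list(pool.records)
    truth = dict(pool.ground_truth)
    manifest = pool.manifest.copy()

    all_lengths = [f for gt in truth.values() for f in gt.all_fragments]
    for p in range(n_pairs):
        a = records[order[2 * p]]
        b = records[order[2 * p + 1]]
        gt_a, gt_b = truth[a.otu_id], truth[b.otu_id]
        target = gt_a.all_fragments[rng.integers(len(gt_a.all_fragments))]
        # replace one fragment of b with target+delta, colliding only with target
        new_per_copy = [list(c) for c in gt_b.fragment_lengths_per_copy]
        ci = int(rng.integers(len(new_per_copy)))
        fi = int(rng.integers(len(new_per_copy[ci])))
        old = new_per_copy[ci][fi]
        # every fragment except the collision target and the one replaced
        rest = list(all_lengths)
        rest.remove(target)
        rest.remove(old)
        placed = None
        for delta in range(1, res):
            cand = target + delta
            if spec.min_fragment_bp <= cand <= spec.max_fragment_bp and all(
                abs(cand - f) >= res for f in rest
            ):
                placed = cand
                break
        if placed is None:
            raise ValueError("could not place a clean collision; pool too dense")
        all_lengths.remove(old)
        all_lengths.append(placed)
        new_per_copy[ci][fi] = placed
        new_copies = list(b.sequences)
        crng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2, p)))
        new_copies[ci] = _build_copy(crng, new_per_copy[ci], spec)
        idx = records.index(b)
        records[idx] = OtuRecord(b.otu_id, new_copies, taxon_tag=b.taxon_tag)
        gel = GelModel(res, None, None, "strict")
        truth[b.otu_id] = OtuGroundTruth(
            b.otu_id,
            b.taxon_tag,
            spec.flank_length_bp,
            new_per_copy,
            merge_bands([f for c in new_per_copy for f in c], gel).n_bands,
        )
        sel = (manifest["otu_id"] == b.otu_id) & (manifest["copy_index"] == ci)
        manifest.loc[sel, "sequence_length"] = len(new_copies[ci])
    return SyntheticPool(spec, records, manifest, truth)


def generate_competitor(length_bp: int = 1100, seed: int = 0, gc: float = 0.4) -> OtuRecord:
    """A chloroplast-like competitor amplicon: a single ~1,100 bp record
    carrying an exact 799F-matchable site at its start, tagged
    ``"competitor"``. It digests through the standard pipeline but its
    dominant fragments fall outside the efficient gel window."""
    if length_bp <= _FWD_FOOTPRINT_LEN:
        raise ValueError("competitor must be longer than the primer footprint")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    seq = _random_bases(rng, length_bp, gc)
    seq[:_FWD_FOOTPRINT_LEN] = np.array(
        list(_expand_degenerate(rng, PRIMER_799F.sequence))
    )
    # keep the planted site 5'-most: scrub any stray match until clean
    for _ in range(50):
        s = "".join(seq)
        stray = [p for p, _ in match_primer(s, PRIMER_799F, 0) if p != 0]
        if not stray:
            break
        for pos in stray:
            seq[max(pos, _FWD_FOOTPRINT_LEN)] = _random_bases(rng, 1, gc)[0]
    return OtuRecord("competitor", ["".join(seq)], taxon_tag="competitor")
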