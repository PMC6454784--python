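"""Degenerate-primer matching and amplicon extraction.

Models the in silico PCR step of the pipeline: locate annealing sites of
IUPAC-degenerate 16S rDNA primers on template sequences and extract the
region that the downstream restriction digestion operates on. The standard
bacterial primer pairs are provided as module constants; 799F/U1492R
delimit the ~700 bp V5-V9 region that the fingerprinting method digests.

Coordinates are 0-based half-open throughout the library; report writers
convert to 1-based inclusive for human consumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import iupac

logger = logging.getLogger(__name__)

__all__ = [
    "PrimerDef",
    "OtuRecord",
    "AmpliconRegion",
    "match_primer",
    "extract_amplicon",
    "PRIMER_27F",
    "PRIMER_1492R",
    "PRIMER_799F",
    "PRIMER_U1492R",
]


@dataclass(frozen=True)
class PrimerDef:
    """A PCR primer: short label, 5'->3' IUPAC sequence, orientation.

    Orientation is ``"forward"`` (anneals to the minus strand, written as it
    appears on the plus strand) or ``"reverse"`` (anneals to the plus
    strand; its reverse complement appears on the plus strand).
    """

    name: str
    sequence: str
    orientation: str

    def __post_init__(self):
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(
                f"orientation must be 'forward' or 'reverse', got {self.orientation!r}"
            )
        if not self.sequence:
            raise ValueError("primer sequence must be non-empty")
        object.__setattr__(
            self, "sequence", iupac.validate_iupac(self.sequence, f"primer {self.name}")
        )

    def __len__(self) -> int:
        return len(self.sequence)


#: Universal bacterial 16S rDNA primers used by the fingerprinting protocol.
PRIMER_27F = PrimerDef("27F", "AGAGTTTGATCCTGGCTCAG", "forward")
PRIMER_1492R = PrimerDef("1492R", "TACGGYTACCTTGTTACGACTT", "reverse")
#: 799F mismatches chloroplast 16S in many plants; pairs with U1492R for the
#: V5-V9 region (~700 bp bacterial amplicon vs ~1,100 bp chloroplast).
PRIMER_799F = PrimerDef("799F", "AACMGGATTAGATACCCKG", "forward")
PRIMER_U1492R = PrimerDef("U1492R", "GGTTACCTTGTTACGACTT", "reverse")


@dataclass
class OtuRecord:
    """One operational taxonomic unit: id, one or more 16S operon copies,
    and a free-form taxon tag used by community composition criteria."""

    otu_id: str
    sequences: list[str]
    taxon_tag: str = ""

    def __post_init__(self):
        if not self.sequences:
            raise ValueError(f"OTU {self.otu_id!r} must have at least one sequence")
        self.sequences = [
            iupac.validate_iupac(s, f"OTU {self.otu_id}") for s in self.sequences
        ]

    @property
    def n_copies(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class AmpliconRegion:
    """An extracted amplicon: half-open [start, end) on one operon copy."""

    otu_id: str
    copy_index: int
    start: int
    end: int
    sequence: str = field(repr=False)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad amplicon coordinates [{self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("amplicon sequence length disagrees with coordinates")

    def __len__(self) -> int:
        return self.end - self.start


def match_primer(
    sequence: str, primer: PrimerDef, max_mismatch: int = 0
) -> list[tuple[int, str]]:
    """Locate every annealing site of *primer* on the plus strand.

    Forward primers are scanned as given; reverse primers are scanned as
    their reverse complement (the footprint they leave on the plus strand).
    A primer symbol matches a template symbol iff their IUPAC base sets
    intersect, so degenerate positions in either primer or template (e.g. N
    in a database entry) match permissively.

    Parameters
    ----------
    sequence : str
        Template, plus strand, IUPAC alphabet.
    primer : PrimerDef
    max_mismatch : int
        Maximum number of incompatible positions tolerated; must be smaller
        than the primer length.

    Returns
    -------
    list of (start, strand)
        0-based start of the footprint on the plus strand, sorted
        ascending; strand is ``"+"`` for forward primers, ``"-"`` for
        reverse primers.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if not 0 <= max_mismatch < len(primer):
        raise ValueError(
            f"max_mismatch must be in [0, {len(primer) - 1}], got {max_mismatch}"
        )
    if primer.orientation == "forward":
        pattern, strand = primer.sequence, "+"
    else:
        pattern, strand = iupac.reverse_complement(primer.sequence), "-"

    tmpl = iupac.encode(sequence)
    pat = [iupac.IUPAC_MASK[c] for c in pattern]
    k = len(pat)
    hits: list[tuple[int, str]] = []
    for start in range(len(tmpl) - k + 1):
        mismatches = 0
        for j in range(k):
            if not (tmpl[start + j] & pat[j]):
                mismatches += 1
                if mismatches > max_mismatch:
                    break
        else:
            hits.append((start, strand))
    return hits


def extract_amplicon(
    record: OtuRecord,
    fwd: PrimerDef,
    rev: PrimerDef | None = None,
    mode: str = "to_end",
    max_mismatch: int = 0,
) -> list[AmpliconRegion]:
    """Extract the amplified region from each operon copy of an OTU.

    The region starts at the 5'-most forward-primer footprint (primer
    included: physical amplicons carry primer sequence, and gel fragment
    sizes include it). In mode ``"to_reverse_primer"`` it ends at the 3'
    end of the nearest downstream reverse-primer footprint; in mode
    ``"to_end"`` (default) it runs to the sequence terminus, which mirrors
    digesting database entries from the forward site onward.

    Copies with no forward-primer site yield no region; an OTU with no
    usable copy at all returns an empty list and logs a warning naming the
    OTU (it is invisible to this primer set).
    """
    if fwd.orientation != "forward":
        raise ValueError(f"{fwd.name} is not a forward primer")
    if mode not in ("to_end", "to_reverse_primer"):
        raise ValueError(f"unknown extraction mode {mode!r}")
    if mode == "to_reverse_primer":
        if rev is None:
            raise ValueError("mode 'to_reverse_primer' requires a reverse primer")
        if rev.orientation != "reverse":
            raise ValueError(f"{rev.name} is not a reverse primer")

    regions: list[AmpliconRegion] = []
    for copy_index, seq in enumerate(record.sequences):
        fwd_hits = match_primer(seq, fwd, max_mismatch)
        if not fwd_hits:
            continue
        start = fwd_hits[0][0]  # 5'-most site
        if mode == "to_end":
            end = len(seq)
        else:
            rev_hits = [
                pos for pos, _ in match_primer(seq, rev, max_mismatch)
                if pos >= start
            ]
            if not rev_hits:
                continue
            end = rev_hits[0] + len(rev)  # nearest downstream footprint
        regions.append(
            AmpliconRegion(record.otu_id, copy_index, start, end, seq[start:end])
        )
    if not regions:
        logger.warning(
            "OTU %s: no %s site on any copy; OTU is invisible to this primer set",
            record.otu_id,
            fwd.name,
        )
    return regions
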