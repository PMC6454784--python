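"""Reading and writing the pipeline's plain-text formats.

FASTA in/out goes through Biopython. Operon copies of one OTU are
encoded as records sharing the OTU id with a ``|copyN`` suffix
(``OTU007|copy1`` is the second copy of OTU007); alternatively a
manifest TSV (columns ``record_id``, ``otu_id``, ``taxon_tag``) maps
arbitrary record ids onto OTUs. Taxon tags ride in the FASTA description
as ``taxon=...`` when no manifest is used.

Tables are tab-separated with a header row. Coordinates in tables are
1-based inclusive (human-readable convention); everything in memory is
0-based half-open.
"""

from __future__ import annotations

import re
from pathlib import Path
from collections.abc import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .communities import MockCommunity
from .digestion import BandSet, FragmentProfile
from .primers import AmpliconRegion, OtuRecord

__all__ = [
    "read_pool_fasta",
    "write_pool_fasta",
    "write_amplicons",
    "write_profiles_tsv",
    "read_profiles_tsv",
    "write_bands_tsv",
    "write_communities_tsv",
]

_COPY_RE = re.compile(r"^(?P<otu>.+)\|copy(?P<n>\d+)$")


def write_pool_fasta(records: Sequence[OtuRecord], path: str | Path) -> None:
    """Write OTU records as multi-FASTA, one entry per operon copy."""
    entries = []
    for rec in records:
        for ci, seq in enumerate(rec.sequences):
            rid = rec.otu_id if rec.n_copies == 1 else f"{rec.otu_id}|copy{ci}"
            entries.append(
                SeqRecord(Seq(seq), id=rid, description=f"taxon={rec.taxon_tag}")
            )
    SeqIO.write(entries, str(path), "fasta")


def read_pool_fasta(
    path: str | Path, manifest: str | Path | None = None
) -> list[OtuRecord]:
    """Read a pool multi-FASTA back into OTU records.

    Without a manifest, record ids are parsed for the ``|copyN`` suffix
    and ``taxon=`` descriptions. With a manifest TSV (``record_id``,
    ``otu_id``, ``taxon_tag``) records are grouped by its mapping instead.
    """
    seqs = list(SeqIO.parse(str(path), "fasta"))
    grouped: dict[str, dict] = {}
    if manifest is not None:
        mf = pd.read_csv(manifest, sep="\t", dtype=str)
        required = {"record_id", "otu_id", "taxon_tag"}
        if not required.issubset(mf.columns):
            raise ValueError(f"manifest must have columns {sorted(required)}")
        mapping = mf.set_index("record_id")[["otu_id", "taxon_tag"]]
        for sr in seqs:
            try:
                otu_id, tag = mapping.loc[sr.id]
            except KeyError:
                raise ValueError(f"record {sr.id!r} missing from manifest") from None
            g = grouped.setdefault(otu_id, {"tag": tag, "seqs": []})
            g["seqs"].append(str(sr.seq))
    else:
        for sr in seqs:
            m = _COPY_RE.match(sr.id)
            otu_id = m.group("otu") if m else sr.id
            tag_m = re.search(r"taxon=(\S+)", sr.description)
            tag = tag_m.group(1) if tag_m else ""
            g = grouped.setdefault(otu_id, {"tag": tag, "seqs": []})
            g["seqs"].append(str(sr.seq))
    return [
        OtuRecord(otu_id, g["seqs"], taxon_tag=g["tag"])
        for otu_id, g in grouped.items()
    ]


def write_amplicons(
    regions: Iterable[AmpliconRegion], fasta_path: str | Path, tsv_path: str | Path
) -> None:
    """Amplicon FASTA plus a coordinate table (1-based inclusive)."""
    regions = list(regions)
    SeqIO.write(
        [
            SeqRecord(
                Seq(r.sequence),
                id=f"{r.otu_id}|copy{r.copy_index}",
                description=f"amplicon {r.start + 1}-{r.end}",
            )
            for r in regions
        ],
        str(fasta_path),
        "fasta",
    )
    pd.DataFrame(
        [
            {
                "otu_id": r.otu_id,
                "copy_index": r.copy_index,
                "start": r.start + 1,
                "end": r.end,
                "length": len(r),
            }
            for r in regions
        ]
    ).to_csv(tsv_path, sep="\t", index=False)


def write_profiles_tsv(
    profiles: Mapping[str, FragmentProfile], path: str | Path
) -> None:
    """One row per fragment: otu_id, copy_index, fragment_length_bp."""
    rows = []
    for otu_id in sorted(profiles):
        prof = profiles[otu_id]
        per_copy = prof.per_copy if prof.per_copy is not None else [prof.fragments]
        for ci, frags in enumerate(per_copy):
            rows.extend(
                {"otu_id": otu_id, "copy_index": ci, "fragment_length_bp": f}
                for f in frags
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path: str | Path) -> dict[str, FragmentProfile]:
    df = pd.read_csv(path, sep="\t")
    profiles = {}
    for otu_id, sub in df.groupby("otu_id", sort=True):
        per_copy = [
            list(g["fragment_length_bp"].astype(int))
            for _, g in sub.groupby("copy_index", sort=True)
        ]
        profiles[str(otu_id)] = FragmentProfile(
            str(otu_id), [f for c in per_copy for f in c], per_copy=per_copy
        )
    return profiles


def write_bands_tsv(bandsets: Mapping[str, BandSet], path: str | Path) -> None:
    """Long-format band table: community_id, band_representative_bp,
    n_members, contributing_otus (semicolon-joined)."""
    rows = []
    for cid in sorted(bandsets):
        bs = bandsets[cid]
        for i, band in enumerate(bs.bands):
            prov = bs.provenance[i] if bs.provenance else ()
            rows.append(
                {
                    "community_id": cid,
                    "band_representative_bp": band,
                    "n_members": len(prov),
                    "contributing_otus": ";".join(sorted(set(map(str, prov)))),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "community_id",
            "band_representative_bp",
            "n_members",
            "contributing_otus",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_communities_tsv(
    communities: Sequence[MockCommunity], path: str | Path
) -> None:
    """Membership manifest: one row per (community, member)."""
    rows = [
        {
            "community_id": c.community_id,
            "mbc_type": c.mbc_type,
            "group_size": c.group_size,
            "otu_id": otu,
        }
        for c in communities
        for otu in c.member_otu_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
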