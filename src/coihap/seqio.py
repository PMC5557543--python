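"""Aligned-FASTA ingestion, validation, trimming and writing.

Everything downstream (haplotype collapsing, distances, neutrality tests)
assumes a single fixed alignment length per run; this module enforces that
contract at the boundary. Coordinates are 0-based half-open internally;
user-facing reports are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes plus the gap character.
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")

#: Unambiguous bases; only these participate in diversity statistics.
ACGT = frozenset("ACGT")

METADATA_KEYS = ("site", "host", "zone", "year", "lat", "lon", "count")


@dataclass
class SequenceRecord:
    """One aligned sequence with its sample metadata.

    ``meta`` carries survey fields (site, host, zone, year, optionally
    lat/lon and an adult-count) as strings; absent metadata is an empty map.
    """

    id: str
    seq: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        self.seq = self.seq.upper()


@dataclass
class Alignment:
    """An ordered, fixed-length nucleotide alignment."""

    records: list[SequenceRecord]

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        if self.records:
            L = len(self.records[0].seq)
            bad = [r.id for r in self.records if len(r.seq) != L]
            if bad:
                raise ValueError(
                    f"unequal sequence lengths (expected {L}): offending ids {bad}"
                )

    @property
    def length(self) -> int:
        return len(self.records[0].seq) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]


def _validate_chars(rec_id: str, seq: str) -> None:
    for pos, ch in enumerate(seq):
        if ch not in IUPAC_CHARS:
            # report 1-based position
            raise ValueError(
                f"sequence {rec_id!r}: invalid character {ch!r} at position {pos + 1}"
            )


def read_metadata(path) -> pd.DataFrame:
    """Read the tab-separated sample metadata table (header row required)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "id" not in df.columns:
        raise ValueError("metadata table must have an 'id' column")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise ValueError(f"duplicate ids in metadata: {dupes}")
    return df.set_index("id")


def read_fasta(path, metadata=None) -> Alignment:
    """Read an aligned FASTA file (wrapped or single-line) into an Alignment.

    If ``metadata`` (a TSV path or DataFrame) is given, each record's meta
    map is filled from the matching row; records absent from the table get
    empty meta and a logged warning.
    """
    meta_df = None
    if metadata is not None:
        meta_df = metadata if isinstance(metadata, pd.DataFrame) else read_metadata(metadata)

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        _validate_chars(rec.id, seq)
        meta = {}
        if meta_df is not None:
            if rec.id in meta_df.index:
                row = meta_df.loc[rec.id]
                meta = {k: str(v) for k, v in row.items() if pd.notna(v)}
            else:
                logger.warning("no metadata for sequence %r", rec.id)
        records.append(SequenceRecord(rec.id, seq, meta))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return Alignment(records)


def trim_alignment(aln: Alignment, start: int, length: int) -> Alignment:
    """Return the half-open window [start, start+length) of the alignment."""
    if start < 0 or length <= 0 or start + length > aln.length:
        raise ValueError(
            f"trim window [{start}, {start + length}) out of range for "
            f"alignment of length {aln.length}"
        )
    return Alignment(
        [SequenceRecord(r.id, r.seq[start : start + length], dict(r.meta)) for r in aln]
    )


def write_fasta(aln: Alignment, path) -> None:
    """Write single-line FASTA; round-trips through read_fasta."""
    if not aln.records:
        raise ValueError("refusing to write an empty alignment")
    with open(path, "w") as fh:
        for r in aln:
            fh.write(f">{r.id}\n{r.seq}\n")


def write_metadata(aln: Alignment, path) -> None:
    """Write the records' metadata back out as TSV in seqio's grammar."""
    keys = [k for k in METADATA_KEYS if any(k in r.meta for r in aln)]
    with open(path, "w") as fh:
        fh.write("\t".join(["id"] + keys) + "\n")
        for r in aln:
            fh.write("\t".join([r.id] + [str(r.meta.get(k, "")) for k in keys]) + "\n")
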