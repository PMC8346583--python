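"""Aligned-FASTA and specimen-metadata I/O, plus multi-locus concatenation.

A dataset is one or more pre-aligned loci (equal-length sequences over the
IUPAC nucleotide alphabet plus ``-``) together with a specimen table mapping
each sequence to a species and a native/non-native/outgroup status.  Loci are
concatenated per specimen into a supermatrix before distance analysis; a
partitions table records where each locus sits in the concatenation.

No multiple sequence alignment is performed here: input must be aligned.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import AlignmentError, FormatError, MetadataError, UsageError

#: IUPAC nucleotide codes, alignment gap and N.  Anything else is rejected.
ALLOWED_CHARS = frozenset("ACGTURYSWKMBDHVN-?")

VALID_STATUSES = ("native", "non-native", "outgroup")

Status = Literal["native", "non-native", "outgroup"]


@dataclass(frozen=True)
class SpecimenRecord:
    """One specimen: a unique voucher-style identifier, its species, and
    whether it is native, non-native, or the outgroup used for rooting."""

    specimen_id: str
    species: str
    status: Status = "native"

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise MetadataError("specimen_id must be non-empty")
        if not self.species:
            raise MetadataError(f"species must be non-empty (specimen {self.specimen_id!r})")
        if self.status not in VALID_STATUSES:
            raise MetadataError(
                f"status {self.status!r} for specimen {self.specimen_id!r} "
                f"not one of {VALID_STATUSES}"
            )


@dataclass
class AlignedLocus:
    """One locus' equal-length labelled sequences.

    Sequences are stored uppercase; records keep file order.  At least two
    records and a positive alignment length are required.
    """

    locus_name: str
    records: list[tuple[SpecimenRecord, str]]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentError(
                f"locus {self.locus_name!r}: need >=2 records, got {len(self.records)}"
            )
        self.records = [(rec, seq.upper()) for rec, seq in self.records]
        length = len(self.records[0][1])
        if length == 0:
            raise AlignmentError(f"locus {self.locus_name!r}: zero-length alignment")
        seen: set[str] = set()
        for rec, seq in self.records:
            if len(seq) != length:
                raise AlignmentError(
                    f"locus {self.locus_name!r}: sequence for {rec.specimen_id!r} "
                    f"has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - ALLOWED_CHARS
            if bad:
                raise AlignmentError(
                    f"locus {self.locus_name!r}: sequence for {rec.specimen_id!r} "
                    f"contains invalid characters {sorted(bad)}"
                )
            if rec.specimen_id in seen:
                raise MetadataError(
                    f"locus {self.locus_name!r}: duplicate specimen {rec.specimen_id!r}"
                )
            seen.add(rec.specimen_id)

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def specimen_ids(self) -> list[str]:
        return [rec.specimen_id for rec, _ in self.records]

    def sequence_of(self, specimen_id: str) -> str:
        for rec, seq in self.records:
            if rec.specimen_id == specimen_id:
                return seq
        raise KeyError(specimen_id)

    def record_of(self, specimen_id: str) -> SpecimenRecord:
        for rec, _ in self.records:
            if rec.specimen_id == specimen_id:
                return rec
        raise KeyError(specimen_id)

    def __len__(self) -> int:
        return len(self.records)


def read_metadata(path: str | Path) -> dict[str, SpecimenRecord]:
    """Read the 3-column specimen table (specimen_id, species, status) TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["specimen_id", "species", "status"]
    if list(df.columns[:3]) != expected:
        raise FormatError(
            f"metadata {path}: expected header {expected}, got {list(df.columns)}"
        )
    if df["specimen_id"].duplicated().any():
        dups = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise MetadataError(f"metadata {path}: duplicate specimen_id(s) {dups}")
    return {
        row.specimen_id: SpecimenRecord(row.specimen_id, row.species, row.status)
        for row in df.itertuples()
    }


def write_metadata(metadata: dict[str, SpecimenRecord] | Iterable[SpecimenRecord],
                   path: str | Path) -> None:
    records = metadata.values() if isinstance(metadata, dict) else metadata
    df = pd.DataFrame(
        [(r.specimen_id, r.species, r.status) for r in records],
        columns=["specimen_id", "species", "status"],
    )
    df.to_csv(path, sep="\t", index=False)


def _header_token(description: str) -> str:
    """First whitespace- or pipe-delimited token of a FASTA header line."""
    return re.split(r"[|\s]+", description.strip())[0]


def read_fasta_alignment(
    path: str | Path,
    metadata: dict[str, SpecimenRecord],
    locus_name: str | None = None,
) -> AlignedLocus:
    """Read an aligned multi-FASTA whose headers start with specimen ids.

    The header's first whitespace/pipe token must match a metadata
    specimen_id (tolerates "voucher accession species" tip-label style).
    """
    path = Path(path)
    seq_records = list(SeqIO.parse(str(path), "fasta"))
    if not seq_records:
        raise FormatError(f"{path}: no FASTA records found")
    records: list[tuple[SpecimenRecord, str]] = []
    for sr in seq_records:
        sid = _header_token(sr.description)
        if sid not in metadata:
            raise MetadataError(f"{path}: specimen {sid!r} not in metadata table")
        records.append((metadata[sid], str(sr.seq)))
    return AlignedLocus(locus_name or path.stem, records)


def write_fasta_alignment(locus: AlignedLocus, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=rec.specimen_id, description="")
        for rec, seq in locus.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def concatenate_loci(
    loci: Sequence[AlignedLocus],
    policy: Literal["strict", "pad"] = "strict",
) -> AlignedLocus:
    """Join per-specimen sequences of several loci into one supermatrix.

    Under ``strict`` every specimen must be present in all loci; under
    ``pad`` a specimen missing from a locus receives a run of N spanning it.
    Record order follows first appearance across loci in the given order.
    """
    if len(loci) < 2:
        raise UsageError(f"concatenation needs >=2 loci, got {len(loci)}")
    if policy not in ("strict", "pad"):
        raise UsageError(f"unknown policy {policy!r}")

    order: list[str] = []
    specimens: dict[str, SpecimenRecord] = {}
    for locus in loci:
        for rec, _ in locus.records:
            if rec.specimen_id not in specimens:
                specimens[rec.specimen_id] = rec
                order.append(rec.specimen_id)

    if policy == "strict":
        missing = {
            sid: [loc.locus_name for loc in loci if sid not in loc.specimen_ids]
            for sid in order
        }
        missing = {sid: locs for sid, locs in missing.items() if locs}
        if missing:
            detail = "; ".join(f"{sid} absent from {locs}" for sid, locs in missing.items())
            raise MetadataError(f"strict concatenation: {detail}")

    records: list[tuple[SpecimenRecord, str]] = []
    for sid in order:
        parts = []
        for locus in loci:
            if sid in locus.specimen_ids:
                parts.append(locus.sequence_of(sid))
            else:
                parts.append("N" * locus.length)
        records.append((specimens[sid], "".join(parts)))
    name = "+".join(loc.locus_name for loc in loci)
    return AlignedLocus(name, records)


def partitions(loci: Sequence[AlignedLocus]) -> list[tuple[str, int, int]]:
    """1-based inclusive (locus_name, start, end) coordinates of each locus
    within the concatenation, in the given order."""
    out = []
    start = 1
    for locus in loci:
        out.append((locus.locus_name, start, start + locus.length - 1))
        start += locus.length
    return out


def write_partitions(loci: Sequence[AlignedLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, start, end in partitions(loci):
            fh.write(f"{name} = {start}-{end}\n")
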