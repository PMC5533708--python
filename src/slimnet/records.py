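"""Protein records and sequence I/O.

Coordinates are 1-based and inclusive everywhere in the public API, matching
the convention of protein databases and feature tables.  Internal code
converts to 0-based slices at the last moment.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_LETTERS = set(AMINO_ACIDS) | {"X"}

ISOFORM_DIFF_KINDS = ("missing", "substituted", "inserted")


class SequenceError(ValueError):
    """Raised for malformed sequences or out-of-range coordinates."""


@dataclasses.dataclass(frozen=True)
class IsoformDiff:
    """A region where an alternative isoform differs from the canonical form.

    ``inserted`` regions are anchored at ``start == end`` (the residue after
    which extra sequence is inserted in the isoform).
    """

    isoform_id: str
    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ISOFORM_DIFF_KINDS:
            raise SequenceError(f"unknown isoform diff kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise SequenceError(
                f"bad isoform diff range {self.start}-{self.end} for {self.isoform_id}"
            )

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence plus optional isoform-difference annotations."""

    accession: str
    name: str
    sequence: str
    isoform_diffs: tuple[IsoformDiff, ...] = ()

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("*", "")
        bad = set(seq) - _VALID_LETTERS
        if bad:
            raise SequenceError(
                f"{self.accession}: non amino-acid letters {sorted(bad)!r}"
            )
        if len(seq) < 1:
            raise SequenceError(f"{self.accession}: empty sequence")
        object.__setattr__(self, "sequence", seq)
        for diff in self.isoform_diffs:
            if diff.end > len(seq):
                raise SequenceError(
                    f"{self.accession}: isoform diff {diff.isoform_id} "
                    f"{diff.start}-{diff.end} exceeds length {len(seq)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Return residues ``start..end`` (1-based, inclusive)."""
        if not (1 <= start <= end <= len(self)):
            raise SequenceError(
                f"{self.accession}: range {start}-{end} outside 1-{len(self)}"
            )
        return self.sequence[start - 1 : end]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Load protein records from a FASTA file.

    The record id becomes the accession; UniProt-style ``db|ACC|NAME`` ids
    are unpacked.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) >= 3:
            accession, name = parts[1], parts[2]
        else:
            accession = name = rec.id
        records.append(ProteinRecord(accession=accession, name=name, sequence=str(rec.seq)))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession} {rec.name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def load_isoform_diffs(path: str | Path) -> dict[str, tuple[IsoformDiff, ...]]:
    """Read an isoform-difference TSV.

    Columns: accession, isoform_id, start, end, kind.
    """
    import csv

    out: dict[str, list[IsoformDiff]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"accession", "isoform_id", "start", "end", "kind"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise SequenceError(f"isoform table {path} missing columns {required}")
        for row in reader:
            out.setdefault(row["accession"], []).append(
                IsoformDiff(
                    isoform_id=row["isoform_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    kind=row["kind"],
                )
            )
    return {acc: tuple(diffs) for acc, diffs in out.items()}


def with_isoform_diffs(record: ProteinRecord, diffs: Iterable[IsoformDiff]) -> ProteinRecord:
    return dataclasses.replace(record, isoform_diffs=tuple(diffs))
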