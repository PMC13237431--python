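"""Aligned-FASTA I/O and the reference-numbered alignment data model.

Every downstream analysis in this package talks about residue *positions*
(27, 142, 173, ...) rather than alignment columns.  Positions are 1-based
residue numbers on a single declared reference sequence (for the HCAR work,
human HCAR2).  This module owns the column <-> reference-position maps so
that "position 27" means the same thing in the fingerprint, indel and
reporting modules regardless of how many insertion columns the alignment
carries.

Conventions
-----------
* Coordinates are 1-based and inclusive throughout.
* Columns where the reference has a gap (insertions relative to the
  reference) carry no reference number; diagnostic analyses skip them,
  indel analyses consume them.
* ``X`` is an allowed residue meaning "unknown"; it never matches any
  profile state.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"
UNKNOWN = "X"
ALLOWED = AA_ALPHABET | {GAP, UNKNOWN}


class Group(str, Enum):
    """Paralog-group membership of an aligned sequence."""

    GROUP_A = "GROUP_A"  # HCAR2-clade
    GROUP_B = "GROUP_B"  # HCAR3-clade
    QUERY = "QUERY"
    REFERENCE_ONLY = "REFERENCE_ONLY"


class AlignmentError(ValueError):
    """Ragged rows, bad alphabet, or other structural problems."""


class LookupId(KeyError):
    """A record or reference id that is not present."""


class RangeError(ValueError):
    """A reference position or region outside the reference frame."""


@dataclass(frozen=True)
class SeqRecord:
    """One gapped protein sequence in an alignment.

    ``residues`` is the gapped string over the 20 amino acids plus ``-``
    (gap) and ``X`` (unknown).
    """

    id: str
    species: str
    group: Group
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise AlignmentError("record id must be nonempty")
        bad = set(self.residues) - ALLOWED
        if bad:
            raise AlignmentError(
                f"record {self.id!r} contains illegal characters: {sorted(bad)!r}"
            )

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count(GAP)


@dataclass(frozen=True)
class RegionAnnotation:
    """A named reference-coordinate interval (e.g. a TM domain).

    ``ref_start``/``ref_end`` are 1-based inclusive positions on the
    reference sequence.
    """

    name: str
    ref_start: int
    ref_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.ref_start <= self.ref_end):
            raise RangeError(
                f"region {self.name!r}: need 1 <= start <= end, "
                f"got ({self.ref_start}, {self.ref_end})"
            )


@dataclass(frozen=True)
class ReferenceAlignment:
    """An alignment anchored to one reference sequence's residue numbering.

    ``col_to_ref[c]`` gives the 1-based reference position of 0-based column
    ``c``, or ``None`` where the reference carries a gap.  ``ref_to_col`` is
    the exact inverse over defined columns.
    """

    records: tuple[SeqRecord, ...]
    reference_id: str
    col_to_ref: tuple[int | None, ...] = field(default=(), compare=True)
    ref_to_col: Mapping[int, int] = field(default_factory=dict, compare=False)

    @staticmethod
    def from_records(
        records: Sequence[SeqRecord], reference_id: str | None = None
    ) -> "ReferenceAlignment":
        records = tuple(records)
        if not records:
            raise AlignmentError("alignment needs at least one record")
        width = len(records[0].residues)
        for rec in records:
            if len(rec.residues) != width:
                raise AlignmentError(
                    f"ragged alignment: {rec.id!r} has length "
                    f"{len(rec.residues)}, expected {width}"
                )
        ids = [rec.id for rec in records]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate record ids in alignment")
        if reference_id is None:
            reference_id = records[0].id
        by_id = {rec.id: rec for rec in records}
        if reference_id not in by_id:
            raise LookupId(f"reference id {reference_id!r} not in alignment")
        ref = by_id[reference_id].residues
        col_to_ref: list[int | None] = []
        pos = 0
        for ch in ref:
            if ch == GAP:
                col_to_ref.append(None)
            else:
                pos += 1
                col_to_ref.append(pos)
        ref_to_col = {p: c for c, p in enumerate(col_to_ref) if p is not None}
        return ReferenceAlignment(
            records=records,
            reference_id=reference_id,
            col_to_ref=tuple(col_to_ref),
            ref_to_col=ref_to_col,
        )

    # -- basic accessors -------------------------------------------------

    @property
    def width(self) -> int:
        return len(self.records[0].residues) if self.records else 0

    @property
    def reference(self) -> SeqRecord:
        return self[self.reference_id]

    @property
    def reference_length(self) -> int:
        """Ungapped length of the reference = highest defined position."""
        return self.reference.ungapped_length

    def __getitem__(self, record_id: str) -> SeqRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise LookupId(f"no record {record_id!r} in alignment")

    def __contains__(self, record_id: str) -> bool:
        return any(rec.id == record_id for rec in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def records_in(self, group: Group) -> tuple[SeqRecord, ...]:
        return tuple(rec for rec in self.records if rec.group is group)

    # -- coordinate mapping ----------------------------------------------

    def column_of(self, ref_pos: int) -> int:
        """0-based column index of 1-based reference position ``ref_pos``."""
        if not (1 <= ref_pos <= self.reference_length):
            raise RangeError(
                f"reference position {ref_pos} outside 1..{self.reference_length}"
            )
        return self.ref_to_col[ref_pos]

    def residue_at(self, record_id: str, ref_pos: int) -> str:
        return self[record_id].residues[self.column_of(ref_pos)]

    def slice_region(self, region: RegionAnnotation) -> "ReferenceAlignment":
        """Sub-alignment over a reference region.

        Spans the region's reference columns plus any insertion columns
        strictly inside it; coordinate maps are rebuilt so positions in the
        slice are renumbered from 1.
        """
        if region.ref_end > self.reference_length:
            raise RangeError(
                f"region {region.name!r} ends at {region.ref_end}, "
                f"reference has {self.reference_length} residues"
            )
        c0 = self.column_of(region.ref_start)
        c1 = self.column_of(region.ref_end)
        new_records = [
            replace(rec, residues=rec.residues[c0 : c1 + 1]) for rec in self.records
        ]
        return ReferenceAlignment.from_records(new_records, self.reference_id)


def check_region_track(regions: Iterable[RegionAnnotation]) -> None:
    """Reject overlapping regions within one annotation track."""
    ordered = sorted(regions, key=lambda r: r.ref_start)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.ref_start <= prev.ref_end:
            raise RangeError(
                f"regions {prev.name!r} and {nxt.name!r} overlap"
            )


# -- file I/O ------------------------------------------------------------


def read_labels(path: str | Path) -> dict[str, tuple[str, Group]]:
    """Read an id -> (species, group) table from TSV/CSV.

    Requires columns ``id``, ``species``, ``group``; the delimiter is
    sniffed from the header line.
    """
    text = Path(path).read_text()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    out: dict[str, tuple[str, Group]] = {}
    for row in csv.DictReader(io.StringIO(text), delimiter=delim):
        out[row["id"]] = (row["species"], Group(row["group"]))
    return out


def read_alignment(
    path: str | Path,
    reference_id: str | None = None,
    labels: Mapping[str, tuple[str, Group]] | None = None,
) -> ReferenceAlignment:
    """Read an aligned protein FASTA into a :class:`ReferenceAlignment`.

    Ids are the description line up to the first whitespace.  Records keep
    file order.  ``labels`` maps id -> (species, group); unlabeled records
    default to species ``""`` and group ``QUERY``.
    """
    records = []
    for bio in SeqIO.parse(str(path), "fasta"):
        species, group = ("", Group.QUERY)
        if labels and bio.id in labels:
            species, group = labels[bio.id]
        records.append(
            SeqRecord(id=bio.id, species=species, group=group,
                      residues=str(bio.seq).upper())
        )
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return ReferenceAlignment.from_records(records, reference_id)


def write_alignment(aln: ReferenceAlignment, path: str | Path) -> None:
    """Write aligned FASTA, wrapped at 60 columns."""
    bio_records = [
        _BioSeqRecord(Seq(rec.residues), id=rec.id, description="")
        for rec in aln.records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio_records, fh, "fasta")


def write_labels(aln: ReferenceAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tspecies\tgroup\n")
        for rec in aln.records:
            fh.write(f"{rec.id}\t{rec.species}\t{rec.group.value}\n")


def read_regions(path: str | Path) -> list[RegionAnnotation]:
    """Read a region track as TSV: name, start, end (1-based inclusive)."""
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, start, end = line.split("\t")[:3]
        regions.append(RegionAnnotation(name, int(start), int(end)))
    check_region_track(regions)
    return regions
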