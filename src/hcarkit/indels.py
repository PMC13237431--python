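"""Lineage-specific indel blocks and pairwise percent identity.

Indel features are read off the alignment relative to the declared
reference frame: maximal runs of reference-gap columns that a record fills
are insertions (e.g. the 24-residue C-terminal insertion of hominine
HCAR3); maximal runs of record-gap columns at reference positions are
deletions (e.g. the 11-residue Colobinae deletion).  Records sharing a
block with *exactly* the same coordinates are merged into one feature with
a carrier set — no fuzzy merging, so every call stays auditable.

Percent identity is reported under an explicit denominator convention,
since published identity values rarely state one.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations

import pandas as pd

from .align_io import GAP, ReferenceAlignment

DEFAULT_MIN_INDEL_LENGTH = 3  # suppress single-gap alignment noise


class IndelKind(str, Enum):
    INSERTION = "INSERTION"
    DELETION = "DELETION"


class IdentityConvention(str, Enum):
    """Denominator used for percent identity.

    UNGAPPED_COLUMNS — columns where both sequences have residues (default);
    SHORTER_SEQ      — same numerator over min(ungapped lengths);
    ALL_COLUMNS      — over every column where at least one sequence has a
    residue (mutual-gap columns say nothing about either sequence and are
    excluded, which keeps self-identity at 100 under all conventions).
    """

    UNGAPPED_COLUMNS = "UNGAPPED_COLUMNS"
    SHORTER_SEQ = "SHORTER_SEQ"
    ALL_COLUMNS = "ALL_COLUMNS"


@dataclass(frozen=True)
class IndelFeature:
    """One insertion/deletion block shared by one or more records.

    ``ref_anchor`` is the 1-based reference position *after which* an
    insertion sits (0 for an insertion before residue 1), or the first
    deleted reference position for a deletion.
    """

    kind: IndelKind
    ref_anchor: int
    length: int
    carriers: frozenset[str]
    region_label: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if not self.carriers:
            raise ValueError("indel carriers must be nonempty")


@dataclass(frozen=True)
class IdentityReport:
    id_x: str
    id_y: str
    n_identical: int
    n_compared: int
    convention: IdentityConvention

    @property
    def percent(self) -> float:
        if self.n_compared == 0:
            return 0.0
        return 100.0 * self.n_identical / self.n_compared


def _gap_runs(mask: list[bool]) -> list[tuple[int, int]]:
    """Maximal (start, end) inclusive runs of True in a boolean column mask."""
    runs, start = [], None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def _last_ref_before(aln: ReferenceAlignment, col: int) -> int:
    """Last defined reference position at or before column ``col`` (0 if none)."""
    for c in range(col, -1, -1):
        if aln.col_to_ref[c] is not None:
            return aln.col_to_ref[c]  # type: ignore[return-value]
    return 0


def detect_indel_blocks(
    aln: ReferenceAlignment, min_length: int = DEFAULT_MIN_INDEL_LENGTH
) -> list[IndelFeature]:
    """Find per-record insertion and deletion blocks, merged by coordinates.

    Insertions are maximal stretches of residues a record places in
    reference-gap columns; deletions are maximal stretches of gaps a record
    shows at reference columns.  Blocks shorter than ``min_length`` are
    dropped.  Records with byte-identical block coordinates share one
    feature; output is sorted by (anchor, kind, length).
    """
    is_insert_col = [p is None for p in aln.col_to_ref]
    # key: (kind, start_col, end_col) -> carriers
    found: dict[tuple[IndelKind, int, int], set[str]] = {}
    for rec in aln.records:
        if rec.id == aln.reference_id:
            # the reference defines the frame; its own gaps are other
            # records' insertions, and it has no deletions from itself
            continue
        res = rec.residues
        ins_mask = [is_insert_col[c] and res[c] != GAP for c in range(aln.width)]
        for start, end in _gap_runs(ins_mask):
            found.setdefault((IndelKind.INSERTION, start, end), set()).add(rec.id)
        del_mask = [not is_insert_col[c] and res[c] == GAP for c in range(aln.width)]
        for start, end in _gap_runs(del_mask):
            found.setdefault((IndelKind.DELETION, start, end), set()).add(rec.id)
    features = []
    for (kind, start, end), carriers in found.items():
        length = end - start + 1
        if length < min_length:
            continue
        if kind is IndelKind.INSERTION:
            anchor = _last_ref_before(aln, start)
        else:
            anchor = aln.col_to_ref[start]  # type: ignore[assignment]
        features.append(
            IndelFeature(kind=kind, ref_anchor=int(anchor), length=length,
                         carriers=frozenset(carriers))
        )
    features.sort(
        key=lambda f: (f.ref_anchor, f.kind.value, f.length, sorted(f.carriers))
    )
    return features


def pairwise_identity(
    aln: ReferenceAlignment,
    id_x: str,
    id_y: str,
    convention: IdentityConvention = IdentityConvention.UNGAPPED_COLUMNS,
) -> IdentityReport:
    """Percent identity between two records under an explicit convention.

    The numerator is always the number of columns where both records carry
    the same residue (gaps never count as identical); the convention picks
    the denominator.  Rounding happens only at display.
    """
    rx, ry = aln[id_x], aln[id_y]
    n_identical = sum(
        1
        for a, b in zip(rx.residues, ry.residues)
        if a != GAP and b != GAP and a == b
    )
    if convention is IdentityConvention.UNGAPPED_COLUMNS:
        n_compared = sum(
            1 for a, b in zip(rx.residues, ry.residues) if a != GAP and b != GAP
        )
    elif convention is IdentityConvention.SHORTER_SEQ:
        n_compared = min(rx.ungapped_length, ry.ungapped_length)
    else:
        n_compared = sum(
            1 for a, b in zip(rx.residues, ry.residues) if (a, b) != (GAP, GAP)
        )
    return IdentityReport(
        id_x=id_x, id_y=id_y, n_identical=n_identical,
        n_compared=n_compared, convention=convention,
    )


def identity_matrix(
    aln: ReferenceAlignment,
    convention: IdentityConvention = IdentityConvention.UNGAPPED_COLUMNS,
) -> pd.DataFrame:
    """Symmetric percent-identity table over all records (diagonal 100)."""
    ids = [rec.id for rec in aln.records]
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for id_x, id_y in combinations(ids, 2):
        pct = pairwise_identity(aln, id_x, id_y, convention).percent
        mat.loc[id_x, id_y] = pct
        mat.loc[id_y, id_x] = pct
    return mat
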