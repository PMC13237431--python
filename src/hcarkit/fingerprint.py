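"""Diagnostic-site discovery and profile classification for paralog groups.

After a gene duplication, a handful of alignment positions may become fixed
for different residues in the two daughter lineages while staying invariant
within each.  Such *diagnostic* (fingerprint) positions let a new sequence
be assigned to one paralog group or the other — the core inference used to
argue that the single-copy HCAR2/3 receptor of non-ape primates resembles
HCAR2 rather than HCAR3.

"Consistently and unambiguously distinguishing" is formalised here as:
within-group invariance plus between-group disjointness, with no gap or X
in either group at the column (strict mode).  Relaxed mode collects
per-group state *sets* and requires only disjointness.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .align_io import (
    GAP,
    UNKNOWN,
    Group,
    LookupId,
    ReferenceAlignment,
    SeqRecord,
)


class InputError(ValueError):
    pass


class Call(str, Enum):
    MATCH_A = "MATCH_A"
    MATCH_B = "MATCH_B"
    NEITHER = "NEITHER"
    AMBIGUOUS = "AMBIGUOUS"


class Verdict(str, Enum):
    A_LIKE = "A_LIKE"
    B_LIKE = "B_LIKE"
    MIXED = "MIXED"
    UNDETERMINED = "UNDETERMINED"


RECOMMENDED_GROUP_SIZE = 4  # the ape profile rests on 4 species per group


@dataclass(frozen=True)
class DiagnosticProfile:
    """Ordered diagnostic positions with their two group-consensus states.

    ``state_a[i]``/``state_b[i]`` are the residue sets observed in groups A
    (HCAR2-like) and B (HCAR3-like) at ``positions[i]``; under strict
    discovery both are singletons.  ``pocket_proximal[i]`` flags positions
    lining the ligand-binding pocket (set by :func:`partition_by_pocket`;
    defaults to all-proximal until a distal set is declared).
    """

    positions: tuple[int, ...]
    state_a: tuple[frozenset[str], ...]
    state_b: tuple[frozenset[str], ...]
    pocket_proximal: tuple[bool, ...]
    min_group_size: int

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise InputError("profile positions must be strictly increasing")
        for pos, sa, sb in zip(self.positions, self.state_a, self.state_b):
            if sa & sb:
                raise InputError(f"states overlap at position {pos}")
        if not (
            len(self.positions)
            == len(self.state_a)
            == len(self.state_b)
            == len(self.pocket_proximal)
        ):
            raise InputError("profile fields must have equal length")

    def __len__(self) -> int:
        return len(self.positions)

    def index_of(self, position: int) -> int:
        try:
            return self.positions.index(position)
        except ValueError:
            raise InputError(f"position {position} not in profile") from None

    def states_at(self, position: int) -> tuple[frozenset[str], frozenset[str]]:
        i = self.index_of(position)
        return self.state_a[i], self.state_b[i]

    def drop_position(self, position: int) -> "DiagnosticProfile":
        i = self.index_of(position)
        keep = [j for j in range(len(self)) if j != i]
        return DiagnosticProfile(
            positions=tuple(self.positions[j] for j in keep),
            state_a=tuple(self.state_a[j] for j in keep),
            state_b=tuple(self.state_b[j] for j in keep),
            pocket_proximal=tuple(self.pocket_proximal[j] for j in keep),
            min_group_size=self.min_group_size,
        )

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "positions": list(self.positions),
            "state_a": ["".join(sorted(s)) for s in self.state_a],
            "state_b": ["".join(sorted(s)) for s in self.state_b],
            "pocket_proximal": list(self.pocket_proximal),
            "min_group_size": self.min_group_size,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @staticmethod
    def from_json(source: str | Path) -> "DiagnosticProfile":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        return DiagnosticProfile(
            positions=tuple(payload["positions"]),
            state_a=tuple(frozenset(s) for s in payload["state_a"]),
            state_b=tuple(frozenset(s) for s in payload["state_b"]),
            pocket_proximal=tuple(payload["pocket_proximal"]),
            min_group_size=payload["min_group_size"],
        )


@dataclass(frozen=True)
class ClassificationResult:
    """Per-position calls and summary counts for one query sequence."""

    query_id: str
    calls: tuple[Call, ...]
    positions: tuple[int, ...]
    n_a: int
    n_b: int
    n_neither: int
    n_ambiguous: int
    pocket_n_a: int
    pocket_n_b: int
    verdict: Verdict

    def call_at(self, position: int) -> Call:
        return self.calls[self.positions.index(position)]


def _diagnostic_states_at_column(
    col_a: Sequence[str], col_b: Sequence[str], strict: bool
) -> tuple[frozenset[str], frozenset[str]] | None:
    """Apply the diagnostic-column definition to one column's group residues.

    Returns the (state_a, state_b) pair if the column is diagnostic under
    the chosen mode, else None.
    """
    sa, sb = frozenset(col_a), frozenset(col_b)
    if strict:
        if len(sa) != 1 or len(sb) != 1 or sa == sb:
            return None
        if (sa | sb) & {GAP, UNKNOWN}:
            return None
        return sa, sb
    # relaxed: per-group state sets, gaps/X stripped, disjointness required
    sa = sa - {GAP, UNKNOWN}
    sb = sb - {GAP, UNKNOWN}
    if not sa or not sb or (sa & sb):
        return None
    return sa, sb


def discover_diagnostic_positions(
    aln: ReferenceAlignment,
    strict: bool = True,
    min_group_size: int = 2,
) -> DiagnosticProfile:
    """Find every reference position that separates group A from group B.

    Strict mode requires each group to be invariant at the column, the two
    states to differ, and no gap or X in either group; relaxed mode only
    requires the per-group state sets to be disjoint.  Insertion columns
    (no reference number) are never diagnostic.
    """
    group_a = aln.records_in(Group.GROUP_A)
    group_b = aln.records_in(Group.GROUP_B)
    if not group_a or not group_b:
        raise InputError("discovery needs at least one record in each group")
    if min(len(group_a), len(group_b)) < min_group_size:
        raise InputError(
            f"group sizes ({len(group_a)}, {len(group_b)}) below "
            f"min_group_size={min_group_size}"
        )
    if min(len(group_a), len(group_b)) < RECOMMENDED_GROUP_SIZE:
        warnings.warn(
            "diagnostic discovery with fewer than "
            f"{RECOMMENDED_GROUP_SIZE} sequences per group is fragile",
            stacklevel=2,
        )
    positions: list[int] = []
    state_a: list[frozenset[str]] = []
    state_b: list[frozenset[str]] = []
    for col, ref_pos in enumerate(aln.col_to_ref):
        if ref_pos is None:
            continue
        states = _diagnostic_states_at_column(
            [rec.residues[col] for rec in group_a],
            [rec.residues[col] for rec in group_b],
            strict,
        )
        if states is not None:
            positions.append(ref_pos)
            state_a.append(states[0])
            state_b.append(states[1])
    return DiagnosticProfile(
        positions=tuple(positions),
        state_a=tuple(state_a),
        state_b=tuple(state_b),
        pocket_proximal=tuple(True for _ in positions),
        min_group_size=min(len(group_a), len(group_b)),
    )


def nondiagnostic_differences(
    aln: ReferenceAlignment, id_x: str, id_y: str, profile: DiagnosticProfile
) -> list[int]:
    """Reference positions where two records differ but that are not in the
    diagnostic profile (e.g. within-group polymorphic sites).

    Reported without interpretation.
    """
    rx, ry = aln[id_x], aln[id_y]
    out = []
    for col, ref_pos in enumerate(aln.col_to_ref):
        if ref_pos is None or ref_pos in profile.positions:
            continue
        a, b = rx.residues[col], ry.residues[col]
        if GAP in (a, b):
            continue
        if a != b:
            out.append(ref_pos)
    return out


def count_pairwise_differences(
    aln: ReferenceAlignment, id_x: str, id_y: str
) -> int:
    """Number of columns where both records have residues and they differ.

    Indel columns (a gap in either record) are excluded — those belong to
    the indel report, not the substitution count.
    """
    rx, ry = aln[id_x], aln[id_y]
    return sum(
        1
        for a, b in zip(rx.residues, ry.residues)
        if a != GAP and b != GAP and a != b
    )


def partition_by_pocket(
    profile: DiagnosticProfile, distal_positions: Iterable[int]
) -> DiagnosticProfile:
    """Flag profile positions as pocket-proximal or pocket-distal.

    ``distal_positions`` must be a subset of the profile's positions;
    everything else is marked proximal.  Returns a new profile with
    ``pocket_proximal`` set.
    """
    distal = set(distal_positions)
    unknown = distal - set(profile.positions)
    if unknown:
        raise InputError(f"distal positions not in profile: {sorted(unknown)}")
    return DiagnosticProfile(
        positions=profile.positions,
        state_a=profile.state_a,
        state_b=profile.state_b,
        pocket_proximal=tuple(p not in distal for p in profile.positions),
        min_group_size=profile.min_group_size,
    )


def split_by_pocket(profile: DiagnosticProfile) -> tuple[list[int], list[int]]:
    """(proximal, distal) position lists from the stored flags."""
    prox = [p for p, f in zip(profile.positions, profile.pocket_proximal) if f]
    dist = [p for p, f in zip(profile.positions, profile.pocket_proximal) if not f]
    return prox, dist


def default_verdict_rule(
    n_a: int, n_b: int, pocket_n_a: int, pocket_n_b: int, n_scored: int
) -> Verdict:
    """Default verdict: majority vote gated on pocket-proximal purity.

    A query is A_LIKE only if A wins the overall vote *and* no
    pocket-proximal position matches B (mismatches far from the binding
    pocket are tolerated, as they are unlikely to change ligand
    interactions); symmetrically for B_LIKE.  Ties and pocket conflicts
    give MIXED; a query with nothing scored is UNDETERMINED.
    """
    if n_scored == 0:
        return Verdict.UNDETERMINED
    if n_a > n_b and pocket_n_b == 0:
        return Verdict.A_LIKE
    if n_b > n_a and pocket_n_a == 0:
        return Verdict.B_LIKE
    return Verdict.MIXED


def classify_sequence(
    query: SeqRecord | str,
    profile: DiagnosticProfile,
    aln: ReferenceAlignment,
    verdict_rule=default_verdict_rule,
) -> ClassificationResult:
    """Score one aligned query against a diagnostic profile.

    Per position: MATCH_A if the residue is in the group-A state,
    MATCH_B if in the group-B state, AMBIGUOUS for gap or X (unknowable is
    distinct from mismatching), NEITHER otherwise.
    """
    if len(profile) == 0:
        raise InputError("cannot classify against an empty profile")
    rec = aln[query] if isinstance(query, str) else query
    if len(rec.residues) != aln.width:
        raise InputError(
            f"query {rec.id!r} length {len(rec.residues)} does not match "
            f"alignment width {aln.width}"
        )
    calls: list[Call] = []
    pocket_n_a = pocket_n_b = 0
    for pos, sa, sb, proximal in zip(
        profile.positions, profile.state_a, profile.state_b, profile.pocket_proximal
    ):
        residue = rec.residues[aln.column_of(pos)]
        if residue in (GAP, UNKNOWN):
            call = Call.AMBIGUOUS
        elif residue in sa:
            call = Call.MATCH_A
            pocket_n_a += proximal
        elif residue in sb:
            call = Call.MATCH_B
            pocket_n_b += proximal
        else:
            call = Call.NEITHER
        calls.append(call)
    n_a = sum(c is Call.MATCH_A for c in calls)
    n_b = sum(c is Call.MATCH_B for c in calls)
    n_ambiguous = sum(c is Call.AMBIGUOUS for c in calls)
    n_neither = len(calls) - n_a - n_b - n_ambiguous
    verdict = verdict_rule(n_a, n_b, pocket_n_a, pocket_n_b, len(calls) - n_ambiguous)
    return ClassificationResult(
        query_id=rec.id,
        calls=tuple(calls),
        positions=profile.positions,
        n_a=n_a,
        n_b=n_b,
        n_neither=n_neither,
        n_ambiguous=n_ambiguous,
        pocket_n_a=pocket_n_a,
        pocket_n_b=pocket_n_b,
        verdict=verdict,
    )


def classify_cohort(
    queries: Sequence[SeqRecord | str],
    profile: DiagnosticProfile,
    aln: ReferenceAlignment,
    verdict_rule=default_verdict_rule,
) -> tuple[list[ClassificationResult], pd.DataFrame]:
    """Classify several queries; returns results plus a wide summary table.

    Summary rows follow input order; one column block per profile position
    holds the per-position call.
    """
    results = [classify_sequence(q, profile, aln, verdict_rule) for q in queries]
    rows = []
    for res in results:
        row: dict[str, object] = {
            "query_id": res.query_id,
            "n_a": res.n_a,
            "n_b": res.n_b,
            "n_neither": res.n_neither,
            "n_ambiguous": res.n_ambiguous,
            "pocket_n_a": res.pocket_n_a,
            "pocket_n_b": res.pocket_n_b,
            "verdict": res.verdict.value,
        }
        for pos, call in zip(res.positions, res.calls):
            row[f"pos{pos}"] = call.value
        rows.append(row)
    return results, pd.DataFrame(rows)
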