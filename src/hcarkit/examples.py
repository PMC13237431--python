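"""Synthetic worked-example data for the primate HCAR2/HCAR3 analysis.

SYNTHETIC STAND-IN.  The real HCAR protein sequences are not bundled (they
require a database download); this module constructs, in code, a sequence
panel and tree set that honour every residue state and per-lineage count
the published analysis reports:

* 12 diagnostic positions {27, 83, 86, 91, 103, 107, 142, 167, 168, 173,
  176, 178}, of which {27, 142, 167, 168, 173} are distal to the
  ligand-binding pocket;
* stated states: position 27 V (HCAR2) / A (HCAR3), position 173 G / T,
  position 167 HCAR3-state L;
* human HCAR2 vs human HCAR3 differ at 18 positions (the 12 diagnostic
  ones plus 6 that are polymorphic within the HCAR3 group);
* a 24-residue C-terminal insertion carried by human/chimpanzee/bonobo
  HCAR3 and absent from gorilla HCAR3;
* an 11-residue C-terminal deletion in the Colobinae;
* the non-ape, orangutan and gibbon match-count patterns (e.g. tarsier
  9 HCAR2 / 2 HCAR3 / serine at 173; New World monkeys S at 27 and N at
  173, matching neither profile).

Residues at positions the text does not state are invented, as is the
background sequence (reference length 363, the length of human HCAR2).
Conclusions drawn from this panel therefore test the *machinery*, not the
real molecules.
"""

from __future__ import annotations

import numpy as np

from .align_io import Group, ReferenceAlignment, SeqRecord
from .fingerprint import DiagnosticProfile, discover_diagnostic_positions, partition_by_pocket
from .reconcile import LabeledTree
from .synthetic import PRIMATE_SPECIES_TREE

REFERENCE_LENGTH = 363  # ungapped length of human HCAR2
INSERTION_ANCHOR = 329  # 24-aa insertion sits after this reference position
INSERTION_LENGTH = 24
DELETION_START = 340  # 11-aa Colobinae deletion covers 340..350
DELETION_LENGTH = 11

DIAGNOSTIC_POSITIONS = (27, 83, 86, 91, 103, 107, 142, 167, 168, 173, 176, 178)
POCKET_DISTAL = frozenset({27, 142, 167, 168, 173})

# HCAR2-state / HCAR3-state per diagnostic position.  27, 167 (HCAR3 L)
# and 173 are as published; the rest are invented placeholders.
STATE_A = {
    27: "V", 83: "S", 86: "N", 91: "R", 103: "M", 107: "F",
    142: "R", 167: "F", 168: "S", 173: "G", 176: "K", 178: "Q",
}
STATE_B = {
    27: "A", 83: "C", 86: "Y", 91: "W", 103: "I", 107: "L",
    142: "C", 167: "L", 168: "N", 173: "T", 176: "E", 178: "H",
}

# positions where human HCAR3 differs from HCAR2 but the HCAR3 group is
# not invariant (so they are differences, not diagnostics): 12 + 6 = 18
NONDIAGNOSTIC_HUMAN_DIFFS = (60, 120, 150, 200, 250, 310)

_PRIVATE_SUBS = {  # species-specific substitutions, for identity spread
    "Gorilla_gorilla_HCAR2": (45, 95, 210, 305),
    "Gorilla_gorilla_HCAR3": (50, 130, 220, 260, 315),
    "Pan_troglodytes_HCAR3": (70,),
    "Pan_paniscus_HCAR3": (235,),
}


def _base_sequence() -> list[str]:
    rng = np.random.default_rng(3631224)
    return list("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, REFERENCE_LENGTH))


def _variant(base_char: str, salt: int) -> str:
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    return alphabet[(alphabet.index(base_char) + 1 + salt % 19) % 20] \
        if alphabet[(alphabet.index(base_char) + 1 + salt % 19) % 20] != base_char \
        else alphabet[(alphabet.index(base_char) + 2) % 20]


def _insertion_block() -> str:
    rng = np.random.default_rng(2024)
    return "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, INSERTION_LENGTH))


def _make_record(
    rec_id: str,
    species: str,
    group: Group,
    overrides: dict[int, str],
    carries_insertion: bool = False,
    carries_deletion: bool = False,
) -> SeqRecord:
    chars = _base_sequence()
    for pos, aa in overrides.items():
        chars[pos - 1] = aa
    if carries_deletion:
        for pos in range(DELETION_START, DELETION_START + DELETION_LENGTH):
            chars[pos - 1] = "-"
    block = _insertion_block() if carries_insertion else "-" * INSERTION_LENGTH
    aligned = "".join(chars[:INSERTION_ANCHOR]) + block + "".join(chars[INSERTION_ANCHOR:])
    return SeqRecord(id=rec_id, species=species, group=group, residues=aligned)


def _profile_overrides(states: dict[int, str]) -> dict[int, str]:
    return dict(states)


def synthetic_ape_alignment() -> ReferenceAlignment:
    """The 8-sequence hominine HCAR2/HCAR3 panel (profile-building set).

    HCAR2 records are GROUP_A, HCAR3 records GROUP_B; reference is human
    HCAR2.  Chimpanzee and bonobo HCAR2 are identical (100% pairwise
    identity, as published); the other species carry a few private
    substitutions for realistic identity spread.
    """
    records = []
    hominines = [
        ("Homo_sapiens", True),
        ("Pan_troglodytes", True),
        ("Pan_paniscus", True),
        ("Gorilla_gorilla", False),  # gorilla HCAR3 lacks the insertion
    ]
    for species, hcar3_has_insertion in hominines:
        over_a = _profile_overrides(STATE_A)
        over_b = _profile_overrides(STATE_B)
        if species == "Homo_sapiens":
            for pos in NONDIAGNOSTIC_HUMAN_DIFFS:
                over_b[pos] = _variant(_base_sequence()[pos - 1], pos)
        for suffix, group, over in (
            ("HCAR2", Group.GROUP_A, over_a),
            ("HCAR3", Group.GROUP_B, over_b),
        ):
            rec_id = f"{species}_{suffix}"
            for pos in _PRIVATE_SUBS.get(rec_id, ()):
                over[pos] = _variant(_base_sequence()[pos - 1], pos + 7)
            records.append(
                _make_record(
                    rec_id, species, group, over,
                    carries_insertion=(suffix == "HCAR3" and hcar3_has_insertion),
                )
            )
    return ReferenceAlignment.from_records(records, "Homo_sapiens_HCAR2")


def _query_specs() -> list[tuple[str, str, dict[int, str], bool]]:
    """(record id, species, diagnostic-state overrides, carries_deletion).

    Encodes the published per-lineage patterns; positions not mentioned
    for a lineage take the HCAR2 state (the ancestral condition).
    """
    A, B = STATE_A, STATE_B

    def pattern(b_at=(), neither=None) -> dict[int, str]:
        over = dict(A)
        for pos in b_at:
            over[pos] = B[pos]
        if neither:
            over.update(neither)
        return over

    return [
        # orangutans: two copies each; the HCAR3-like copy keeps the HCAR2
        # state at 86 and 142 (10 of 12 distinguish)
        ("Pongo_abelii_copyA", "Pongo_abelii", pattern(), False),
        ("Pongo_abelii_copyB", "Pongo_abelii",
         pattern(b_at=[p for p in DIAGNOSTIC_POSITIONS if p not in (86, 142)]), False),
        ("Pongo_pygmaeus_copyA", "Pongo_pygmaeus", pattern(), False),
        ("Pongo_pygmaeus_copyB", "Pongo_pygmaeus",
         pattern(b_at=[p for p in DIAGNOSTIC_POSITIONS if p not in (86, 142)]), False),
        # lesser apes: green clade = HCAR2-like except position 27;
        # blue clade = 8 HCAR3 / 3 HCAR2 / neither at 91
        ("Symphalangus_syndactylus_green", "Symphalangus_syndactylus",
         pattern(b_at=[27]), False),
        ("Symphalangus_syndactylus_blue", "Symphalangus_syndactylus",
         pattern(b_at=[p for p in DIAGNOSTIC_POSITIONS if p not in (91, 142, 167, 176)],
                 neither={91: "H"}), False),
        ("Hoolock_leuconedys_blue1", "Hoolock_leuconedys",
         pattern(b_at=[p for p in DIAGNOSTIC_POSITIONS if p not in (91, 142, 167, 176)],
                 neither={91: "H"}), False),
        ("Hoolock_leuconedys_blue2", "Hoolock_leuconedys",
         pattern(b_at=[27, 86, 103]), False),
        ("Hylobates_agilis_single", "Hylobates_agilis", pattern(b_at=[27]), False),
        ("Nomascus_leucogenys_single", "Nomascus_leucogenys", pattern(b_at=[27]), False),
        # Old World monkeys: 11 HCAR2-like, HCAR3 state at 173; the Uganda
        # red colobus has serine there instead; Colobinae carry the deletion
        ("Macaca_fascicularis_single", "Macaca_fascicularis",
         pattern(b_at=[173]), False),
        ("Rhinopithecus_roxellana_single", "Rhinopithecus_roxellana",
         pattern(b_at=[173]), True),
        ("Piliocolobus_tephrosceles_single", "Piliocolobus_tephrosceles",
         pattern(neither={173: "S"}), True),
        # New World monkeys: S at 27 and N at 173 (neither), N at 168 (HCAR3)
        ("Callithrix_jacchus_single", "Callithrix_jacchus",
         pattern(b_at=[168], neither={27: "S", 173: "N"}), False),
        # tarsier: 9 HCAR2 / 2 HCAR3 / serine at 173
        ("Carlito_syrichta_single", "Carlito_syrichta",
         pattern(b_at=[27, 168], neither={173: "S"}), False),
        # strepsirrhines: all HCAR3-like at 168; aye-aye and ring-tailed
        # lemur keep the HCAR2 state at 27, the other two do not; lemur is
        # HCAR3-like (leucine) at 167; 173 is P or S (neither)
        ("Lemur_catta_single", "Lemur_catta",
         pattern(b_at=[167, 168], neither={173: "S"}), False),
        ("Daubentonia_madagascariensis_single", "Daubentonia_madagascariensis",
         pattern(b_at=[168], neither={173: "P"}), False),
        ("Propithecus_coquereli_single", "Propithecus_coquereli",
         pattern(b_at=[27, 168], neither={173: "P"}), False),
        ("Nycticebus_coucang_single", "Nycticebus_coucang",
         pattern(b_at=[27, 168], neither={173: "S"}), False),
    ]


def synthetic_primate_panel() -> ReferenceAlignment:
    """Hominine profile set plus every non-hominine query, one alignment.

    Queries carry group QUERY; reference remains human HCAR2.
    """
    records = list(synthetic_ape_alignment().records)
    for rec_id, species, overrides, deletion in _query_specs():
        records.append(
            _make_record(rec_id, species, Group.QUERY, overrides,
                         carries_deletion=deletion)
        )
    return ReferenceAlignment.from_records(records, "Homo_sapiens_HCAR2")


def synthetic_ape_profile() -> DiagnosticProfile:
    """Diagnostic profile discovered from the synthetic hominine panel,
    with the published pocket-distal partition applied."""
    profile = discover_diagnostic_positions(synthetic_ape_alignment())
    return partition_by_pocket(profile, POCKET_DISTAL)


# -- transcribed tree topologies -----------------------------------------

def _n(*parts: str) -> str:
    return "(" + ",".join(parts) + ")"


def _hominines(tag: str) -> str:
    return _n(
        _n(f"h{tag}|Homo_sapiens",
           _n(f"c{tag}|Pan_troglodytes", f"b{tag}|Pan_paniscus")),
        f"g{tag}|Gorilla_gorilla",
    )


_OWM = _n("mac|Macaca_fascicularis", "rhi|Rhinopithecus_roxellana")


def _with_outgroups(ape_clade: str) -> str:
    out = _n(ape_clade, _OWM)
    out = _n(out, "cal|Callithrix_jacchus")
    out = _n(out, "car|Carlito_syrichta")
    return _n(out, "lem|Lemur_catta") + ";"


# Gene-tree topology in the style of the published primate HCAR phylogeny:
# hominine HCAR2 and HCAR3 clades are sisters (one duplication in their
# common ancestor), the orangutan copies form their own pair clade, the
# gibbon copies split into an HCAR2-like ("green") and an HCAR3-like
# ("blue") clade with a nested Hoolock duplication, and every non-ape
# lineage contributes a single pre-duplication gene.
FIG1_STYLE_GENE_TREE = _with_outgroups(
    _n(
        _n(
            _n(_hominines("2"), _hominines("3")),
            _n(_n("paA|Pongo_abelii", "ppA|Pongo_pygmaeus"),
               _n("paB|Pongo_abelii", "ppB|Pongo_pygmaeus")),
        ),
        _n(
            _n("syG|Symphalangus_syndactylus",
               _n("hy|Hylobates_agilis", "no|Nomascus_leucogenys")),
            _n("syB|Symphalangus_syndactylus",
               _n("hoA|Hoolock_leuconedys", "hoB|Hoolock_leuconedys")),
        ),
    )
)

# The previously proposed alternative: one duplication in the ape ancestor
# with all HCAR2-like copies in one clade (including, as that proposal had
# it, the single-copy genes of non-ape primates) and all HCAR3-like copies
# in the other.
_HCAR2_CLADE_APES = _n(
    _n(_hominines("2"), _n("paA|Pongo_abelii", "ppA|Pongo_pygmaeus")),
    _n("hoA|Hoolock_leuconedys",
       _n("syG|Symphalangus_syndactylus",
          _n("hy|Hylobates_agilis", "no|Nomascus_leucogenys"))),
)
_HCAR2_CLADE = _n(
    _n(_n(_n(_HCAR2_CLADE_APES, _OWM), "cal|Callithrix_jacchus"),
       "car|Carlito_syrichta"),
    "lem|Lemur_catta",
)
_HCAR3_CLADE = _n(
    _n(_hominines("3"), _n("paB|Pongo_abelii", "ppB|Pongo_pygmaeus")),
    _n("syB|Symphalangus_syndactylus", "hoB|Hoolock_leuconedys"),
)
SINGLE_DUPLICATION_GENE_TREE = _n(_HCAR2_CLADE, _HCAR3_CLADE) + ";"


def fig1_style_gene_tree() -> LabeledTree:
    return LabeledTree.from_newick(FIG1_STYLE_GENE_TREE)


def single_duplication_gene_tree() -> LabeledTree:
    return LabeledTree.from_newick(SINGLE_DUPLICATION_GENE_TREE)


def primate_species_tree() -> LabeledTree:
    return LabeledTree.from_newick(PRIMATE_SPECIES_TREE)
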