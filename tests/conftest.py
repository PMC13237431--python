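import numpy as np
import pytest

from hcarkit.align_io import Group, ReferenceAlignment, SeqRecord


def make_alignment(rows, reference_id=None):
    """rows: list of (id, group, residues) or (id, species, group, residues)."""
    records = []
    for row in rows:
        if len(row) == 3:
            rec_id, group, residues = row
            species = rec_id
        else:
            rec_id, species, group, residues = row
        records.append(
            SeqRecord(id=rec_id, species=species, group=group, residues=residues)
        )
    return ReferenceAlignment.from_records(records, reference_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def toy_gapped():
    """Reference MK-LV with a gap at column 3 (the hand-walk example)."""
    return make_alignment(
        [
            ("ref", Group.GROUP_A, "MK-LV"),
            ("a", Group.GROUP_A, "MKQLV"),
            ("b", Group.GROUP_B, "MKQIV"),
        ],
        "ref",
    )
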