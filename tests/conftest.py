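import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import cladediag as cd


@pytest.fixture(scope="session")
def default_ds():
    """The default synthetic study dataset (3 clades x 8 members)."""
    return cd.default_dataset(seed=1)


@pytest.fixture(scope="session")
def default_reports(default_ds):
    aln, part, _ = default_ds
    return cd.screen_all_clades(aln, part)


@pytest.fixture(scope="session")
def landmark_ds():
    """The coordinate-landmark fixture (4 clades, 2188 columns)."""
    return cd.landmark_dataset(seed=1)


@pytest.fixture
def toy_alignment():
    """6 x 60 alignment with a planted 12-column clade-exclusive block.

    CladeA rows carry the background block of columns 25..36 (1-based)
    with two diagnostic substitutions; the two flanking columns are
    deleted in one CladeA member each so the block has hard boundaries.
    """
    bg = "ACGTACGTGCTAGCATCGATCGAT" "TACGATTACGGT" "AGCTTAGCATGCATGCATGCGTAC"
    assert len(bg) == 60
    block = "TACTATTAAGGT"  # bg block with offsets 3 (G->T) and 8 (C->A) changed

    def with_block(row: str, deletion_at: int | None = None) -> str:
        row = row[:24] + block + row[36:]
        if deletion_at is not None:
            row = row[:deletion_at] + "-" + row[deletion_at + 1:]
        return row

    rows = {
        "a1": with_block(bg, deletion_at=23),
        "a2": with_block(bg, deletion_at=36),
        "a3": with_block(bg),
        "b1": bg,
        "b2": bg,
        "b3": bg[:50] + "A" + bg[51:],  # a stray substitution
    }
    aln = cd.Alignment(
        [cd.AlignedSequence(i, s) for i, s in rows.items()]
    )
    part = cd.CladePartition(
        {"a1": "CladeA", "a2": "CladeA", "a3": "CladeA",
         "b1": "CladeB", "b2": "CladeB", "b3": "CladeB"}
    )
    return aln, part, rows
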