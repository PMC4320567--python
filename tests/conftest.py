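import numpy as np
import pytest

from cryoscan.family_assembly import AlignedRow, FamilyAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(20140)


@pytest.fixture
def small_family():
    """A hand-built aligned family with all four provenances."""
    rows = [
        AlignedRow("u1", "uniprot", "MKVLADERTG"),
        AlignedRow("u2", "uniprot", "MKVLADERTG"),
        AlignedRow("p1", "psychrophile", "MKVLGDERTG"),
        AlignedRow("p2", "psychrophile", "MKVLGDERSG"),
        AlignedRow("m1", "mesophile", "MKILADERTG"),
        AlignedRow("m2", "mesophile", "MKILADERTA"),
        AlignedRow("f1", "pfam", "MKVLADE-TG"),
    ]
    return FamilyAlignment(family="toy", rows=rows)
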