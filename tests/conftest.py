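import pytest

import phylocurate as pc
from phylocurate.alignment import GeneAlignment, OrthologSet, TaxonManifest


@pytest.fixture(scope="session")
def gastropod_fixture():
    """The study-shaped benchmark dataset (74 terminals, 1059 genes)."""
    return pc.make_gastropod_fixture(seed=1)


@pytest.fixture
def small_manifest():
    return TaxonManifest.from_rows(
        [
            ("A", "Gastropoda", "new"),
            ("B", "Gastropoda", "published_ingroup"),
            ("C", "Gastropoda", "published_ingroup"),
            ("D", "Bivalvia", "outgroup"),
        ]
    )


@pytest.fixture
def small_set(small_manifest):
    genes = [
        GeneAlignment("g1", {"A": "ACDE", "B": "ACDF", "C": "AC-E", "D": "ACDE"}),
        GeneAlignment("g2", {"A": "WWWW", "B": "WWW-"}),
        GeneAlignment("g3", {"A": "MMM", "B": "MM-", "C": "MMM"}),
    ]
    return OrthologSet(small_manifest, genes)

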