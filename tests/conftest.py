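"""Shared fixtures: tiny panels, rank stores, and synthetic inputs."""

import pytest

from neoscreen.haplotype_io import Allotype, Haplotype, HaplotypePanel
from neoscreen.predictor_gateway import RankRecord, RankStore


def allo(name: str) -> Allotype:
    from neoscreen.haplotype_io import parse_allotype

    return parse_allotype(name)


def make_haplotype(ind_id: str, a1="A*01:01", a2="A*02:01", b1="B*07:02",
                   b2="B*08:01", c1="C*07:01", c2="C*07:02") -> Haplotype:
    return Haplotype(ind_id, tuple(allo(x) for x in (a1, a2, b1, b2, c1, c2)))


def make_store(entries) -> RankStore:
    """entries: iterable of (peptide, allotype_name, rank[, icore])."""
    store = RankStore()
    for entry in entries:
        peptide, allotype, rank = entry[:3]
        icore = entry[3] if len(entry) > 3 else peptide
        store.add(RankRecord(peptide, allo(allotype), rank, icore))
    return store


@pytest.fixture
def six_allotype_haplotype():
    return make_haplotype("IND1")


@pytest.fixture
def two_person_panel():
    return HaplotypePanel(
        [
            make_haplotype("IND1"),
            make_haplotype("IND2", a1="A*03:01", a2="A*03:01"),
        ],
        provenance="fixture",
    )
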