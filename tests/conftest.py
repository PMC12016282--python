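from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from brackenlite.kmer_index import GenomeRecord, build_kmer_index
from brackenlite.distribution import build_distribution
from brackenlite.taxonomy import TaxonNode, TaxonomyTree

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def build_tree(rows):
    """rows: (taxid, parent, rank, name) tuples -> TaxonomyTree."""
    return TaxonomyTree([TaxonNode(*row) for row in rows])


@pytest.fixture(scope="session")
def myco_tree():
    """A family with a species group and strains, shaped like the
    Mycobacteriaceae: two genera, one species group holding a near-identical
    sister pair, and two strains under one species."""
    return build_tree(
        [
            (1, 1, "root", "root"),
            (2, 1, "family", "family_mb"),
            (3, 2, "genus", "genus_m"),
            (4, 3, "species-group", "m_complex"),
            (5, 4, "species", "m_alpha"),
            (6, 4, "species", "m_beta"),
            (7, 3, "species", "m_gamma"),
            (8, 2, "genus", "genus_h"),
            (9, 8, "species", "h_delta"),
            (51, 5, "strain", "m_alpha_str1"),
            (52, 5, "strain", "m_alpha_str2"),
        ]
    )


@pytest.fixture(scope="session")
def myco_parent():
    return {1: 1, 2: 1, 3: 2, 4: 3, 5: 4, 6: 4, 7: 3, 8: 2, 9: 8, 51: 5, 52: 5}


@pytest.fixture(scope="session")
def chain_tree():
    return build_tree(
        [
            (1, 1, "root", "root"),
            (2, 1, "genus", "g"),
            (3, 2, "species", "s"),
        ]
    )


@pytest.fixture(scope="session")
def toy_ab():
    """The two-sibling toy: A='AAACC' and B='AAAGG' under one genus, k=3.

    The shared k-mer AAA maps to the genus; the others are species-unique.
    """
    tree = build_tree(
        [
            (1, 1, "root", "root"),
            (2, 1, "genus", "G"),
            (3, 2, "species", "S1"),
            (4, 2, "species", "S2"),
        ]
    )
    genomes = [
        GenomeRecord.from_sequence(3, "AAACC"),
        GenomeRecord.from_sequence(4, "AAAGG"),
    ]
    index = build_kmer_index(genomes, 3, tree)
    dist = build_distribution(genomes, index, tree, 3)
    return tree, genomes, index, dist
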