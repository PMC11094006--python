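"""Shared fixtures: small planted taxonomies, references and datasets."""

from __future__ import annotations

import numpy as np
import pytest

from thermarch import synthetic as syn
from thermarch.lineage import Lineage


def paired_taxonomy() -> syn.ReferenceTaxonomy:
    """Hand-built taxonomy in which every genus holds two species.

    2 phyla x 2 classes x 2 orders x 2 families x 2 genera x 2 species
    per genus is overkill; this uses 2 phyla, each with one class, two
    orders, one family per order, two genera per family, two species per
    genus = 16 species.
    """
    lineages = []
    sp = 0
    for p in range(2):
        for o in range(2):
            for g in range(2):
                for s in range(2):
                    sp += 1
                    lineages.append(
                        Lineage(
                            (
                                "Archaea",
                                f"Phy{p + 1:03d}",
                                f"Cla{p + 1:03d}",
                                f"Ord{2 * p + o + 1:03d}",
                                f"Fam{2 * p + o + 1:03d}",
                                f"Gen{4 * p + 2 * o + g + 1:03d}",
                                f"Sp{sp:03d}",
                            )
                        )
                    )
    return syn.ReferenceTaxonomy(lineages=tuple(lineages))


@pytest.fixture(scope="session")
def taxonomy_paired() -> syn.ReferenceTaxonomy:
    return paired_taxonomy()


@pytest.fixture(scope="session")
def taxonomy_random() -> syn.ReferenceTaxonomy:
    return syn.make_reference_taxonomy(n_phyla=3, n_species=20, seed=11)


@pytest.fixture(scope="session")
def references_random(taxonomy_random) -> syn.MarkerReferenceSet:
    return syn.synthesize_marker_references(taxonomy_random, gene_length=900, seed=11)


@pytest.fixture(scope="session")
def references_paired(taxonomy_paired) -> syn.MarkerReferenceSet:
    return syn.synthesize_marker_references(taxonomy_paired, gene_length=900, seed=5)


@pytest.fixture(scope="session")
def spring_dataset(taxonomy_random):
    scenario = syn.spring_scenario(
        taxonomy_random, n_acidic=5, n_alkaline=5, seed=7
    )
    return syn.simulate_springs(taxonomy_random, scenario), scenario


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
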