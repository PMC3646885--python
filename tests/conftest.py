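"""Shared fixtures: small synthetic datasets and hand-built alignments."""

from __future__ import annotations

import pytest

from mhcscan.alignment_io import CodonAlignment, GenotypeTable
from mhcscan.synthetic_data import SimulationConfig, simulate_dataset

#: Small generator configuration used by fast unit tests.
SMALL_CONFIG = dict(
    n_codons=40,
    boundary_codon=20,
    n_alleles=12,
    n_individuals=10,
    mutations_per_allele=5.2,
    selected_codons=(3, 9, 17, 25, 33),
)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(SimulationConfig(seed=7, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_dataset_b():
    return simulate_dataset(SimulationConfig(seed=8, **SMALL_CONFIG))


@pytest.fixture()
def tiny_alignment():
    """Four alleles, three codons, hand-checkable variation.

    codon 1: TTT/TTC — one synonymous difference (Phe).
    codon 2: AAA invariant.
    codon 3: GGG/GGC/CGG — recurrent variation, one column with 2 states
             at position 7 and one with 2 states at position 9.
    """
    return CodonAlignment(
        allele_ids=("a1", "a2", "a3", "a4"),
        sequences=(
            "TTTAAAGGG",
            "TTCAAAGGG",
            "TTTAAAGGC",
            "TTTAAACGG",
        ),
        reference_id="a1",
    )


@pytest.fixture()
def tiny_genotypes():
    return GenotypeTable(
        {
            "i1": ("a1", "a2"),
            "i2": ("a1", "a3"),
            "i3": ("a2",),
            "i4": ("a3", "a4"),
            "i5": ("a1", "a4"),
        }
    )
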