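"""Alignment/table I/O, validation, and region bookkeeping."""

import pytest

from mhcscan.alignment_io import (
    AlleleFrequencyTable,
    CodonAlignment,
    GenotypeTable,
    RegionSpec,
    complete_column_mask,
    partition_regions,
    read_codon_alignment,
    read_frequencies,
    read_genotypes,
    ungapped_site_count,
    validate_tables,
    write_codon_alignment,
    write_frequencies,
    write_genotypes,
)
from mhcscan.errors import (
    BoundaryError,
    DuplicateIdError,
    EmptyAlignmentError,
    FrameViolationError,
    FrequencyTableError,
    GenotypeTableError,
    InvalidCharacterError,
    InvalidRegionError,
    UnequalLengthError,
)


def test_alignment_validation_errors():
    with pytest.raises(EmptyAlignmentError):
        CodonAlignment((), ())
    with pytest.raises(DuplicateIdError):
        CodonAlignment(("a", "a"), ("ATG", "ATG"))
    with pytest.raises(UnequalLengthError):
        CodonAlignment(("a", "b"), ("ATG", "ATGATG"))
    with pytest.raises(FrameViolationError):
        CodonAlignment(("a", "b"), ("ATGA", "ATGA"))
    with pytest.raises(InvalidCharacterError):
        CodonAlignment(("a",), ("ATX",))
    with pytest.raises(InvalidCharacterError):
        CodonAlignment(("a",), ("ATG",), reference_id="missing")


def test_alignment_accessors(tiny_alignment):
    assert tiny_alignment.n_sequences == 4
    assert tiny_alignment.length_nt == 9
    assert tiny_alignment.codon_count == 3
    assert tiny_alignment.codon(0, 1) == "TTT"
    assert tiny_alignment.codon(1, 1) == "TTC"
    assert tiny_alignment.total_region() == RegionSpec("total", 1, 3)
    assert tiny_alignment.to_array().shape == (4, 9)


def test_region_spec_geometry():
    r = RegionSpec("alpha1", 1, 91)
    assert r.n_codons == 91
    assert r.n_nt == 273
    assert r.nt_slice == slice(0, 273)
    assert list(r.codon_indices)[:3] == [1, 2, 3]


def test_partition_regions(tiny_alignment):
    a1, a2, total = partition_regions(tiny_alignment, boundary_codon=2)
    assert (a1.start_codon, a1.end_codon) == (1, 2)
    assert (a2.start_codon, a2.end_codon) == (3, 3)
    assert (total.start_codon, total.end_codon) == (1, 3)
    with pytest.raises(BoundaryError):
        partition_regions(tiny_alignment)  # default boundary 91 too large
    with pytest.raises(InvalidRegionError):
        partition_regions(tiny_alignment, boundary_codon=3)


def test_complete_column_mask_and_ungapped_sites():
    aln = CodonAlignment(("a", "b"), ("ATG-CGNTT", "ATGACGATT"))
    region = aln.total_region()
    mask = complete_column_mask(aln, region)
    assert mask.tolist() == [True, True, True, False, True, True, False, True, True]
    assert ungapped_site_count(aln, region) == 7


def test_region_haplotypes(tiny_alignment):
    region = RegionSpec("c1", 1, 1)
    assert tiny_alignment.region_haplotypes(region) == ["TTT", "TTC"]


def test_fasta_round_trip(tmp_path, tiny_alignment):
    path = tmp_path / "aln.fasta"
    write_codon_alignment(tiny_alignment, path)
    back = read_codon_alignment(path, reference_id="a1")
    assert back.allele_ids == tiny_alignment.allele_ids
    assert back.sequences == tiny_alignment.sequences
    assert back.reference_id == "a1"
    with pytest.raises(EmptyAlignmentError):
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        read_codon_alignment(empty)


def test_genotype_round_trip_and_validation(tmp_path, tiny_genotypes):
    path = tmp_path / "geno.tsv"
    write_genotypes(tiny_genotypes, path)
    back = read_genotypes(path)
    assert back.genotypes == tiny_genotypes.genotypes
    assert back.n_individuals == 5
    assert back.carrier_counts()["a1"] == 3
    assert back.distinct_alleles() == {"a1", "a2", "a3", "a4"}

    multi = tmp_path / "multi.tsv"
    multi.write_text("individual\tallele\ni1\ta\ni1\tb\ni1\tc\n")
    with pytest.raises(GenotypeTableError):
        read_genotypes(multi)
    table = read_genotypes(multi, allow_multi=True)
    assert table.alleles_of("i1") == ("a", "b", "c")
    assert table.diploid_subset().n_individuals == 0


def test_frequency_round_trip_and_validation(tmp_path):
    table = AlleleFrequencyTable.from_counts({"a": 3, "b": 1})
    assert table.frequencies["a"] == pytest.approx(0.75)
    path = tmp_path / "freq.tsv"
    write_frequencies(table, path)
    back = read_frequencies(path)
    assert back.frequencies == pytest.approx(table.frequencies)
    assert back.frequency_vector(["b", "a", "c"]).tolist() == pytest.approx([0.25, 0.75, 0.0])

    with pytest.raises(FrequencyTableError):
        AlleleFrequencyTable({"a": 0.5, "b": 0.2})
    with pytest.raises(FrequencyTableError):
        AlleleFrequencyTable.from_counts({"a": -1})
    with pytest.raises(FrequencyTableError):
        AlleleFrequencyTable.from_counts({})


def test_validate_tables(tiny_alignment, tiny_genotypes):
    freqs = AlleleFrequencyTable.from_counts({"a1": 1, "a2": 1, "a3": 1, "a4": 1})
    validate_tables(tiny_alignment, tiny_genotypes, freqs)
    bad_geno = GenotypeTable({"i1": ("a1", "zzz")})
    with pytest.raises(GenotypeTableError):
        validate_tables(tiny_alignment, bad_geno, None)
    bad_freq = AlleleFrequencyTable({"zzz": 1.0})
    with pytest.raises(FrequencyTableError):
        validate_tables(tiny_alignment, None, bad_freq)
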