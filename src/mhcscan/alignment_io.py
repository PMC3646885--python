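"""Codon alignment and population-table I/O.

The central container is :class:`CodonAlignment`: an in-frame nucleotide
alignment of alleles at a single locus, with 1-based reference codon
numbering (codon 1 = the first codon of the alignment, following the
convention that positions are cited against a designated reference allele).
The peptide-binding region of an MHC class I gene splits into the alpha-1
and alpha-2 domains; :func:`partition_regions` produces that partition plus
the full-length region.

Conventions
-----------
* codons and nucleotide columns are numbered 1-based, inclusive;
* ``N`` is treated as missing data: any column containing a gap or an N in
  any sequence is excluded from site-based statistics ("complete-column"
  convention, recorded in output metadata);
* FASTA ids are the description line up to the first whitespace.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
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

VALID_CHARS = frozenset("ACGTN-")

#: Default last codon of the alpha-1 domain (alpha-2 starts at the next codon).
DEFAULT_BOUNDARY_CODON = 91


@dataclass(frozen=True)
class RegionSpec:
    """A contiguous block of codons, 1-based inclusive."""

    name: str
    start_codon: int
    end_codon: int

    @property
    def n_codons(self) -> int:
        return self.end_codon - self.start_codon + 1

    @property
    def n_nt(self) -> int:
        return 3 * self.n_codons

    @property
    def nt_slice(self) -> slice:
        """0-based column slice of this region in the alignment."""
        return slice(3 * (self.start_codon - 1), 3 * self.end_codon)

    @property
    def codon_indices(self) -> range:
        """1-based codon numbers covered by the region."""
        return range(self.start_codon, self.end_codon + 1)


@dataclass(frozen=True)
class CodonAlignment:
    """In-frame aligned allele sequences.

    Parameters
    ----------
    allele_ids
        Unique allele names, in file order.
    sequences
        Aligned nucleotide strings over ``A,C,G,T,N,-``, all the same length,
        length divisible by 3.
    reference_id
        Allele whose translation provides reference amino-acid numbering;
        ``None`` means numbering uses alignment columns directly.
    """

    allele_ids: tuple[str, ...]
    sequences: tuple[str, ...]
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.allele_ids) == 0:
            raise EmptyAlignmentError("alignment contains no records")
        if len(set(self.allele_ids)) != len(self.allele_ids):
            dups = sorted({a for a in self.allele_ids if self.allele_ids.count(a) > 1})
            raise DuplicateIdError(f"duplicate allele ids: {dups}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise UnequalLengthError(f"sequences have differing lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise FrameViolationError(f"alignment length {length} is not divisible by 3")
        for aid, seq in zip(self.allele_ids, self.sequences):
            bad = set(seq) - VALID_CHARS
            if bad:
                raise InvalidCharacterError(f"allele {aid!r} contains invalid characters {sorted(bad)}")
        if self.reference_id is not None and self.reference_id not in self.allele_ids:
            raise InvalidCharacterError(
                f"reference_id {self.reference_id!r} is not among the allele ids"
            )

    @property
    def n_sequences(self) -> int:
        return len(self.allele_ids)

    @property
    def length_nt(self) -> int:
        return len(self.sequences[0])

    @property
    def codon_count(self) -> int:
        return self.length_nt // 3

    def to_array(self) -> np.ndarray:
        """(n_sequences, length_nt) array of single-byte characters."""
        return np.frombuffer("".join(self.sequences).encode(), dtype="S1").reshape(
            self.n_sequences, self.length_nt
        )

    def total_region(self) -> RegionSpec:
        return RegionSpec("total", 1, self.codon_count)

    def codon(self, allele_index: int, codon_number: int) -> str:
        """Codon string of one allele at a 1-based reference codon number."""
        start = 3 * (codon_number - 1)
        return self.sequences[allele_index][start : start + 3]

    def region_haplotypes(self, region: RegionSpec) -> list[str]:
        """Distinct sub-sequences within a region, in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sequences:
            seen.setdefault(s[region.nt_slice], None)
        return list(seen)


@dataclass(frozen=True)
class GenotypeTable:
    """Alleles observed per individual (1 or 2; more only when allowed)."""

    genotypes: Mapping[str, tuple[str, ...]]

    @property
    def individual_ids(self) -> list[str]:
        return list(self.genotypes)

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes)

    def alleles_of(self, individual: str) -> tuple[str, ...]:
        return self.genotypes[individual]

    def distinct_alleles(self) -> set[str]:
        return {a for alleles in self.genotypes.values() for a in alleles}

    def carrier_counts(self) -> dict[str, int]:
        """Number of individuals carrying each allele at least once."""
        counts: dict[str, int] = {}
        for alleles in self.genotypes.values():
            for a in set(alleles):
                counts[a] = counts.get(a, 0) + 1
        return counts

    def diploid_subset(self) -> "GenotypeTable":
        """Drop individuals carrying more than two alleles (anomalies)."""
        kept = {i: g for i, g in self.genotypes.items() if len(g) <= 2}
        return GenotypeTable(kept)


@dataclass(frozen=True)
class AlleleFrequencyTable:
    """Normalized allele frequencies."""

    frequencies: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise FrequencyTableError(f"frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.frequencies.values()):
            raise FrequencyTableError("negative frequency")

    @classmethod
    def from_counts(cls, counts: Mapping[str, float]) -> "AlleleFrequencyTable":
        if any(c < 0 for c in counts.values()):
            raise FrequencyTableError("negative count")
        total = float(sum(counts.values()))
        if total <= 0:
            raise FrequencyTableError("counts sum to zero")
        return cls({a: c / total for a, c in counts.items()})

    def frequency_vector(self, allele_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.frequencies.get(a, 0.0) for a in allele_ids])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_codon_alignment(path: str | Path, reference_id: str | None = None) -> CodonAlignment:
    """Read an in-frame FASTA alignment and validate it.

    Ids are the description line up to the first whitespace; sequences are
    uppercased. Raises the distinct errors documented in :mod:`mhcscan.errors`
    for frame violations, unequal lengths, duplicates and empty files.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyAlignmentError(f"no FASTA records in {path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    return CodonAlignment(ids, seqs, reference_id=reference_id)


def write_codon_alignment(aln: CodonAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=aid, description="")
        for aid, seq in zip(aln.allele_ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def partition_regions(
    aln: CodonAlignment, boundary_codon: int = DEFAULT_BOUNDARY_CODON
) -> list[RegionSpec]:
    """Split into alpha-1 (1..boundary), alpha-2 (boundary+1..end) and total."""
    if boundary_codon < 1 or boundary_codon >= aln.codon_count:
        if boundary_codon == DEFAULT_BOUNDARY_CODON:
            raise BoundaryError(
                f"alignment has {aln.codon_count} codons, too short for the default "
                f"domain boundary at codon {DEFAULT_BOUNDARY_CODON}; pass boundary_codon explicitly"
            )
        raise InvalidRegionError(
            f"boundary codon {boundary_codon} outside 1..{aln.codon_count - 1}"
        )
    return [
        RegionSpec("alpha1", 1, boundary_codon),
        RegionSpec("alpha2", boundary_codon + 1, aln.codon_count),
        RegionSpec("total", 1, aln.codon_count),
    ]


def validate_region(aln: CodonAlignment, region: RegionSpec) -> None:
    if not (1 <= region.start_codon <= region.end_codon <= aln.codon_count):
        raise InvalidRegionError(
            f"region {region.name} ({region.start_codon}-{region.end_codon}) outside "
            f"1..{aln.codon_count}"
        )


def complete_column_mask(aln: CodonAlignment, region: RegionSpec) -> np.ndarray:
    """Boolean mask (region nt columns) of columns free of gaps and Ns."""
    validate_region(aln, region)
    arr = aln.to_array()[:, region.nt_slice]
    return ~np.any((arr == b"-") | (arr == b"N"), axis=0)


def ungapped_site_count(aln: CodonAlignment, region: RegionSpec) -> int:
    """Number of columns in the region with no gap and no N in any sequence."""
    return int(complete_column_mask(aln, region).sum())


def read_genotypes(path: str | Path, allow_multi: bool = False) -> GenotypeTable:
    """Read a two-column TSV (individual, allele) with header.

    Each row records one allele observed in one individual. Individuals with
    more than two distinct alleles raise :class:`GenotypeTableError` unless
    ``allow_multi`` is set (the occasional fish typed with three alleles at a
    nominally diploid locus).
    """
    genotypes: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise GenotypeTableError(f"empty genotype file {path}")
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise GenotypeTableError(f"malformed genotype row {row!r}")
            ind, allele = row[0].strip(), row[1].strip()
            alleles = genotypes.setdefault(ind, [])
            if allele not in alleles:
                alleles.append(allele)
    if not genotypes:
        raise GenotypeTableError(f"no genotype rows in {path}")
    for ind, alleles in genotypes.items():
        if len(alleles) > 2 and not allow_multi:
            raise GenotypeTableError(
                f"individual {ind!r} carries {len(alleles)} alleles; "
                "pass allow_multi=True to accept"
            )
    return GenotypeTable({i: tuple(a) for i, a in genotypes.items()})


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["individual", "allele"])
        for ind, alleles in table.genotypes.items():
            for a in alleles:
                writer.writerow([ind, a])


def read_frequencies(path: str | Path) -> AlleleFrequencyTable:
    """Read a two-column TSV (allele, count-or-frequency) with header; normalize."""
    counts: dict[str, float] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise FrequencyTableError(f"empty frequency file {path}")
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise FrequencyTableError(f"malformed frequency row {row!r}")
            allele = row[0].strip()
            try:
                value = float(row[1])
            except ValueError as exc:
                raise FrequencyTableError(f"non-numeric count for {allele!r}") from exc
            counts[allele] = counts.get(allele, 0.0) + value
    return AlleleFrequencyTable.from_counts(counts)


def write_frequencies(table: AlleleFrequencyTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["allele", "frequency"])
        for allele, freq in table.frequencies.items():
            writer.writerow([allele, repr(freq)])


def validate_tables(
    aln: CodonAlignment,
    genotypes: GenotypeTable | None = None,
    frequencies: AlleleFrequencyTable | None = None,
) -> None:
    """Check that every allele referenced in the tables exists in the alignment."""
    known = set(aln.allele_ids)
    if genotypes is not None:
        unknown = genotypes.distinct_alleles() - known
        if unknown:
            raise GenotypeTableError(f"genotype table references unknown alleles: {sorted(unknown)}")
    if frequencies is not None:
        unknown = set(frequencies.frequencies) - known
        if unknown:
            raise FrequencyTableError(
                f"frequency table references unknown alleles: {sorted(unknown)}"
            )
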