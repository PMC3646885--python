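"""Nei–Gojobori (1986) synonymous/nonsynonymous counting primitives.

Potential sites per codon and pathway-averaged differences per codon pair,
under the standard genetic code. Mutational pathways passing through stop
codons are excluded from the averaging; single-nucleotide changes *to* stop
codons are excluded from the potential-site enumeration. By default sites
are left unrenormalized (s + n < 3 for stop-adjacent codons), matching the
common implementation in descriptive-diversity software; pass
``renormalize=True`` to rescale each codon's sites to total 3.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations, product

from .errors import InvalidCodonError

NUCLEOTIDES = "ACGT"

# Standard genetic code, stop codons mapped to "*".
_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE: dict[str, str] = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))


def translate(codon: str) -> str:
    try:
        return GENETIC_CODE[codon]
    except KeyError:
        raise InvalidCodonError(f"cannot translate {codon!r}") from None


def _check_sense(codon: str) -> None:
    if len(codon) != 3 or any(c not in NUCLEOTIDES for c in codon):
        raise InvalidCodonError(f"invalid codon {codon!r} (gapped or ambiguous)")
    if codon in STOP_CODONS:
        raise InvalidCodonError(f"stop codon {codon!r}")


@lru_cache(maxsize=None)
def codon_sites(codon: str, renormalize: bool = False) -> tuple[float, float]:
    """Potential (synonymous, nonsynonymous) sites of a sense codon.

    Each of the nine single-nucleotide mutations contributes 1/3 of a site
    to the synonymous or nonsynonymous total according to whether it
    preserves the amino acid; mutations to stop codons contribute to
    neither, so s + n may fall below 3 unless ``renormalize`` is set.
    """
    _check_sense(codon)
    aa = GENETIC_CODE[codon]
    s = n = 0.0
    for pos in range(3):
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            if GENETIC_CODE[mutant] == aa:
                s += 1.0 / 3.0
            else:
                n += 1.0 / 3.0
    if renormalize and (s + n) > 0:
        scale = 3.0 / (s + n)
        s, n = s * scale, n * scale
    return s, n


@lru_cache(maxsize=None)
def pair_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons.

    All orderings of the differing positions are enumerated; pathways whose
    intermediate codons are stops are discarded (if every pathway is blocked
    the average falls back to all pathways, preserving sd + nd = Hamming
    distance). Returns (sd, nd).
    """
    _check_sense(codon_a)
    _check_sense(codon_b)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        current = codon_a
        sd = nd = 0.0
        for step, pos in enumerate(order):
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            # intermediates may not be stops; endpoints are known sense codons
            if nxt in STOP_CODONS:
                return None
            if GENETIC_CODE[nxt] == GENETIC_CODE[current]:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return sd, nd

    paths = [walk(order) for order in permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [
            _walk_through_stops(codon_a, codon_b, order) for order in permutations(diff_pos)
        ]
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


def _walk_through_stops(codon_a: str, codon_b: str, order: tuple[int, ...]) -> tuple[float, float]:
    """Pathway counts allowing stop intermediates (fallback only)."""
    current = codon_a
    sd = nd = 0.0
    for pos in order:
        nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
        if GENETIC_CODE[nxt] == GENETIC_CODE[current]:
            sd += 1.0
        else:
            nd += 1.0
        current = nxt
    return sd, nd


def all_sense_pairs():
    """Iterator over all ordered sense-codon pairs (61 x 61)."""
    return product(SENSE_CODONS, SENSE_CODONS)
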