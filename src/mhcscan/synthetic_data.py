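"""Synthetic codon alignments with known selection and recombination structure.

The generator emulates the population structure the analysis pipeline
assumes for a classical MHC class I locus: a handful of deeply diverged
ancestral lineages per domain (alpha-1 and alpha-2), alleles formed as
interdomain lineage combinations (crossovers concentrated at the domain
boundary), occasional intradomain crossovers, per-codon omega controlling
the nonsynonymous/synonymous balance of mutations, and diploid genotypes
drawn under Hardy–Weinberg equilibrium from Dirichlet allele frequencies.

The mutation engine picks single-nucleotide changes with weight 1 for
synonymous and omega[codon] for nonsynonymous candidates (stop-creating
changes excluded outright), so the configured omega is the expected
nonsynonymous/synonymous odds relative to Nei–Gojobori opportunities —
which is what makes parameter recovery by the sitewise scan well defined.

Alleles form a random recursive genealogy: each new allele copies the
full haplotype of a uniformly chosen ancestor (a founder or an earlier
allele) before adding its private substitutions, so mutations accumulate
serially along many short observable branches rather than piling onto a
few deep ones. Recombinant alleles instead graft domain segments from two
ancestors, and only such grafts introduce crossovers — with recombination
rates at zero inheritance is strictly vertical.

Limitations (by design): no indels, no explicit coalescent times, no
trans-species structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import ng86
from .alignment_io import (
    AlleleFrequencyTable,
    CodonAlignment,
    GenotypeTable,
    write_codon_alignment,
    write_frequencies,
    write_genotypes,
)
from .errors import SimulationError

#: Default codons under diversifying selection: 14 in alpha-1 and 6 in
#: alpha-2, at peptide-binding-cleft-like positions.
DEFAULT_SELECTED_CODONS = (
    9, 15, 24, 33, 42, 47, 53, 58, 62, 66, 70, 77, 83, 88,
    94, 96, 113, 130, 156, 170,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults emulate a single-river brown trout sample.

    ``lineage_divergence`` is the expected substitutions/site between a
    domain lineage founder and the ancestral base sequence;
    ``mutations_per_allele`` the expected allele-private substitutions.
    """

    seed: int
    n_codons: int = 184
    boundary_codon: int = 91
    lineages_per_domain: int = 3
    lineage_divergence: float = 0.3
    n_alleles: int = 21
    mutations_per_allele: float = 27.0
    omega_background: float = 0.3
    omega_selected: float = 5.0
    selected_codons: tuple[int, ...] = DEFAULT_SELECTED_CODONS
    recomb_rate_interdomain: float = 0.5
    recomb_rate_intradomain: float = 0.05
    n_individuals: int = 28
    dirichlet_alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.boundary_codon < self.n_codons):
            raise SimulationError("boundary_codon must lie strictly inside the gene")
        for rate in (self.recomb_rate_interdomain, self.recomb_rate_intradomain):
            if not 0.0 <= rate <= 1.0:
                raise SimulationError("recombination rates must be probabilities")
        if self.omega_background <= 0 or self.omega_selected <= 0:
            raise SimulationError("omega values must be positive")
        if any(not 1 <= c <= self.n_codons for c in self.selected_codons):
            raise SimulationError("selected codons outside the gene")

    @property
    def omega_profile(self) -> dict[int, float]:
        profile = {c: self.omega_background for c in range(1, self.n_codons + 1)}
        for c in self.selected_codons:
            profile[c] = self.omega_selected
        return profile

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "selected_codons" in d:
            d["selected_codons"] = tuple(d["selected_codons"])
        return cls(**d)


@dataclass
class Truth:
    """Ground-truth bookkeeping for a generated dataset."""

    lineage_alpha1: dict[str, int] = field(default_factory=dict)
    lineage_alpha2: dict[str, int] = field(default_factory=dict)
    crossovers: dict[str, list[int]] = field(default_factory=dict)  # nt positions after which
    is_interdomain_recombinant: dict[str, bool] = field(default_factory=dict)
    codon_syn_counts: dict[int, int] = field(default_factory=dict)
    codon_nonsyn_counts: dict[int, int] = field(default_factory=dict)
    n_mutations_placed: int = 0

    def record_mutation(self, codon: int, synonymous: bool) -> None:
        key = self.codon_syn_counts if synonymous else self.codon_nonsyn_counts
        key[codon] = key.get(codon, 0) + 1
        self.n_mutations_placed += 1

    def as_json_dict(self) -> dict:
        d = asdict(self)
        d["codon_syn_counts"] = {str(k): v for k, v in self.codon_syn_counts.items()}
        d["codon_nonsyn_counts"] = {str(k): v for k, v in self.codon_nonsyn_counts.items()}
        return d


@dataclass(frozen=True)
class SyntheticDataset:
    config: SimulationConfig
    alignment: CodonAlignment
    frequencies: AlleleFrequencyTable
    genotypes: GenotypeTable
    truth: Truth


# ---------------------------------------------------------------------------
# mutation engine
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _candidates(codon: str) -> tuple[tuple[tuple[int, str, str], ...], tuple[tuple[int, str, str], ...]]:
    """(synonymous, nonsynonymous) single-nt changes of a sense codon,
    stop-creating changes excluded. Entries are (pos, alt_nt, new_codon)."""
    syn, nonsyn = [], []
    aa = ng86.GENETIC_CODE[codon]
    for pos in range(3):
        for alt in ng86.NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in ng86.STOP_CODONS:
                continue
            (syn if ng86.GENETIC_CODE[mutant] == aa else nonsyn).append((pos, alt, mutant))
    return tuple(syn), tuple(nonsyn)


def _apply_mutations(
    codons: list[str],
    n_mutations: int,
    omega: Mapping[int, float],
    codon_offset: int,
    rng: np.random.Generator,
    truth: Truth | None = None,
) -> None:
    """Place n_mutations on a codon list in place.

    Candidate changes are weighted 1 (synonymous) or omega[codon]
    (nonsynonymous); stops can never arise. ``codon_offset`` maps local
    list indices to reference codon numbers.
    """
    for _ in range(n_mutations):
        weights = np.empty(len(codons))
        for i, c in enumerate(codons):
            syn, nonsyn = _candidates(c)
            weights[i] = len(syn) + len(nonsyn) * omega[codon_offset + i]
        total = weights.sum()
        if total <= 0:
            raise SimulationError("no mutable positions available")
        i = int(rng.choice(len(codons), p=weights / total))
        syn, nonsyn = _candidates(codons[i])
        w_syn = float(len(syn))
        w_non = len(nonsyn) * omega[codon_offset + i]
        synonymous = rng.random() < w_syn / (w_syn + w_non)
        pool = syn if synonymous else nonsyn
        _, _, new_codon = pool[int(rng.integers(len(pool)))]
        codons[i] = new_codon
        if truth is not None:
            truth.record_mutation(codon_offset + i, synonymous)


def _random_sense_sequence(n_codons: int, rng: np.random.Generator) -> list[str]:
    idx = rng.integers(0, len(ng86.SENSE_CODONS), size=n_codons)
    return [ng86.SENSE_CODONS[i] for i in idx]


# ---------------------------------------------------------------------------
# generator stages
# ---------------------------------------------------------------------------

def simulate_founders(
    config: SimulationConfig, rng: np.random.Generator, truth: Truth | None = None
) -> tuple[list[list[str]], list[list[str]]]:
    """Ancestral lineage founders per domain.

    Returns (alpha1_founders, alpha2_founders), each a list of codon lists.
    Every founder derives from a common random in-frame, stop-free base
    sequence by Poisson(divergence * domain nt length) substitutions placed
    by the omega-weighted mutation engine.
    """
    base = _random_sense_sequence(config.n_codons, rng)
    b = config.boundary_codon
    omega = config.omega_profile
    founders_a1: list[list[str]] = []
    founders_a2: list[list[str]] = []
    for domain, (start, stop) in (("a1", (0, b)), ("a2", (b, config.n_codons))):
        length_nt = 3 * (stop - start)
        for _ in range(config.lineages_per_domain):
            founder = base[start:stop].copy()
            n_mut = int(rng.poisson(config.lineage_divergence * length_nt))
            _apply_mutations(founder, n_mut, omega, start + 1, rng, truth)
            (founders_a1 if domain == "a1" else founders_a2).append(founder)
    return founders_a1, founders_a2


def simulate_alleles(
    config: SimulationConfig,
    founders: tuple[list[list[str]], list[list[str]]],
    rng: np.random.Generator,
    truth: Truth,
    max_retries: int = 50,
) -> CodonAlignment:
    """Build n_alleles distinct alleles from the lineage founders.

    Each allele descends from the growing set of ancestors (the lineage
    founders plus every allele generated so far). With probability
    ``1 - recomb_rate_interdomain`` it copies one ancestor's full haplotype
    (inheriting that ancestor's lineage labels and crossover history), so
    each lineage grows as a random recursive genealogy; otherwise it is an
    interdomain recombinant grafting the alpha-1 half of one ancestor onto
    the alpha-2 half of another from a different lineage, recorded as a
    crossover at the domain boundary. The allele optionally receives one
    intradomain crossover to a different-lineage ancestor's domain tail,
    then accumulates Poisson(mutations_per_allele) private substitutions.
    Duplicate alleles are regenerated up to ``max_retries``.
    """
    founders_a1, founders_a2 = founders
    n_lin = config.lineages_per_domain
    b = config.boundary_codon
    omega = config.omega_profile
    boundary_nt = 3 * b
    # ancestor records: (codons, lin1, lin2, crossovers, is_recombinant)
    ancestors: list[tuple[list[str], int, int, list[int], bool]] = [
        (founders_a1[l] + founders_a2[l], l, l, [], False) for l in range(n_lin)
    ]

    def pick(predicate) -> tuple[list[str], int, int, list[int], bool]:
        pool = [rec for rec in ancestors if predicate(rec)]
        return pool[int(rng.integers(len(pool)))]

    ids: list[str] = []
    seqs: list[str] = []
    seen: set[str] = set()
    for a in range(config.n_alleles):
        name = f"allele_{a + 1:03d}"
        for attempt in range(max_retries):
            shuffled = n_lin > 1 and rng.random() < config.recomb_rate_interdomain
            if shuffled:
                head = pick(lambda r: True)
                lin1 = head[1]
                tail = pick(lambda r: r[2] != lin1)
                lin2 = tail[2]
                codons = head[0][:b] + tail[0][b:]
                crossovers = (
                    [x for x in head[3] if x < boundary_nt]
                    + [boundary_nt]
                    + [x for x in tail[3] if x > boundary_nt]
                )
            else:
                parent = pick(lambda r: True)
                codons, lin1, lin2, crossovers, _ = parent
                codons = list(codons)
                crossovers = list(crossovers)

            if n_lin > 1 and rng.random() < config.recomb_rate_intradomain:
                # splice the tail of one domain from a different lineage
                domain = int(rng.integers(2))
                if domain == 0:
                    donor = pick(lambda r: r[1] != lin1)
                    cut = int(rng.integers(1, b))  # after codon `cut`
                    codons = codons[:cut] + donor[0][cut:b] + codons[b:]
                else:
                    donor = pick(lambda r: r[2] != lin2)
                    cut = int(rng.integers(b + 1, config.n_codons))
                    codons = codons[:cut] + donor[0][cut:]
                crossovers.append(3 * cut)

            codons = list(codons)
            n_mut = int(rng.poisson(config.mutations_per_allele))
            # record truth only for the accepted attempt
            trial_truth = Truth()
            _apply_mutations(codons, n_mut, omega, 1, rng, trial_truth)
            seq = "".join(codons)
            if seq not in seen:
                seen.add(seq)
                ids.append(name)
                seqs.append(seq)
                crossovers = sorted(set(crossovers))
                is_recomb = shuffled or any(x == boundary_nt for x in crossovers)
                ancestors.append((codons, lin1, lin2, crossovers, is_recomb))
                truth.lineage_alpha1[name] = lin1
                truth.lineage_alpha2[name] = lin2
                truth.crossovers[name] = crossovers
                truth.is_interdomain_recombinant[name] = is_recomb
                for codon, k in trial_truth.codon_syn_counts.items():
                    for _ in range(k):
                        truth.record_mutation(codon, True)
                for codon, k in trial_truth.codon_nonsyn_counts.items():
                    for _ in range(k):
                        truth.record_mutation(codon, False)
                break
        else:
            raise SimulationError(
                f"could not generate {config.n_alleles} distinct alleles "
                f"(stuck at {len(seqs)})"
            )
    return CodonAlignment(tuple(ids), tuple(seqs), reference_id=ids[0])


def sample_population(
    alignment: CodonAlignment,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[AlleleFrequencyTable, GenotypeTable]:
    """Dirichlet allele frequencies + HWE diploid genotypes.

    Each individual draws two alleles i.i.d. from the frequencies; the
    genotype table records the one or two distinct alleles observed.
    """
    k = alignment.n_sequences
    if np.isinf(config.dirichlet_alpha):
        freqs = np.full(k, 1.0 / k)
    else:
        freqs = rng.dirichlet(np.full(k, config.dirichlet_alpha))
        freqs = freqs / freqs.sum()
    table = AlleleFrequencyTable(
        {aid: float(f) for aid, f in zip(alignment.allele_ids, freqs)}
    )
    genotypes: dict[str, tuple[str, ...]] = {}
    for i in range(config.n_individuals):
        pair = rng.choice(k, size=2, p=freqs)
        alleles = {alignment.allele_ids[int(pair[0])], alignment.allele_ids[int(pair[1])]}
        genotypes[f"ind_{i + 1:03d}"] = tuple(sorted(alleles))
    return table, GenotypeTable(genotypes)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all stages under a single seeded generator."""
    rng = np.random.default_rng(config.seed)
    truth = Truth()
    founders = simulate_founders(config, rng, truth)
    alignment = simulate_alleles(config, founders, rng, truth)
    frequencies, genotypes = sample_population(alignment, config, rng)
    _assert_no_stops(alignment)
    return SyntheticDataset(config, alignment, frequencies, genotypes, truth)


def _assert_no_stops(aln: CodonAlignment) -> None:
    for idx in range(aln.n_sequences):
        for c in range(1, aln.codon_count + 1):
            if aln.codon(idx, c) in ng86.STOP_CODONS:
                raise SimulationError("stop codon generated (internal error)")


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write alignment.fasta, genotypes.tsv, frequencies.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": out / "alignment.fasta",
        "genotypes": out / "genotypes.tsv",
        "frequencies": out / "frequencies.tsv",
        "truth": out / "truth.json",
        "config": out / "config.json",
    }
    write_codon_alignment(dataset.alignment, paths["alignment"])
    write_genotypes(dataset.genotypes, paths["genotypes"])
    write_frequencies(dataset.frequencies, paths["frequencies"])
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth.as_json_dict(), fh, indent=1, sort_keys=True)
    with open(paths["config"], "w") as fh:
        json.dump(asdict(dataset.config), fh, indent=1, sort_keys=True)
    return paths
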