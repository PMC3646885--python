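"""Descriptive diversity statistics for codon alignments.

Reproduces the classical population-summary layout for an allele alignment:
haplotype counts, polymorphic sites S, total mutations eta, average pairwise
differences k, nucleotide diversity pi, Watterson's theta, effective
population size, Nei–Gojobori synonymous/nonsynonymous diversity (dS, dN,
dN/dS), and rarefaction allelic richness from genotype tables.

Denominator conventions (each recorded in the output metadata):

* percent polymorphic sites uses the full region length L (gap columns
  included);
* pi uses the number of complete (gap/N-free) sites;
* Ne = theta_per_seq / (4 mu L) uses the full region length L.

Pairwise statistics are computed over *distinct* haplotypes of the region
by default (each unique sequence counted once); a frequency-weighted
variant is available where noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from . import ng86
from .alignment_io import (
    CodonAlignment,
    GenotypeTable,
    RegionSpec,
    complete_column_mask,
    ungapped_site_count,
    validate_region,
)
from .errors import InsufficientDataError, InvalidRegionError

#: Per-site per-sequence mutation rate used for Ne throughout the salmonid analyses.
DEFAULT_MU = 1.1e-8


# ---------------------------------------------------------------------------
# site counts
# ---------------------------------------------------------------------------

def polymorphic_and_mutations(aln: CodonAlignment, region: RegionSpec) -> tuple[int, int]:
    """(S, eta): polymorphic complete columns and total mutations.

    S counts complete columns with >= 2 distinct nucleotides; eta sums
    (distinct nucleotides - 1) over complete columns, so recurrent mutation
    at a column inflates eta but not S.
    """
    mask = complete_column_mask(aln, region)
    arr = aln.to_array()[:, region.nt_slice][:, mask]
    s = eta = 0
    for col in arr.T:
        k = len(np.unique(col))
        if k > 1:
            s += 1
            eta += k - 1
    return s, eta


def avg_pairwise_diff(
    aln: CodonAlignment, region: RegionSpec, unique: bool = True
) -> float:
    """Mean pairwise nucleotide differences k over complete columns.

    With ``unique=True`` (default) each distinct region haplotype enters
    once, matching analyses run on unique alleles; with ``unique=False``
    every sequence row is used.
    """
    mask = complete_column_mask(aln, region)
    arr = aln.to_array()[:, region.nt_slice][:, mask]
    if unique:
        arr = np.unique(arr, axis=0)
    n = arr.shape[0]
    if n < 2:
        raise InsufficientDataError("avg_pairwise_diff requires >= 2 (distinct) sequences")
    total = 0
    for i, j in combinations(range(n), 2):
        total += int(np.sum(arr[i] != arr[j]))
    return total / (n * (n - 1) / 2)


def pi(aln: CodonAlignment, region: RegionSpec, unique: bool = True) -> float:
    """Nucleotide diversity: avg pairwise differences per complete site."""
    sites = ungapped_site_count(aln, region)
    if sites == 0:
        raise InvalidRegionError(f"region {region.name} has zero complete sites")
    return avg_pairwise_diff(aln, region, unique=unique) / sites


def watterson_theta(s: int, n: int) -> float:
    """Watterson's theta per sequence: S over the harmonic number a_n."""
    if n < 2:
        raise InsufficientDataError("watterson_theta requires n >= 2")
    if s < 0:
        raise ValueError("S must be non-negative")
    a_n = sum(1.0 / i for i in range(1, n))
    return s / a_n


def effective_size(theta_per_seq: float, length_nt: int, mu: float = DEFAULT_MU) -> float:
    """Ne = theta / (4 mu L), with L the full sequence length in nt."""
    if theta_per_seq <= 0 or length_nt <= 0 or mu <= 0:
        raise ValueError("effective_size requires positive theta, L and mu")
    return theta_per_seq / (4.0 * mu * length_nt)


# ---------------------------------------------------------------------------
# synonymous / nonsynonymous diversity
# ---------------------------------------------------------------------------

def jukes_cantor(p: float) -> float:
    """JC69 distance correction d = -(3/4) ln(1 - 4p/3)."""
    if p >= 0.75:
        raise ValueError(f"proportion {p} >= 3/4: Jukes-Cantor correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _pair_syn_nonsyn(seq_a: str, seq_b: str, region: RegionSpec) -> tuple[float, float, float, float]:
    """(sd, nd, s_sites, n_sites) for one sequence pair, pairwise codon deletion."""
    sd = nd = s_sites = n_sites = 0.0
    for c in region.codon_indices:
        start = 3 * (c - 1)
        ca, cb = seq_a[start : start + 3], seq_b[start : start + 3]
        if set(ca + cb) - set(ng86.NUCLEOTIDES):
            continue  # gap or N in either member: skip this codon for this pair
        if ca in ng86.STOP_CODONS or cb in ng86.STOP_CODONS:
            continue
        d_s, d_n = ng86.pair_diffs(ca, cb)
        sd += d_s
        nd += d_n
        sa, na = ng86.codon_sites(ca)
        sb, nb = ng86.codon_sites(cb)
        s_sites += 0.5 * (sa + sb)
        n_sites += 0.5 * (na + nb)
    return sd, nd, s_sites, n_sites


def syn_nonsyn_diversity(
    aln: CodonAlignment,
    region: RegionSpec,
    jc: bool = False,
    unique: bool = True,
) -> tuple[float, float, float]:
    """(dS, dN, dN/dS) by Nei–Gojobori counting, averaged over sequence pairs.

    Per pair: pS = sum sd / sum syn sites, pN = sum nd / sum nonsyn sites over
    ungapped codons (pairwise deletion); optional per-pair Jukes–Cantor
    correction. dS and dN are means over pairs; pairs where the correction is
    undefined (pS or pN >= 3/4) are dropped with a count kept internally.
    Returns NaN for the ratio when dS == 0.
    """
    validate_region(aln, region)
    seqs = aln.region_haplotypes(region) if unique else [s[region.nt_slice] for s in aln.sequences]
    # re-anchor region to the extracted sub-sequences
    sub_region = RegionSpec(region.name, 1, region.n_codons)
    if len(seqs) < 2:
        raise InsufficientDataError("syn_nonsyn_diversity requires >= 2 sequences")
    ps_list: list[float] = []
    pn_list: list[float] = []
    for a, b in combinations(seqs, 2):
        sd, nd, s_sites, n_sites = _pair_syn_nonsyn(a, b, sub_region)
        if s_sites == 0 or n_sites == 0:
            continue
        p_s, p_n = sd / s_sites, nd / n_sites
        if jc:
            if p_s >= 0.75 or p_n >= 0.75:
                continue  # correction undefined; drop pair
            p_s, p_n = jukes_cantor(p_s), jukes_cantor(p_n)
        ps_list.append(p_s)
        pn_list.append(p_n)
    if not ps_list:
        raise InsufficientDataError("no usable sequence pairs for dS/dN")
    d_s = float(np.mean(ps_list))
    d_n = float(np.mean(pn_list))
    ratio = d_n / d_s if d_s > 0 else float("nan")
    return d_s, d_n, ratio


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversitySummary:
    """One region's row-block of the descriptive-statistics table."""

    region: str
    n_sequences: int
    n_haplotypes: int
    seq_length_nt: int
    ungapped_sites: int
    polymorphic_sites: int
    pct_polymorphic: float
    total_mutations: int
    avg_pairwise_diff: float
    pi: float
    theta_per_seq: float
    ne: float
    ds: float
    dn: float
    dnds: float

    def as_dict(self) -> dict:
        return asdict(self)


def summarize_region(
    aln: CodonAlignment,
    region: RegionSpec,
    mu: float = DEFAULT_MU,
    jc: bool = False,
    theta_n: int | None = None,
) -> DiversitySummary:
    """All descriptive statistics for one region.

    ``theta_n`` overrides the sample size used for Watterson's theta
    (defaults to the number of sequences in the alignment).
    """
    s, eta = polymorphic_and_mutations(aln, region)
    sites = ungapped_site_count(aln, region)
    k = avg_pairwise_diff(aln, region)
    n = theta_n if theta_n is not None else aln.n_sequences
    theta = watterson_theta(s, n)
    d_s, d_n, ratio = syn_nonsyn_diversity(aln, region, jc=jc)
    return DiversitySummary(
        region=region.name,
        n_sequences=aln.n_sequences,
        n_haplotypes=len(aln.region_haplotypes(region)),
        seq_length_nt=region.n_nt,
        ungapped_sites=sites,
        polymorphic_sites=s,
        pct_polymorphic=100.0 * s / region.n_nt,
        total_mutations=eta,
        avg_pairwise_diff=k,
        pi=k / sites if sites else float("nan"),
        theta_per_seq=theta,
        ne=effective_size(theta, region.n_nt, mu) if theta > 0 else float("nan"),
        ds=d_s,
        dn=d_n,
        dnds=ratio,
    )


#: Row order of the emitted table, mirroring the conventional layout.
TABLE_ROWS = [
    ("Haplotypes", "n_haplotypes"),
    ("Sequence length", "seq_length_nt"),
    ("Sites (excluding gaps)", "ungapped_sites"),
    ("Polymorphic sites", "polymorphic_sites"),
    ("% Polymorphic sites", "pct_polymorphic"),
    ("Total mutations", "total_mutations"),
    ("Nucleotide diversity (pi)", "pi"),
    ("Theta per sequence", "theta_per_seq"),
    ("Ne", "ne"),
    ("Average nt differences", "avg_pairwise_diff"),
    ("Synonymous diversity (dS)", "ds"),
    ("Non-synonymous diversity (dN)", "dn"),
    ("dN/dS", "dnds"),
]


def diversity_table(
    aln: CodonAlignment,
    regions: Sequence[RegionSpec],
    mu: float = DEFAULT_MU,
    jc: bool = False,
) -> pd.DataFrame:
    """Statistics for several regions as a table (rows = statistics)."""
    summaries = {r.name: summarize_region(aln, r, mu=mu, jc=jc) for r in regions}
    data = {
        name: [getattr(summaries[rname], attr) for _, attr in TABLE_ROWS]
        for name, rname in ((r.name, r.name) for r in regions)
    }
    return pd.DataFrame(data, index=[label for label, _ in TABLE_ROWS])


# ---------------------------------------------------------------------------
# rarefaction allelic richness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RarefactionResult:
    sample_size: int
    replicates: int
    mean_richness: float
    sd_richness: float
    exact_expectation: float


def rarefaction_exact(genotypes: GenotypeTable, m: int) -> float:
    """Closed-form expected number of distinct alleles among m individuals.

    E[A_m] = sum over alleles a of 1 - C(N - c_a, m) / C(N, m), where c_a is
    the number of individuals carrying a.
    """
    n = genotypes.n_individuals
    if m > n:
        raise InsufficientDataError(f"m={m} exceeds {n} individuals")
    denom = math.comb(n, m)
    total = 0.0
    for c in genotypes.carrier_counts().values():
        total += 1.0 - math.comb(n - c, m) / denom
    return total


def rarefaction_richness(
    genotypes: GenotypeTable,
    m: int,
    replicates: int,
    seed: int | np.random.Generator,
) -> RarefactionResult:
    """Monte-Carlo allelic richness: distinct alleles in m individuals
    sampled without replacement, averaged over replicates, with the exact
    hypergeometric expectation alongside."""
    n = genotypes.n_individuals
    if m > n:
        raise InsufficientDataError(f"m={m} exceeds {n} individuals")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    alleles = sorted(genotypes.distinct_alleles())
    a_index = {a: i for i, a in enumerate(alleles)}
    incidence = np.zeros((n, len(alleles)), dtype=bool)
    for row, ind in enumerate(genotypes.individual_ids):
        for a in genotypes.alleles_of(ind):
            incidence[row, a_index[a]] = True

    richness = np.empty(replicates, dtype=np.int64)
    # batch to bound memory at large replicate counts
    batch = 20000
    done = 0
    while done < replicates:
        b = min(batch, replicates - done)
        # m distinct individuals per replicate via random-key argpartition
        keys = rng.random((b, n))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        present = incidence[idx].any(axis=1)  # (b, m, A) -> (b, A)
        richness[done : done + b] = present.sum(axis=1)
        done += b
    return RarefactionResult(
        sample_size=m,
        replicates=replicates,
        mean_richness=float(richness.mean()),
        sd_richness=float(richness.std(ddof=1)) if replicates > 1 else 0.0,
        exact_expectation=rarefaction_exact(genotypes, m),
    )
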