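"""Per-codon diversifying-selection scan.

A deliberately simple Bayesian model of the per-codon nonsynonymous /
synonymous balance, designed so that downstream consumers (site-tier
classification and cross-population posterior comparison) receive proper
posterior samples of omega = dN/dS per codon.

The module has two layers:

Descriptive layer
    :func:`codon_diff_counts` accumulates pathway-averaged synonymous and
    nonsynonymous differences over all unordered allele pairs with
    Hardy-Weinberg pair weights 2 f_i f_j, normalized to per-pair means,
    alongside Nei-Gojobori potential-site counts. :func:`omega_posterior`
    turns such counts into a conjugate Beta posterior on the probability b
    that a difference is nonsynonymous, with
    omega = b / (1 - b) * (s_sites / n_sites).
    These are reported per codon but carry limited evidence: a normalized
    pairwise mean never exceeds the 3 nt of a codon regardless of how many
    alleles were sampled, so the Beta posterior stays prior-dominated.

Inference layer (what the model fits)
    :func:`codon_event_counts` estimates the number of distinct synonymous
    and nonsynonymous substitution events per codon by Fitch parsimony on
    per-domain guide trees (UPGMA on nucleotide Hamming distances; one tree
    per domain so that interdomain recombinants do not distort either
    genealogy). Multi-nucleotide changes on a tree edge are classified by
    the Nei-Gojobori pathway average, excluding paths through stop codons.

    The scan then assumes a site-invariant synonymous substitution rate --
    the standard identifying assumption of sitewise selection models --
    estimated by pooling synonymous events over all codons:

        lambda | data ~ Gamma(c0 + sum_c Sd_c,  rate = sum_c s_sites_c).

    Conditional on lambda, nonsynonymous events at codon c are modelled as
    Nd_c ~ Poisson(omega_c * lambda * n_sites_c) with a proper unit-mean
    prior omega_c ~ Gamma(a0, rate a0), giving

        omega_c | Nd_c, lambda ~ Gamma(a0 + Nd_c, rate a0 + lambda * n_sites_c).

    Posterior draws of omega_c mix over the lambda posterior, propagating
    the (small) pooled-rate uncertainty. P(omega > 1) is computed
    semi-analytically as the lambda-averaged Gamma survival at 1, and the
    retained Monte-Carlo draws feed HPD intervals and cross-population
    comparisons. With no events anywhere the posterior reverts toward the
    unit-mean prior (P(omega > 1) ~ 0.32 at a0 = 0.5), so an uninformative
    codon can never reach a support tier.

Regional summaries average the per-codon posterior medians, which are
robust to the heavy right tail of low-count codons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.special import gammaincc

from . import ng86
from .alignment_io import (
    DEFAULT_BOUNDARY_CODON,
    AlleleFrequencyTable,
    CodonAlignment,
    RegionSpec,
    partition_regions,
)
from .errors import InsufficientDataError, InvalidCodonError
from .posterior_compare import hpd_interval

TIER_THRESHOLDS = (0.95, 0.99, 0.999)


@dataclass(frozen=True)
class CodonCounts:
    """Frequency-weighted pairwise difference counts at one codon.

    ``nd``/``sd`` are normalized per-pair pathway-averaged means (bounded by
    the 3 nt of a codon); ``n_sites``/``s_sites`` the frequency-weighted
    Nei-Gojobori potential sites.
    """

    codon: int
    nd: float
    sd: float
    n_sites: float
    s_sites: float
    pairs_used: int
    n_alleles: int


@dataclass(frozen=True)
class CodonEvents:
    """Parsimony-estimated substitution events at one codon.

    ``nd``/``sd`` are minimum-change event counts from Fitch parsimony on
    the domain guide tree (pathway-averaged for multi-nt edge changes);
    ``n_sites``/``s_sites`` unweighted mean potential sites over the
    alleles observed at the codon.
    """

    codon: int
    nd: float
    sd: float
    n_sites: float
    s_sites: float
    n_changes: int
    n_alleles: int


def codon_diff_counts(
    aln: CodonAlignment,
    frequencies: AlleleFrequencyTable | None,
    codon: int,
) -> CodonCounts:
    """Pathway-averaged pairwise difference counts at one codon (1-based).

    Pairs where either member is gapped/ambiguous at the codon are skipped;
    a codon observed in fewer than two alleles raises
    :class:`InsufficientDataError`. Uniform weights are used when no
    frequency table is supplied.
    """
    codons: list[str] = []
    weights: list[float] = []
    for idx, allele in enumerate(aln.allele_ids):
        c = aln.codon(idx, codon)
        if set(c) - set(ng86.NUCLEOTIDES) or c in ng86.STOP_CODONS:
            continue
        codons.append(c)
        weights.append(
            1.0 if frequencies is None else frequencies.frequencies.get(allele, 0.0)
        )
    w = np.array(weights, dtype=float)
    usable = w > 0 if frequencies is not None else np.ones(len(codons), bool)
    codons = [c for c, u in zip(codons, usable) if u]
    w = w[usable]
    k = len(codons)
    if k < 2:
        raise InsufficientDataError(f"codon {codon} observed in fewer than 2 alleles")
    w = w / w.sum()

    sum_w = sum_nd = sum_sd = 0.0
    pairs_used = 0
    for i, j in combinations(range(k), 2):
        pw = 2.0 * w[i] * w[j]
        if pw == 0.0:
            continue
        sd_ij, nd_ij = ng86.pair_diffs(codons[i], codons[j])
        sum_w += pw
        sum_nd += pw * nd_ij
        sum_sd += pw * sd_ij
        pairs_used += 1
    mean_nd = sum_nd / sum_w if sum_w > 0 else 0.0
    mean_sd = sum_sd / sum_w if sum_w > 0 else 0.0

    sites = np.array([ng86.codon_sites(c) for c in codons])  # (k, 2) = (s, n)
    s_sites = float(w @ sites[:, 0])
    n_sites = float(w @ sites[:, 1])

    return CodonCounts(
        codon=codon,
        nd=mean_nd,
        sd=mean_sd,
        n_sites=n_sites,
        s_sites=s_sites,
        pairs_used=pairs_used,
        n_alleles=k,
    )


# ---------------------------------------------------------------------------
# parsimony event counting
# ---------------------------------------------------------------------------

def _guide_tree(seqs: Sequence[str]):
    """UPGMA guide tree (scipy ClusterNode) from nucleotide Hamming distances."""
    if len(seqs) < 2:
        raise InsufficientDataError("guide tree needs at least 2 sequences")
    arr = (
        np.frombuffer("".join(seqs).encode(), dtype="S1")
        .reshape(len(seqs), -1)
        .view(np.uint8)
    )
    return hierarchy.to_tree(hierarchy.average(pdist(arr, metric="hamming")))


def _fitch_changes(tree, states: Sequence[str | None]) -> list[tuple[str, str]]:
    """Fitch parsimony (parent, child) state changes on a binary guide tree.

    ``states[i]`` is the codon of leaf i, or None for missing data (treated
    as compatible with any state; never contributes a change).
    """
    changes: list[tuple[str, str]] = []

    def down(node):
        if node.is_leaf():
            s = states[node.id]
            node._set = None if s is None else {s}
        else:
            left, right = down(node.left), down(node.right)
            if left is None:
                node._set = right
            elif right is None:
                node._set = left
            else:
                node._set = (left & right) or (left | right)
        return node._set

    def up(node, parent_state):
        if node._set is None:
            s = parent_state
        elif node.is_leaf():
            s = states[node.id]
        else:
            s = parent_state if parent_state in node._set else min(node._set)
        if parent_state is not None and s is not None and s != parent_state:
            changes.append((parent_state, s))
        if not node.is_leaf():
            up(node.left, s)
            up(node.right, s)

    root_set = down(tree)
    if root_set is None:
        return []
    root_state = min(root_set)
    up(tree.left, root_state)
    up(tree.right, root_state)
    return changes


def codon_event_counts(
    aln: CodonAlignment,
    boundary_codon: int | None = DEFAULT_BOUNDARY_CODON,
) -> dict[int, CodonEvents]:
    """Per-codon substitution events via Fitch parsimony on domain guide trees.

    One guide tree is built per domain (split after ``boundary_codon``;
    a single tree when the boundary is None or outside the alignment), so
    interdomain recombinants cannot distort either genealogy. Codons with
    fewer than two unambiguous states are omitted from the result.
    """
    n_codons = aln.codon_count
    if boundary_codon is not None and 0 < boundary_codon < n_codons:
        cut = 3 * boundary_codon
        trees = [
            (_guide_tree([s[:cut] for s in aln.sequences]), range(1, boundary_codon + 1)),
            (_guide_tree([s[cut:] for s in aln.sequences]), range(boundary_codon + 1, n_codons + 1)),
        ]
    else:
        trees = [(_guide_tree(aln.sequences), range(1, n_codons + 1))]

    out: dict[int, CodonEvents] = {}
    for tree, codon_range in trees:
        for codon in codon_range:
            states: list[str | None] = []
            valid: list[str] = []
            for idx in range(aln.n_sequences):
                c = aln.codon(idx, codon)
                if set(c) - set(ng86.NUCLEOTIDES) or c in ng86.STOP_CODONS:
                    states.append(None)
                else:
                    states.append(c)
                    valid.append(c)
            if len(valid) < 2:
                continue
            nd = sd = 0.0
            changes = _fitch_changes(tree, states)
            for a, b in changes:
                sd_ab, nd_ab = ng86.pair_diffs(a, b)
                sd += sd_ab
                nd += nd_ab
            sites = np.array([ng86.codon_sites(c) for c in valid])
            out[codon] = CodonEvents(
                codon=codon,
                nd=nd,
                sd=sd,
                n_sites=float(sites[:, 1].mean()),
                s_sites=float(sites[:, 0].mean()),
                n_changes=len(changes),
                n_alleles=len(valid),
            )
    return out


# ---------------------------------------------------------------------------
# posteriors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OmegaPosterior:
    """Posterior summary for one codon."""

    codon: int
    omega_hat: float
    omega_mean: float
    omega_median: float
    hpd_lo: float
    hpd_hi: float
    p_gt1: float
    tier: str
    prior_only: bool
    samples: np.ndarray


def omega_posterior(
    counts: CodonCounts,
    prior_a: float = 0.5,
    prior_b: float = 0.5,
    n_samples: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> OmegaPosterior:
    """Conjugate Beta posterior of omega from pairwise difference counts.

    b | data ~ Beta(prior_a + nd, prior_b + sd); omega = b/(1-b) scaled by
    the potential-site ratio s_sites/n_sites, so omega = 1 corresponds to
    equal per-site rates. Summaries come from seeded Monte-Carlo draws.
    The posterior mean of omega does not exist when sd + prior_b <= 1; the
    reported sample mean should be read with that caveat (the median and
    HPD are robust).
    """
    if counts.n_sites <= 0 or counts.s_sites <= 0:
        raise InvalidCodonError(f"codon {counts.codon} has zero potential sites")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = rng.beta(prior_a + counts.nd, prior_b + counts.sd, size=n_samples)
    ratio = counts.s_sites / counts.n_sites
    omega = b / (1.0 - b) * ratio
    p_gt1 = float(np.mean(omega > 1.0))
    lo, hi = hpd_interval(omega, 0.95)
    if counts.sd > 0:
        hat = (counts.nd / counts.n_sites) / (counts.sd / counts.s_sites)
    elif counts.nd > 0:
        hat = float("inf")
    else:
        hat = float("nan")
    return OmegaPosterior(
        codon=counts.codon,
        omega_hat=hat,
        omega_mean=float(omega.mean()),
        omega_median=float(np.median(omega)),
        hpd_lo=float(lo),
        hpd_hi=float(hi),
        p_gt1=p_gt1,
        tier=classify_probability(p_gt1),
        prior_only=(counts.nd == 0.0 and counts.sd == 0.0),
        samples=omega,
    )


def event_omega_posterior(
    events: CodonEvents,
    lambda_draws: np.ndarray,
    lambda_hat: float,
    prior_a: float = 0.5,
    n_samples: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> OmegaPosterior:
    """Gamma-Poisson posterior of omega from event counts and a pooled rate.

    omega | Nd, lambda ~ Gamma(prior_a + Nd, rate prior_a + lambda*n_sites),
    mixed over ``lambda_draws`` from the pooled synonymous-rate posterior.
    ``lambda_draws`` must have length >= n_samples.
    """
    if events.n_sites <= 0:
        raise InvalidCodonError(f"codon {events.codon} has zero nonsynonymous sites")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = np.asarray(lambda_draws, dtype=float)[:n_samples]
    rate = prior_a + lam * events.n_sites
    omega = rng.gamma(prior_a + events.nd, 1.0, size=lam.size) / rate
    # P(omega > 1 | lambda) = Q(a0 + Nd, a0 + lambda * n); average over lambda
    p_gt1 = float(np.mean(gammaincc(prior_a + events.nd, rate)))
    lo, hi = hpd_interval(omega, 0.95)
    hat = (events.nd / events.n_sites) / lambda_hat if lambda_hat > 0 else float("nan")
    return OmegaPosterior(
        codon=events.codon,
        omega_hat=hat,
        omega_mean=float(omega.mean()),
        omega_median=float(np.median(omega)),
        hpd_lo=float(lo),
        hpd_hi=float(hi),
        p_gt1=p_gt1,
        tier=classify_probability(p_gt1),
        prior_only=(events.nd == 0.0 and events.sd == 0.0),
        samples=omega,
    )


def classify_probability(p_gt1: float, thresholds: Sequence[float] = TIER_THRESHOLDS) -> str:
    """Highest support tier reached by P(omega > 1); 'none' below the lowest."""
    tier = "none"
    for t in sorted(thresholds):
        if p_gt1 >= t:
            tier = format(t, "g")
    return tier


class SitewiseSelectionModel:
    """Per-codon omega scan over a codon alignment.

    Parameters
    ----------
    alignment
        In-frame allele alignment.
    frequencies
        Optional allele frequencies; used by the descriptive pairwise
        counts (Hardy-Weinberg pair weights). The event-count inference is
        genealogical and does not weight by frequency.
    prior
        ``(a0, c0)``: ``a0`` is both shape and rate of the proper unit-mean
        Gamma prior on omega (and the Beta prior parameters of the
        descriptive posterior); ``c0`` the shape increment of the pooled
        synonymous-rate posterior.
    boundary_codon
        Domain boundary for the per-domain guide trees (after this codon);
        None for a single tree.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        frequencies: AlleleFrequencyTable | None = None,
        prior: tuple[float, float] = (0.5, 0.5),
        boundary_codon: int | None = DEFAULT_BOUNDARY_CODON,
    ) -> None:
        self.alignment = alignment
        self.frequencies = frequencies
        self.prior = prior
        self.boundary_codon = boundary_codon

    @classmethod
    def from_files(
        cls,
        alignment_path,
        frequency_path=None,
        prior: tuple[float, float] = (0.5, 0.5),
        boundary_codon: int | None = DEFAULT_BOUNDARY_CODON,
    ) -> "SitewiseSelectionModel":
        from .alignment_io import read_codon_alignment, read_frequencies

        aln = read_codon_alignment(alignment_path)
        freqs = read_frequencies(frequency_path) if frequency_path else None
        return cls(aln, freqs, prior, boundary_codon)

    def fit(
        self,
        n_samples: int = 10_000,
        seed: int | None = None,
        thresholds: Sequence[float] = TIER_THRESHOLDS,
    ) -> "SitewiseSelectionResults":
        """Run the scan over every codon; returns results with raw samples."""
        rng = np.random.default_rng(seed)
        a0, c0 = self.prior
        events = codon_event_counts(self.alignment, self.boundary_codon)
        if not events:
            raise InsufficientDataError("no codon observed in 2 or more alleles")
        s_events = sum(e.sd for e in events.values())
        s_sites = sum(e.s_sites for e in events.values())
        lambda_hat = s_events / s_sites if s_sites > 0 else 0.0
        lambda_draws = rng.gamma(c0 + s_events, 1.0 / s_sites, size=n_samples)

        posteriors: dict[int, OmegaPosterior] = {}
        counts_by_codon: dict[int, CodonCounts] = {}
        skipped: list[int] = []
        for codon in range(1, self.alignment.codon_count + 1):
            ev = events.get(codon)
            if ev is None:
                skipped.append(codon)
                continue
            posteriors[codon] = event_omega_posterior(
                ev,
                lambda_draws,
                lambda_hat,
                prior_a=a0,
                n_samples=n_samples,
                seed=rng,
            )
            try:
                counts_by_codon[codon] = codon_diff_counts(
                    self.alignment, self.frequencies, codon
                )
            except InsufficientDataError:
                pass
        return SitewiseSelectionResults(
            model=self, posteriors=posteriors, events=events,
            counts=counts_by_codon, lambda_hat=lambda_hat,
            skipped=tuple(skipped), seed=seed,
            n_samples=n_samples, thresholds=tuple(thresholds),
        )


class SitewiseSelectionResults:
    """Fit output: per-codon posteriors, tiers, and regional summaries."""

    def __init__(self, model, posteriors, events, counts, lambda_hat,
                 skipped, seed, n_samples, thresholds):
        self.model = model
        self.posteriors: Mapping[int, OmegaPosterior] = posteriors
        self.events: Mapping[int, CodonEvents] = events
        self.counts: Mapping[int, CodonCounts] = counts
        self.lambda_hat = lambda_hat
        self.skipped = skipped
        self.seed = seed
        self.n_samples = n_samples
        self.thresholds = thresholds

    @property
    def codons(self) -> list[int]:
        return sorted(self.posteriors)

    def samples_matrix(self) -> tuple[list[int], np.ndarray]:
        codons = self.codons
        return codons, np.vstack([self.posteriors[c].samples for c in codons])

    def reference_aa(self, codon: int) -> str:
        aln = self.model.alignment
        idx = 0
        if aln.reference_id is not None:
            idx = aln.allele_ids.index(aln.reference_id)
        c = aln.codon(idx, codon)
        if set(c) - set(ng86.NUCLEOTIDES):
            return "?"
        return ng86.GENETIC_CODE.get(c, "?")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.codons:
            p = self.posteriors[c]
            ev = self.events[c]
            ct = self.counts.get(c)
            rows.append(
                {
                    "codon": c,
                    "ref_aa": self.reference_aa(c),
                    "Nd": ev.nd,
                    "Sd": ev.sd,
                    "n_sites": ev.n_sites,
                    "s_sites": ev.s_sites,
                    "n_changes": ev.n_changes,
                    "pair_nd": ct.nd if ct else float("nan"),
                    "pair_sd": ct.sd if ct else float("nan"),
                    "omega_hat": p.omega_hat,
                    "omega_mean": p.omega_mean,
                    "omega_median": p.omega_median,
                    "hpd_lo": p.hpd_lo,
                    "hpd_hi": p.hpd_hi,
                    "p_gt1": p.p_gt1,
                    "tier": p.tier,
                    "prior_only": p.prior_only,
                }
            )
        return pd.DataFrame(rows)

    def selected_codons(self, min_tier: float = 0.95) -> list[int]:
        return [c for c in self.codons if self.posteriors[c].p_gt1 >= min_tier]

    def region_mean_omega(self, region: RegionSpec) -> float:
        """Mean over the region's codons of the posterior median omega."""
        vals = [
            self.posteriors[c].omega_median
            for c in self.codons
            if region.start_codon <= c <= region.end_codon
        ]
        if not vals:
            return float("nan")
        return float(np.mean(vals))

    def summary(self, boundary_codon: int | None = None) -> str:
        aln = self.model.alignment
        lines = [
            "Sitewise selection scan",
            "=======================",
            f"alleles: {aln.n_sequences}   codons: {aln.codon_count}   "
            f"posterior draws/codon: {self.n_samples}   seed: {self.seed}",
            f"prior (omega shape/rate, rate shape): {self.model.prior}",
            f"pooled synonymous rate: {self.lambda_hat:.4f} events/site",
        ]
        if self.skipped:
            lines.append(f"codons without data (skipped): {len(self.skipped)}")
        try:
            regions = partition_regions(aln, boundary_codon or self.model.boundary_codon or 91)
        except Exception:
            regions = [aln.total_region()]
        for r in regions:
            lines.append(
                f"mean omega (posterior medians), {r.name}: {self.region_mean_omega(r):.3f}"
            )
        for t in self.thresholds:
            n = sum(1 for c in self.codons if self.posteriors[c].p_gt1 >= t)
            lines.append(f"codons with P(omega>1) >= {t}: {n}")
        sel = self.selected_codons()
        if sel:
            labelled = ", ".join(f"{self.reference_aa(c)}{c}" for c in sel)
            lines.append(f"selected codons (tier >= 0.95): {labelled}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def selection_profile(
    aln: CodonAlignment,
    frequencies: AlleleFrequencyTable | None = None,
    seed: int | None = None,
    n_samples: int = 10_000,
    boundary_codon: int | None = DEFAULT_BOUNDARY_CODON,
) -> SitewiseSelectionResults:
    """Convenience wrapper: build the model and fit it."""
    return SitewiseSelectionModel(aln, frequencies, boundary_codon=boundary_codon).fit(
        n_samples=n_samples, seed=seed
    )
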