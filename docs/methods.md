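# Methods

Statistical models, conventions and numerical choices in `mhcscan`.

## 1. Alignment and region conventions

* Input is an in-frame nucleotide alignment of the distinct alleles of one
  locus (length divisible by 3, characters `ACGTN-`). Codons and
  nucleotide columns are numbered 1-based.
* The α1/α2 domain boundary defaults to codon 91: α1 = codons 1–91,
  α2 = 92–end. All region-aware functions accept an explicit boundary.
* `N` is missing data. Site-based statistics use the **complete-column**
  convention: any column containing a gap or `N` in any sequence is
  excluded. Pairwise codon statistics use **pairwise deletion** (a codon is
  skipped for a pair only when either member is gapped/ambiguous there).
* Pairwise statistics are computed over *distinct* haplotypes of the
  region by default (each unique sequence once), matching how allele
  surveys treat alignments of named alleles.

## 2. Descriptive diversity statistics

For a region of full length L with m complete columns:

* S = number of polymorphic complete columns; η = Σ (distinct states − 1)
  over complete columns, so recurrent mutation inflates η but not S.
* k = mean pairwise nucleotide differences over distinct haplotypes;
  π = k / m.
* Watterson θ (per sequence) = S / a_n with a_n = Σ_{i=1}^{n−1} 1/i.
* Ne = θ / (4 μ L) with μ = 1.1 × 10⁻⁸ per site per sequence by default.

Denominators differ deliberately: % polymorphic sites and Ne use the full
length L (gap columns included), π uses the complete-site count m. Both
conventions are recorded in the analysis manifest. These choices reproduce
the arithmetic of the published brown trout *UBA* survey tables: e.g.
π(total) = 135/519 = 0.26, %poly = 334/552 = 60.5%, θ = ⌊334/a₂₁⌋ = 92,
Ne = 92/(4·1.1×10⁻⁸·552) = 3.8 × 10⁶. θ is floored to an integer before
the Ne division when reproducing printed tables.

### Nei–Gojobori (1986) counting

`ng86.codon_sites` assigns each of a codon's nine single-nucleotide
mutations 1/3 of a synonymous or nonsynonymous site; mutations creating a
stop codon contribute to neither, so s + n may fall below 3 (the common
convention in descriptive-diversity software; `renormalize=True` rescales
to 3). `ng86.pair_diffs` averages synonymous/nonsynonymous step counts
over all orderings of the differing positions, discarding pathways through
stop intermediates; when every pathway is blocked the average falls back
to all pathways so that sd + nd always equals the Hamming distance.

dS and dN are per-pair pS = Σsd/Σ(syn sites), pN = Σnd/Σ(nonsyn sites)
(sites averaged over the two codons), averaged over haplotype pairs, with
an optional per-pair Jukes–Cantor correction (pairs with p ≥ 3/4 dropped).

### Rarefaction allelic richness

For a genotype table of N individuals with allele a carried by c_a of
them, the expected richness in m individuals is the hypergeometric
closed form E[A_m] = Σ_a (1 − C(N−c_a, m)/C(N, m)). The Monte-Carlo
estimator samples m distinct individuals per replicate (random-key
argpartition over a boolean incidence matrix, batched to bound memory)
and reports mean, SD and the closed form side by side. Individuals typed
with more than two alleles are dropped by `diploid_subset()` before
rarefaction.

## 3. LD decay permutation test

Biallelic complete columns are extracted per region (multiallelic columns
counted but excluded). Three pairwise measures: r², |D′|, and G4 coded as
a *compatibility indicator* (1 = at most three of the four two-site
gametes present). All three decline with distance under recombination, so
one test form serves all: the observed statistic is the Pearson
correlation between the per-pair LD value and the inter-site nucleotide
distance, and the null distribution is built by permuting site *positions*
(each pair keeps its LD value while distances are recomputed). The test is
one-sided for negative correlation; p = (#{perm ≤ obs} + 1)/(n_perm + 1)
with ties counted conservatively. For ≤ 8 sites an exact enumeration over
all position permutations is available. Degenerate inputs (no variance in
LD values or distances) raise a dedicated error and are reported as
untestable rows, not as p-values.

Calibration caveat: p-values are uniform under the no-recombination null
only when ω is homogeneous. Heterogeneous per-codon ω induces genuine
short-range LD through within-codon rate coupling — a property of the
data, not a defect of the test — so the calibration benchmark uses a flat
ω = 1 profile.

## 4. Hudson–Kaplan minimum recombination

Every four-gamete-incompatible site pair defines an open interval that
must contain a recombination event. Intervals containing a smaller
incompatible interval are discarded (minimal intervals); a left-to-right
greedy sweep then keeps a maximal disjoint subset whose size is the
classical lower bound Rm. Position queries (`RecombinationScan.overlaps`)
use the **full minimal set**, because every minimal interval localizes an
event while the greedy subset only determines the count — a
boundary-straddling interval can be legitimately displaced from the
greedy subset by neighbours without ceasing to localize an event.

## 5. Sitewise selection scan

The scan has a descriptive layer and an inference layer.

**Descriptive layer.** Per codon, pathway-averaged pairwise differences
are accumulated over allele pairs with Hardy–Weinberg weights 2 f_i f_j
and normalized to per-pair means, alongside frequency-weighted potential
sites; a conjugate Beta posterior on the nonsynonymous fraction converts
these to an ω posterior. These counts are reported (`pair_nd`, `pair_sd`)
but carry limited evidence: a normalized per-pair mean is bounded by the
3 nt of a codon no matter how many alleles were sampled, so this
posterior stays prior-dominated by construction.

**Inference layer (what the model fits).** Substitution *events* are
estimated by Fitch parsimony on per-domain guide trees:

* One UPGMA guide tree per domain (scipy average-linkage on nucleotide
  Hamming distances), so interdomain recombinants cannot distort either
  genealogy — each domain's tree reflects that domain's lineage history.
* Per codon, Fitch parsimony counts the minimum state changes on the
  domain tree; leaves with gapped/ambiguous codons are wildcards and
  never contribute changes. Multi-nucleotide changes on an edge are
  classified by the NG86 pathway average.

The identifying assumption, standard in sitewise selection models, is a
**site-invariant synonymous rate** λ pooled over codons:

    λ | data ~ Gamma(c₀ + Σ_c Sd_c, rate Σ_c s_c)

Conditional on λ, nonsynonymous events at codon c are
Nd_c ~ Poisson(ω_c λ n_c) with a proper unit-mean prior
ω_c ~ Gamma(a₀, rate a₀), giving the conjugate posterior

    ω_c | Nd_c, λ ~ Gamma(a₀ + Nd_c, rate a₀ + λ n_c)

Posterior draws mix over the λ posterior; P(ω > 1) is computed
semi-analytically as the λ-averaged Gamma survival function at 1
(`scipy.special.gammaincc`), and the Monte-Carlo draws feed HPD intervals
and cross-population comparisons. Defaults a₀ = c₀ = 0.5. With no events
the posterior reverts toward the unit-mean prior (P(ω>1) ≈ 0.32), so an
uninformative codon can never reach a support tier. Support tiers are
P(ω > 1) ≥ 0.95 / 0.99 / 0.999; no multiple-testing correction is applied
(the number of codons tested is reported). Regional summaries average
posterior *medians*, which are robust to the heavy right tail of
low-count codons.

Why parsimony events rather than pairwise counts: with ~20 alleles, deep
allelic lineages and recurrent substitution, pairwise means saturate at
3 nt per codon and discard the genealogical multiplicity of changes;
minimum-change counts on a guide tree recover each observable
substitution once, which is what makes the Poisson event model and its
operating characteristics (TPR ≈ 0.9, FPR < 0.001 at tier 0.95 on the
default synthetic regime) achievable.

## 6. Cross-population comparison

For codon-matched scans of populations A and B, equality is rejected when
the 95% HPD interval of log(ω_A/ω_B) excludes 0. The two posterior sample
vectors are combined by seeded random pairing; the shuffling generator is
keyed by seed, codon and a *content digest* of each vector's ranking
pattern (CRC of the stable argsort), which makes the test exactly
antisymmetric under swapping A and B and invariant to rescaling both
vectors. Nonpositive samples are dropped (counted). The HPD interval is
the shortest contiguous window over the sorted samples holding
⌈mass·n⌉ points, ties broken toward the smallest lower bound; at least 20
samples are required. Measured type-I error on posteriors resampled from
a shared true rate is ≈ 5% at 95% mass.

## 7. Synthetic-data generator

Structure (defaults emulate a single-river brown trout sample):

* 184 codons, boundary at codon 91; 3 ancestral lineages per domain
  diverged from a common stop-free base sequence by
  Poisson(0.3 × domain nt length) substitutions.
* 21 alleles form a **random recursive genealogy**: each new allele
  copies the full haplotype of a uniformly chosen ancestor (founder or
  earlier allele) and adds Poisson(27) private substitutions. With
  probability 0.5 it is instead an interdomain recombinant grafting the
  α1 half of one ancestor onto the α2 half of another from a different
  lineage (crossover recorded at the boundary; ancestral crossovers
  inherited per side); with probability 0.05 one intradomain crossover
  splices a different-lineage domain tail. Grafts are the *only* source
  of crossovers — with both rates at zero, inheritance is strictly
  vertical, which is what makes the generator a valid null for the LD
  calibration benchmark.
* The mutation engine picks single-nucleotide changes with weight 1 for
  synonymous and ω(codon) for nonsynonymous candidates, stop-creating
  changes excluded outright; ω is therefore the expected
  nonsynonymous/synonymous odds relative to NG86 opportunities, which is
  what makes parameter recovery well defined. Default profile: ω = 0.3
  background, ω = 5 at 20 cleft-like codons (14 in α1, 6 in α2).
* Population layer: Dirichlet(1) allele frequencies; 28 diploid
  individuals drawn under Hardy–Weinberg equilibrium.
* Ground truth records per-allele lineages and crossovers, the
  interdomain-recombinant flag, and per-codon synonymous/nonsynonymous
  mutation counts.

Default `lineage_divergence` and `mutations_per_allele` were calibrated
against published total-region diversity anchors (π ≈ 0.26, η ≈ 519,
k ≈ 135, S ≈ 334 for n = 21 alleles of 552 nt), giving simulated
π ≈ 0.25, η ≈ 534, k ≈ 136, S ≈ 354.

**Limitations (by design):** no indels; no explicit coalescent times or
branch lengths (the recursive-copy genealogy fixes the *expected* number
of private substitutions per allele rather than drawing times); no
trans-species structure; crossovers occur at the boundary or at uniform
intradomain cut points rather than from a per-interval ρ map; allele
frequencies are exchangeable Dirichlet draws, not the skewed frequency
spectra balancing selection can maintain.

## 8. Numerical choices

* All randomness flows through `numpy.random.Generator` /
  `SeedSequence`; pipeline stages receive independent spawned seeds, so
  every output is exactly reproducible from the CLI seed.
* Permutation tests are vectorized over batched permutations (≤ 512 at a
  time) with the correlation computed as a centred dot product; ties are
  counted with a 1e-12 slack toward significance.
* NG86 primitives are `lru_cache`d (61 codons, 3721 pairs).
* Monte-Carlo rarefaction batches 20 000 replicates to bound memory.
* P(ω > 1) uses the analytic Gamma survival averaged over λ draws rather
  than counting Monte-Carlo exceedances, removing sampling error from
  tier classification near thresholds.
* HPD windows are computed by a single vectorized sweep over sorted
  samples.
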