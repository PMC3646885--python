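# mhcscan

Selection and recombination analysis of MHC class I codon alignments.

`mhcscan` is a population-genetics toolkit for allele alignments at a single
classical MHC class I locus (such as the salmonid *UBA* locus). The peptide
binding region (PBR) of such a gene is encoded by two domains — α1 and α2,
here codons 1–91 and 92–184 — that sit on separate exons flanking a large
intron. Two evolutionary forces dominate these genes:

* **diversifying (balancing) selection** at the codons whose side chains
  line the peptide-binding cleft, visible as an excess of nonsynonymous
  substitutions (ω = dN/dS > 1) at a discrete set of sites against a
  purifying background; and
* **interdomain recombination**, which reshuffles α1 and α2 sequence
  lineages at the intron and shows up as linkage disequilibrium (LD)
  decaying with distance across the domain boundary, a recombination
  hotspot localizable between the exons.

The package provides the full analysis chain used in descriptive surveys of
such loci, plus a ground-truthed synthetic-data generator for validating
every inferential component:

| Module | Contents |
| --- | --- |
| `mhcscan.alignment_io` | in-frame codon alignments (FASTA), genotype and allele-frequency tables, α1/α2/total region bookkeeping |
| `mhcscan.ng86` | Nei–Gojobori (1986) synonymous/nonsynonymous sites and pathway-averaged differences |
| `mhcscan.diversity` | S, η, π, k, Watterson θ, Ne, dS/dN/dN/dS tables; rarefaction allelic richness |
| `mhcscan.ld_recombination` | r², D′ and four-gamete LD, distance-decay permutation tests, Hudson–Kaplan Rm with event intervals |
| `mhcscan.sitewise_selection` | per-codon Bayesian ω scan (model/results objects, posterior samples, support tiers) |
| `mhcscan.posterior_compare` | HPD intervals and cross-population per-codon ω equality tests |
| `mhcscan.synthetic_data` | codon-alignment simulator with known selected codons, lineage structure and crossovers |
| `mhcscan.benchmarks` | seeded operating-characteristic measurements (recovery, calibration, localization) |
| `mhcscan.cli` | `mhcscan simulate / analyze / compare / rarefy` |

## Quick start (CLI)

```bash
# generate a fully ground-truthed synthetic dataset
mhcscan simulate --seed 42 --out data/

# full single-population analysis: diversity table, LD permutation tests,
# Hudson–Kaplan scan, sitewise selection scan, rarefaction, manifest
mhcscan analyze --alignment data/alignment.fasta \
                --frequencies data/frequencies.tsv \
                --genotypes data/genotypes.tsv \
                --seed 1 --out results/

# per-codon omega equality tests between two populations
mhcscan compare --alignment-a popA.fasta --alignment-b popB.fasta \
                --seed 1 --out comparison.tsv

# rarefaction allelic richness from a genotype table
mhcscan rarefy --genotypes data/genotypes.tsv --m 10 --replicates 1000 --seed 1
```

Every stage is seeded and reproducible; `analyze` writes a `manifest.json`
recording versions, stage seeds and all denominator conventions.

## Worked example (Python)

The default generator configuration emulates a single-river brown trout
sample: 21 alleles of 184 codons, three deep allelic lineages per domain,
20 codons under diversifying selection (ω = 5) on a purifying background
(ω = 0.3), and interdomain crossovers concentrated at the codon 91/92
boundary.

```python
from mhcscan import SimulationConfig, simulate_dataset, selection_profile
from mhcscan.alignment_io import partition_regions
from mhcscan.diversity import diversity_table
from mhcscan.ld_recombination import hudson_kaplan_scan, recombination_tests

ds = simulate_dataset(SimulationConfig(seed=42))
regions = partition_regions(ds.alignment, 91)
print(diversity_table(ds.alignment, regions).round(3))
```

```
                                   alpha1      alpha2       total
Haplotypes                         21.000      21.000      21.000
Sequence length                   273.000     279.000     552.000
Sites (excluding gaps)            273.000     279.000     552.000
Polymorphic sites                 174.000     182.000     356.000
% Polymorphic sites                63.736      65.233      64.493
Total mutations                   274.000     273.000     547.000
Nucleotide diversity (pi)           0.246       0.252       0.249
Theta per sequence                 48.364      50.587      98.951
Ne                            4026282.018 4120830.724 4074070.222
Average nt differences             67.067      70.257     137.324
Synonymous diversity (dS)           0.347       0.430       0.387
Non-synonymous diversity (dN)       0.221       0.209       0.215
dN/dS                               0.638       0.486       0.556
```

LD decays with distance over the whole gene but not within either domain —
the signature of interdomain recombination:

```python
tests = recombination_tests(ds.alignment, regions, n_perm=10_000, seed=1)
print(tests[["region", "measure", "correlation", "p_value", "stars"]])
```

```
region measure  correlation  p_value stars
alpha1      r2       -0.024    0.166
alpha1  Dprime       -0.035    0.073
alpha1      G4       -0.047    0.035     *
alpha2      r2        0.033    0.890
alpha2  Dprime        0.001    0.510
alpha2      G4        0.001    0.515
 total      r2       -0.182    0.000   ***
 total  Dprime       -0.166    0.000   ***
 total      G4       -0.172    0.000   ***
```

The Hudson–Kaplan scan localizes a recombination event straddling the
domain boundary (between nt 273 and 274):

```python
scan = hudson_kaplan_scan(ds.alignment, ds.alignment.total_region())
print("Rm =", scan.rm, "| boundary straddled:", scan.overlaps(273.5))
# Rm = 41 | boundary straddled: True
```

The sitewise scan recovers the selected codons:

```python
res = selection_profile(ds.alignment, ds.frequencies, seed=1)
print(res.summary())
```

```
Sitewise selection scan
=======================
alleles: 21   codons: 184   posterior draws/codon: 10000   seed: 1
prior (omega shape/rate, rate shape): (0.5, 0.5)
pooled synonymous rate: 2.2246 events/site
mean omega (posterior medians), alpha1: 0.727
mean omega (posterior medians), alpha2: 0.546
mean omega (posterior medians), total: 0.635
codons with P(omega>1) >= 0.95: 19
codons with P(omega>1) >= 0.99: 16
codons with P(omega>1) >= 0.999: 10
selected codons (tier >= 0.95): V9, Y24, S33, T42, A47, R53, H58, R62, Y66,
E70, I77, W83, G88, A94, K96, S113, P130, R156, G170
```

Against the generator's ground truth (codons 9, 15, 24, 33, 42, 47, 53, 58,
62, 66, 70, 77, 83, 88, 94, 96, 113, 130, 156, 170), this seed recovers
19 of the 20 selected codons with zero false positives. Pooled over 50
seeds the scan achieves a true-positive rate of 0.93 with a false-positive
rate of 0.0002 at the 0.95 support tier (see `mhcscan.benchmarks`).

## Validation and reproduction

The test suite (including the acceptance tests) runs in a few minutes:

```bash
python -m pytest -q tests/
```

The acceptance script recomputes the headline quantities — both the
arithmetic identities among the published descriptive statistics of the
Srahrevagh River (n = 21 alleles) and Colorado River (n = 10) brown trout
*UBA* samples, and the seeded operating characteristics of every
inferential component — and writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Representative output at seed 1 (about two minutes on one CPU):

| quantity | value | n |
| --- | --- | --- |
| `sitewise_tpr` / `sitewise_fpr` | 0.925 / 0.0002 | 50 seeds |
| `ld_permutation_ks_uniformity_p` | 0.50 | 1000 seeds |
| `interdomain_median_p_r2` (also D′, G4) | 0.00033 | 10 seeds |
| `within_domain_median_p` | 0.29 | 10 seeds |
| `hk_boundary_overlap_rate` | 0.965 | 200 seeds |
| `hpd_type1_error_rate` | 0.050 | 1000 replicates |
| `rarefaction_abs_z` (MC vs closed form) | 0.75 | 10⁵ replicates |
| `pi_total_srahrevagh` (= 135/519) | 0.2601 | 21 alleles |
| `ne_total_srahrevagh_e6` (= 92/(4·1.1×10⁻⁸·552)) | 3.788 | 21 alleles |
| `hotspot_to_mean_rho_ratio` (= 3.093/0.22) | 14.06 | — |

All randomness is driven by the `--seed` argument through
`numpy.random.SeedSequence`, so reruns reproduce the JSON exactly.

See `docs/methods.md` for the statistical models, the identifying
assumptions of the sitewise scan, the generator design, and every
denominator/rounding convention.
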