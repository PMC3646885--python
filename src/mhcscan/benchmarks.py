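"""Property-based validation benchmarks over the synthetic generator.

These routines quantify, over many seeded synthetic datasets, the
operating characteristics that the package is designed to deliver:

* :func:`scan_recovery` — sensitivity/specificity of the sitewise omega
  scan against the generator's known selected codons;
* :func:`ks_uniformity` — calibration of the LD-decay permutation test
  (p-values uniform when the generator runs with all recombination rates
  at zero and a flat omega profile);
* :func:`ld_decay_tests` — the per-region permutation-test pattern on
  the default interdomain-shuffle regime (significant decay over the
  whole gene, none within either domain);
* :func:`hk_boundary_rate` — how often a minimal Hudson–Kaplan interval
  straddles the configured domain boundary;
* :func:`hpd_type1` — type-I error of the cross-population HPD equality
  test on posteriors resampled from a shared true rate;
* :func:`rarefaction_check` — Monte-Carlo rarefaction against the
  closed-form hypergeometric expectation.

They are consumed by the test suite and the acceptance script; all are
deterministic given their seed arguments.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment_io import partition_regions
from .diversity import rarefaction_exact, rarefaction_richness
from .errors import DegenerateLDError, InsufficientDataError
from .ld_recombination import hudson_kaplan_scan, permutation_test, recombination_tests
from .posterior_compare import compare_samples
from .sitewise_selection import SitewiseSelectionModel
from .synthetic_data import SimulationConfig, SyntheticDataset, simulate_dataset

#: Generator overrides for the recombination-free, selectively flat null
#: used to check permutation-test calibration. Small on purpose: many
#: independent replicates are needed and each must still yield >= 3
#: biallelic sites.
KS_NULL_OVERRIDES: Mapping[str, object] = {
    "n_codons": 40,
    "boundary_codon": 20,
    "n_alleles": 12,
    "n_individuals": 10,
    "mutations_per_allele": 5.2,
    "omega_background": 1.0,
    "omega_selected": 1.0,
    "selected_codons": (),
    "recomb_rate_interdomain": 0.0,
    "recomb_rate_intradomain": 0.0,
}


def default_dataset(seed: int, **overrides) -> SyntheticDataset:
    """Simulate one dataset under the default configuration (plus overrides)."""
    return simulate_dataset(SimulationConfig(seed=seed, **overrides))


def scan_recovery(
    seeds: Iterable[int],
    tier: float = 0.95,
    n_samples: int = 2000,
    datasets: Sequence[SyntheticDataset] | None = None,
) -> dict:
    """Pooled TPR/FPR of the sitewise scan against generator ground truth.

    For each seed the default synthetic dataset is scanned and codons with
    P(omega > 1) >= ``tier`` are called selected. True/false positive
    counts are pooled over seeds; codons the scan could not test are
    excluded from both denominators.
    """
    tp = fp = fn = tn = 0
    per_seed_tpr: list[float] = []
    per_seed_fpr: list[float] = []
    for i, seed in enumerate(seeds):
        ds = datasets[i] if datasets is not None else default_dataset(seed)
        result = SitewiseSelectionModel(ds.alignment, ds.frequencies).fit(
            n_samples=n_samples, seed=seed
        )
        truth = set(ds.config.selected_codons)
        tested = set(result.codons)
        flagged = set(result.selected_codons(tier))
        tp_i = len(flagged & truth)
        fp_i = len(flagged - truth)
        fn_i = len((truth & tested) - flagged)
        tn_i = len(tested - truth - flagged)
        tp, fp, fn, tn = tp + tp_i, fp + fp_i, fn + fn_i, tn + tn_i
        per_seed_tpr.append(tp_i / (tp_i + fn_i) if tp_i + fn_i else float("nan"))
        per_seed_fpr.append(fp_i / (fp_i + tn_i) if fp_i + tn_i else float("nan"))
    return {
        "tpr": tp / (tp + fn) if tp + fn else float("nan"),
        "fpr": fp / (fp + tn) if fp + tn else float("nan"),
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "per_seed_tpr": per_seed_tpr,
        "per_seed_fpr": per_seed_fpr,
    }


def ks_uniformity(
    seeds: Iterable[int],
    n_perm: int = 199,
    measure: str = "r2",
) -> dict:
    """KS test of LD-decay permutation p-values against Uniform(0, 1).

    Each seed generates an independent recombination-free, selectively
    flat dataset (:data:`KS_NULL_OVERRIDES`) and contributes one p-value
    for the whole-gene LD-decay test. Seeds whose dataset is degenerate
    (no testable LD variation) are skipped and counted.
    """
    pvals: list[float] = []
    skipped = 0
    for seed in seeds:
        ds = default_dataset(seed, **KS_NULL_OVERRIDES)
        try:
            res = permutation_test(
                ds.alignment, ds.alignment.total_region(), measure,
                n_perm=n_perm, seed=seed,
            )
        except (DegenerateLDError, InsufficientDataError):
            skipped += 1
            continue
        pvals.append(res.p_value)
    ks_stat, ks_p = stats.kstest(pvals, "uniform")
    return {
        "ks_stat": float(ks_stat),
        "ks_p": float(ks_p),
        "n_pvalues": len(pvals),
        "n_skipped": skipped,
        "p_values": pvals,
    }


def ld_decay_tests(
    seeds: Iterable[int],
    n_perm: int = 2999,
    datasets: Sequence[SyntheticDataset] | None = None,
) -> pd.DataFrame:
    """Per-region permutation tests over default (interdomain-shuffle) seeds.

    Returns the concatenated :func:`recombination_tests` tables with a
    ``seed`` column; regions are alpha-1, alpha-2 and total.
    """
    frames = []
    for i, seed in enumerate(seeds):
        ds = datasets[i] if datasets is not None else default_dataset(seed)
        regions = partition_regions(ds.alignment, ds.config.boundary_codon)
        df = recombination_tests(ds.alignment, regions, n_perm=n_perm, seed=seed)
        df.insert(0, "seed", seed)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def hk_boundary_rate(
    seeds: Iterable[int],
    datasets: Sequence[SyntheticDataset] | None = None,
) -> dict:
    """Fraction of default-regime seeds whose Hudson–Kaplan scan localizes
    an event straddling the domain boundary (a minimal incompatible
    interval containing the boundary nt midpoint)."""
    hits = 0
    total = 0
    for i, seed in enumerate(seeds):
        ds = datasets[i] if datasets is not None else default_dataset(seed)
        scan = hudson_kaplan_scan(ds.alignment, ds.alignment.total_region())
        midpoint = 3 * ds.config.boundary_codon + 0.5
        hits += int(scan.overlaps(midpoint))
        total += 1
    return {"rate": hits / total if total else float("nan"), "hits": hits, "n": total}


def hpd_type1(
    n_replicates: int,
    seed: int,
    n_obs: int = 60,
    p_true: float = 0.3,
    n_samples: int = 3000,
    mass: float = 0.95,
) -> dict:
    """Type-I error of the HPD equality test on matched posteriors.

    Each replicate draws two Binomial(n_obs, p_true) counts (the same true
    rate for both populations), forms Jeffreys Beta posterior samples for
    each, and tests equality via the log-ratio HPD. The rejection rate
    estimates the type-I error at the given mass.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for rep in range(n_replicates):
        xa, xb = rng.binomial(n_obs, p_true), rng.binomial(n_obs, p_true)
        sa = rng.beta(0.5 + xa, 0.5 + n_obs - xa, n_samples)
        sb = rng.beta(0.5 + xb, 0.5 + n_obs - xb, n_samples)
        res = compare_samples(sa, sb, codon=rep, seed=seed, mass=mass)
        rejections += int(res.significant)
    return {
        "rate": rejections / n_replicates,
        "rejections": rejections,
        "n": n_replicates,
    }


def rarefaction_check(genotypes, m: int, replicates: int, seed: int) -> dict:
    """Monte-Carlo rarefaction vs the closed-form expectation.

    Returns the MC mean, exact expectation, and the discrepancy in units
    of the Monte-Carlo standard error.
    """
    res = rarefaction_richness(genotypes, m, replicates, seed=seed)
    exact = rarefaction_exact(genotypes, m)
    se = res.sd_richness / np.sqrt(replicates) if replicates > 1 else float("nan")
    z = abs(res.mean_richness - exact) / se if se and se > 0 else 0.0
    return {
        "mc_mean": res.mean_richness,
        "exact": exact,
        "se": se,
        "z": float(z),
    }
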