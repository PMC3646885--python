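"""Cross-population comparison of per-codon omega posteriors.

For two populations A and B with per-codon posterior samples of omega, the
equality hypothesis omega_A = omega_B is rejected at a codon when the 95%
highest-posterior-density interval of log(omega_A / omega_B) excludes 0.

The two posteriors are independent Monte-Carlo sample vectors; they are
combined by random pairing after seeded shuffling (equal lengths enforced
by truncation), which is deterministic given the seed and O(n), rather
than by all-pairs subsampling (available via ``all_pairs``).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ComparisonError, InsufficientDataError


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval over sorted samples holding ceil(mass*n).

    Ties in width are broken toward the smallest lower bound. Requires at
    least 20 samples and 0 < mass < 1.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 20:
        raise InsufficientDataError(f"hpd_interval needs >= 20 samples, got {n}")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    w = int(np.ceil(mass * n))
    if w >= n:
        return float(x[0]), float(x[-1])
    widths = x[w - 1 :] - x[: n - w + 1]
    i = int(np.argmin(widths))  # first minimum -> smallest lower bound
    return float(x[i]), float(x[i + w - 1])


@dataclass(frozen=True)
class CodonComparison:
    codon: int
    log_ratio_mean: float
    hpd_lo: float
    hpd_hi: float
    significant: bool
    direction: str  # "A>B", "B>A", "none"
    n_paired_samples: int
    n_dropped: int


@dataclass(frozen=True)
class PopulationComparison:
    """Per-codon HPD equality tests plus the cross-codon mean omega ratio."""

    codons: tuple[CodonComparison, ...]
    seed: int | None
    mass: float
    mean_omega_ratio: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "codon": [c.codon for c in self.codons],
                "log_ratio_mean": [c.log_ratio_mean for c in self.codons],
                "hpd_lo": [c.hpd_lo for c in self.codons],
                "hpd_hi": [c.hpd_hi for c in self.codons],
                "significant": [c.significant for c in self.codons],
                "direction": [c.direction for c in self.codons],
            }
        )

    @property
    def significant_codons(self) -> list[int]:
        return [c.codon for c in self.codons if c.significant]

    def counts_by_direction(self) -> dict[str, int]:
        out = {"A>B": 0, "B>A": 0}
        for c in self.codons:
            if c.significant:
                out[c.direction] += 1
        return out

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            df.to_csv(fh, sep="\t", index=False)
            fh.write(f"# mean omega_A/omega_B across codons\t{self.mean_omega_ratio!r}\n")


def _rank_digest(x: np.ndarray) -> int:
    """CRC of the ranking pattern of x: invariant to positive rescaling."""
    return zlib.crc32(np.argsort(x, kind="stable").astype(np.int64).tobytes())


def _keyed_rng(seed: int | None, codon: int, digest: int) -> np.random.Generator:
    """Generator keyed by seed, codon and a sample-content digest (not
    argument order), so that swapping populations A and B reproduces the
    same per-vector shuffles (exact antisymmetry) and rescaling both
    vectors by c > 0 leaves the comparison unchanged (scale equivariance)."""
    return np.random.default_rng(np.random.SeedSequence([seed or 0, codon, digest]))


def compare_samples(
    samples_a: np.ndarray,
    samples_b: np.ndarray,
    codon: int,
    seed: int | None = None,
    mass: float = 0.95,
    all_pairs: int = 0,
) -> CodonComparison:
    """HPD equality test for one codon from two posterior sample vectors."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    dropped = int(np.sum(a <= 0) + np.sum(b <= 0))
    a, b = a[a > 0], b[b > 0]
    if all_pairs > 0:
        rng = _keyed_rng(seed, codon, _rank_digest(a) ^ _rank_digest(b))
        ia = rng.integers(0, a.size, size=all_pairs)
        ib = rng.integers(0, b.size, size=all_pairs)
        log_ratio = np.log(a[ia]) - np.log(b[ib])
    else:
        a = _keyed_rng(seed, codon, _rank_digest(a)).permutation(a)
        b = _keyed_rng(seed, codon, _rank_digest(b)).permutation(b)
        n = min(a.size, b.size)
        log_ratio = np.log(a[:n]) - np.log(b[:n])
    lo, hi = hpd_interval(log_ratio, mass)
    significant = lo > 0.0 or hi < 0.0
    direction = "none"
    if significant:
        direction = "A>B" if lo > 0.0 else "B>A"
    return CodonComparison(
        codon=codon,
        log_ratio_mean=float(log_ratio.mean()),
        hpd_lo=lo,
        hpd_hi=hi,
        significant=significant,
        direction=direction,
        n_paired_samples=int(log_ratio.size),
        n_dropped=dropped,
    )


def compare_populations(
    result_a,
    result_b,
    seed: int | None = None,
    mass: float = 0.95,
    all_pairs: int = 0,
) -> PopulationComparison:
    """Per-codon log(omega_A/omega_B) HPD tests between two fitted scans.

    ``result_a``/``result_b`` are :class:`SitewiseSelectionResults` (or any
    objects exposing ``codons`` and per-codon ``posteriors[c].samples``).
    Codon sets must match exactly.
    """
    codons_a, codons_b = list(result_a.codons), list(result_b.codons)
    if codons_a != codons_b:
        only_a = sorted(set(codons_a) - set(codons_b))
        only_b = sorted(set(codons_b) - set(codons_a))
        raise ComparisonError(
            f"codon sets differ (only in A: {only_a[:5]}..., only in B: {only_b[:5]}...)"
            if only_a or only_b
            else "codon sets differ in order"
        )
    comparisons = []
    ratios = []
    for c in codons_a:
        sa = result_a.posteriors[c].samples
        sb = result_b.posteriors[c].samples
        comparisons.append(compare_samples(sa, sb, c, seed, mass=mass, all_pairs=all_pairs))
        med_b = np.median(sb)
        if med_b > 0:
            ratios.append(np.median(sa) / med_b)
    mean_ratio = float(np.mean(ratios)) if ratios else float("nan")
    return PopulationComparison(
        codons=tuple(comparisons), seed=seed, mass=mass, mean_omega_ratio=mean_ratio
    )
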