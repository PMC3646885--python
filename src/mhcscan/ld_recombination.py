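"""Linkage-disequilibrium decay tests and minimum-recombination localization.

Two complementary views of recombination in an allele alignment:

* a permutation test on the Pearson correlation between pairwise LD
  (r-squared, D-prime, or the four-gamete compatibility indicator G4) and
  physical distance — recombination makes LD decay with distance, so a
  significantly *negative* correlation is the signal;
* the Hudson–Kaplan lower bound Rm with its disjoint intervals, which
  localizes where recombination events must have occurred (a hotspot at
  the domain boundary shows up as an interval straddling it).

G4 is coded as a compatibility indicator (1 = at most three of the four
two-site haplotypes observed, 0 = all four present) so that, like the other
two measures, it declines with distance under recombination and the same
one-sided negative-correlation test applies to all three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations as iter_permutations
from math import factorial

import numpy as np
import pandas as pd

from .alignment_io import CodonAlignment, RegionSpec, complete_column_mask
from .errors import DegenerateLDError, InsufficientDataError

MEASURES = ("r2", "Dprime", "G4")


@dataclass(frozen=True)
class BiallelicSites:
    """Biallelic complete columns of a region.

    positions are 1-based nucleotide columns of the full alignment;
    ``matrix`` holds 0/1 state codes (0 = first-seen allele), one row per
    site and one column per (distinct) sequence.
    """

    positions: np.ndarray
    matrix: np.ndarray
    n_multiallelic: int


def biallelic_segregating_sites(
    aln: CodonAlignment, region: RegionSpec, unique: bool = True
) -> BiallelicSites:
    """Extract biallelic complete columns; count >2-state columns in metadata."""
    mask = complete_column_mask(aln, region)
    arr = aln.to_array()[:, region.nt_slice]
    if unique:
        arr = np.unique(arr, axis=0)
    offset = region.nt_slice.start  # 0-based start of region in the alignment
    positions: list[int] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for col_idx in np.flatnonzero(mask):
        col = arr[:, col_idx]
        states = np.unique(col)
        if len(states) == 2:
            positions.append(offset + col_idx + 1)  # 1-based nt position
            rows.append((col == states[1]).astype(np.int8))
        elif len(states) > 2:
            n_multi += 1
    matrix = np.array(rows, dtype=np.int8) if rows else np.empty((0, arr.shape[0]), np.int8)
    return BiallelicSites(np.array(positions, dtype=np.int64), matrix, n_multi)


def _ld_matrices(matrix: np.ndarray) -> dict[str, np.ndarray]:
    """All-pairs LD matrices (sites x sites) for the three measures."""
    x = matrix.astype(np.float64)
    n = x.shape[1]
    p = x.mean(axis=1)
    p_ab = (x @ x.T) / n
    d = p_ab - np.outer(p, p)
    denom = np.outer(p * (1 - p), p * (1 - p))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, d * d / denom, np.nan)
        d_max_pos = np.minimum(np.outer(p, 1 - p), np.outer(1 - p, p))
        d_max_neg = np.minimum(np.outer(p, p), np.outer(1 - p, 1 - p))
        d_max = np.where(d > 0, d_max_pos, d_max_neg)
        dprime = np.where(d_max > 0, np.abs(d) / d_max, 0.0)
    # gamete presence counts
    xi = matrix.astype(np.int32)
    n11 = xi @ xi.T
    n10 = xi @ (1 - xi).T
    n01 = (1 - xi) @ xi.T
    n00 = (1 - xi) @ (1 - xi).T
    four = (n11 > 0) & (n10 > 0) & (n01 > 0) & (n00 > 0)
    g4 = (~four).astype(np.float64)  # 1 = compatible
    return {"r2": r2, "Dprime": dprime, "G4": g4}


def pairwise_ld(
    site_i: np.ndarray, site_j: np.ndarray
) -> tuple[float, float, int]:
    """(r2, Dprime, G4) for two 0/1-coded biallelic sites over the same sequences."""
    for s in (site_i, site_j):
        if len(np.unique(s)) < 2:
            raise DegenerateLDError("monomorphic site passed to pairwise_ld")
    m = np.vstack([site_i, site_j]).astype(np.int8)
    out = _ld_matrices(m)
    return float(out["r2"][0, 1]), float(out["Dprime"][0, 1]), int(out["G4"][0, 1])


@dataclass(frozen=True)
class LDResult:
    measure: str
    correlation: float
    p_value: float
    permutations: int
    n_sites: int
    n_pairs: int
    site_pairs: pd.DataFrame | None = field(default=None, repr=False)


def _pair_arrays(sites: BiallelicSites, measure: str):
    n_sites = len(sites.positions)
    iu = np.triu_indices(n_sites, k=1)
    values = _ld_matrices(sites.matrix)[measure][iu]
    return iu, values


def permutation_test(
    aln: CodonAlignment,
    region: RegionSpec,
    measure: str = "r2",
    n_perm: int = 100_000,
    seed: int | np.random.Generator | None = None,
    exhaustive: bool = False,
    keep_pairs: bool = False,
    unique: bool = True,
) -> LDResult:
    """One-sided permutation test for LD decay with distance.

    The observed statistic is the Pearson correlation between per-pair LD
    values and the nucleotide distance between the sites (column midpoints).
    The null is built by permuting site positions — distances are
    recomputed while each pair keeps its LD value. Recombination predicts a
    negative correlation, so p = (#{perm corr <= observed} + 1) / (n_perm + 1)
    with ties counted as <= (conservative). With ``exhaustive=True`` all
    site-position permutations are enumerated and p is the exact fraction
    (the identity permutation included).
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown LD measure {measure!r}; choose from {MEASURES}")
    sites = biallelic_segregating_sites(aln, region, unique=unique)
    n_sites = len(sites.positions)
    if n_sites < 3:
        raise InsufficientDataError(f"need >= 3 biallelic sites, found {n_sites}")
    iu, values = _pair_arrays(sites, measure)
    positions = sites.positions.astype(np.float64)
    dist = np.abs(positions[iu[0]] - positions[iu[1]])
    if np.ptp(values) == 0:
        raise DegenerateLDError(f"all {measure} values are equal; correlation undefined")
    if np.ptp(dist) == 0:
        raise DegenerateLDError("all pairwise distances are equal; correlation undefined")

    v_c = values - values.mean()
    v_norm = np.sqrt((v_c**2).sum())

    def corr_for(pos_rows: np.ndarray) -> np.ndarray:
        d = np.abs(pos_rows[:, iu[0]] - pos_rows[:, iu[1]])
        d_c = d - d.mean(axis=1, keepdims=True)
        d_norm = np.sqrt((d_c**2).sum(axis=1))
        return (d_c @ v_c) / (d_norm * v_norm)

    observed = float(corr_for(positions[None, :])[0])

    if exhaustive:
        if n_sites > 8:
            raise ValueError("exhaustive enumeration limited to <= 8 sites")
        perms = np.array(list(iter_permutations(positions)))
        corrs = corr_for(perms)
        n_total = factorial(n_sites)
        p = float(np.sum(corrs <= observed + 1e-12) / n_total)
        n_used = n_total
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        count = 0
        batch = max(1, min(n_perm, 512))
        done = 0
        while done < n_perm:
            b = min(batch, n_perm - done)
            perms = rng.permuted(np.tile(positions, (b, 1)), axis=1)
            corrs = corr_for(perms)
            count += int(np.sum(corrs <= observed + 1e-12))
            done += b
        p = (count + 1) / (n_perm + 1)
        n_used = n_perm

    pairs_df = None
    if keep_pairs:
        pairs_df = pd.DataFrame(
            {
                "pos_i": sites.positions[iu[0]],
                "pos_j": sites.positions[iu[1]],
                "distance": dist.astype(int),
                measure: values,
            }
        )
    return LDResult(measure, observed, p, n_used, n_sites, len(values), pairs_df)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def recombination_tests(
    aln: CodonAlignment,
    regions,
    n_perm: int = 100_000,
    seed: int | None = None,
    unique: bool = True,
) -> pd.DataFrame:
    """Permutation tests for all three measures over several regions.

    Degenerate region/measure combinations (no LD variance — e.g. every
    site pair four-gamete compatible) are reported as non-significant with
    NaN correlation and p, flagged in the ``note`` column.
    """
    root = np.random.default_rng(seed)
    rows = []
    for region in regions:
        for measure in MEASURES:
            rng = np.random.default_rng(root.integers(2**31))
            try:
                res = permutation_test(
                    aln, region, measure, n_perm=n_perm, seed=rng, unique=unique
                )
                rows.append(
                    {
                        "region": region.name,
                        "measure": measure,
                        "correlation": res.correlation,
                        "p_value": res.p_value,
                        "stars": significance_stars(res.p_value),
                        "permutations": res.permutations,
                        "note": "",
                    }
                )
            except (DegenerateLDError, InsufficientDataError) as exc:
                rows.append(
                    {
                        "region": region.name,
                        "measure": measure,
                        "correlation": float("nan"),
                        "p_value": float("nan"),
                        "stars": "",
                        "permutations": 0,
                        "note": f"not testable: {exc}",
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hudson–Kaplan minimum recombination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecombinationScan:
    """Hudson–Kaplan lower bound and its disjoint event intervals.

    ``intervals`` are (left nt, right nt) pairs, 1-based site positions;
    each interval contains at least one inferred recombination event
    strictly between its endpoints. rm == len(intervals).
    ``minimal_intervals`` is the full set of minimal incompatible intervals
    before the disjoint greedy selection; every one of them localizes an
    event, so position queries (:meth:`overlaps`) use this set — the greedy
    subset only determines the count.
    """

    rm: int
    intervals: tuple[tuple[int, int], ...]
    minimal_intervals: tuple[tuple[int, int], ...] = ()

    def overlaps(self, nt_position: float) -> bool:
        """True if any minimal interval straddles the given (possibly half-integer) position."""
        return any(lo < nt_position < hi for lo, hi in self.minimal_intervals)


def hudson_kaplan_scan(
    aln: CodonAlignment, region: RegionSpec, unique: bool = True
) -> RecombinationScan:
    """Minimum number of recombination events via the four-gamete test.

    All incompatible site pairs define intervals; intervals containing a
    smaller incompatible interval are discarded, then a left-to-right greedy
    sweep keeps the maximal set of non-overlapping (open) intervals. The
    count of kept intervals is the classical lower bound Rm.
    """
    sites = biallelic_segregating_sites(aln, region, unique=unique)
    if len(sites.positions) < 2:
        return RecombinationScan(0, (), ())
    g4 = _ld_matrices(sites.matrix)["G4"]
    iu = np.triu_indices(len(sites.positions), k=1)
    incompatible = g4[iu] == 0.0
    lefts = sites.positions[iu[0]][incompatible]
    rights = sites.positions[iu[1]][incompatible]
    intervals = sorted(set(zip(lefts.tolist(), rights.tolist())))
    # Drop intervals containing another incompatible interval. Sweeping lefts
    # in decreasing order, an interval (l, h) is redundant iff some interval
    # with left >= l has right <= h; at most one interval per left survives.
    minimal: list[tuple[int, int]] = []
    min_right = np.inf
    for lo, hi in reversed(intervals):  # lefts descending; per left, rights descending
        if hi < min_right:
            # smallest right so far for this left, and nothing nested inside
            if not minimal or minimal[-1][0] != lo:
                minimal.append((lo, hi))
            else:
                minimal[-1] = (lo, hi)
            min_right = hi
    minimal.reverse()
    chosen: list[tuple[int, int]] = []
    last_right = -np.inf
    for lo, hi in sorted(minimal, key=lambda lr: lr[1]):
        if lo >= last_right:  # open intervals sharing an endpoint are disjoint
            chosen.append((lo, hi))
            last_right = hi
    return RecombinationScan(len(chosen), tuple(chosen), tuple(minimal))
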