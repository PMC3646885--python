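"""LD measures, permutation tests, and Hudson–Kaplan localization."""

import numpy as np
import pytest

from mhcscan.alignment_io import CodonAlignment
from mhcscan.errors import DegenerateLDError, InsufficientDataError
from mhcscan.ld_recombination import (
    biallelic_segregating_sites,
    hudson_kaplan_scan,
    pairwise_ld,
    permutation_test,
    recombination_tests,
    significance_stars,
)


def test_pairwise_ld_perfect_association():
    site = np.array([0, 0, 1, 1])
    r2, dprime, g4 = pairwise_ld(site, site)
    assert r2 == pytest.approx(1.0)
    assert dprime == pytest.approx(1.0)
    assert g4 == 1  # only two gametes -> compatible


def test_pairwise_ld_four_gametes():
    a = np.array([0, 0, 1, 1])
    b = np.array([0, 1, 0, 1])
    r2, dprime, g4 = pairwise_ld(a, b)
    assert r2 == pytest.approx(0.0)
    assert dprime == pytest.approx(0.0)
    assert g4 == 0  # all four gametes present -> incompatible


def test_pairwise_ld_rejects_monomorphic():
    with pytest.raises(DegenerateLDError):
        pairwise_ld(np.array([0, 0, 0, 0]), np.array([0, 1, 0, 1]))


def test_biallelic_site_extraction():
    # column 3 biallelic, column 7 triallelic, column 9 biallelic
    aln = CodonAlignment(
        ("a", "b", "c"), ("TTTAAAGGG", "TTCAAACGC", "TTTAAAAGG")
    )
    sites = biallelic_segregating_sites(aln, aln.total_region())
    assert sites.positions.tolist() == [3, 9]
    assert sites.n_multiallelic == 1
    assert sites.matrix.shape == (2, 3)


def test_permutation_test_requires_three_sites():
    aln = CodonAlignment(("a", "b"), ("TTTAAA", "TTCAAA"))
    with pytest.raises(InsufficientDataError):
        permutation_test(aln, aln.total_region(), "r2", n_perm=10, seed=0)


def test_permutation_test_degenerate_values():
    # three perfectly associated sites: all r2 values equal 1 -> no variance
    aln = CodonAlignment(
        ("a", "b", "c", "d"),
        ("AAAAAAAAA", "AACAACAAC", "AAAAAAAAA", "AACAACAAC"),
    )
    with pytest.raises(DegenerateLDError):
        permutation_test(aln, aln.total_region(), "r2", n_perm=10, seed=0)


@pytest.fixture()
def recombinant_alignment():
    """Six haplotypes over four biallelic sites with LD decaying in distance."""
    return CodonAlignment(
        ("h1", "h2", "h3", "h4", "h5", "h6"),
        (
            "AAATTTAAATTT",
            "CAATTTAAATTG",
            "AACTTTAAATTT",
            "CACTTGAAATTG",
            "AAATTGACATTT",
            "CACTTTACATTG",
        ),
    )


def test_permutation_test_deterministic(recombinant_alignment):
    region = recombinant_alignment.total_region()
    a = permutation_test(recombinant_alignment, region, "r2", n_perm=500, seed=11)
    b = permutation_test(recombinant_alignment, region, "r2", n_perm=500, seed=11)
    assert a.correlation == b.correlation
    assert a.p_value == b.p_value
    assert 0.0 < a.p_value <= 1.0
    assert a.n_sites >= 3


def test_permutation_test_exhaustive_matches_large_mc(recombinant_alignment):
    region = recombinant_alignment.total_region()
    exact = permutation_test(recombinant_alignment, region, "r2", exhaustive=True)
    mc = permutation_test(recombinant_alignment, region, "r2", n_perm=40_000, seed=3)
    assert exact.correlation == pytest.approx(mc.correlation)
    assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)


def test_permutation_test_keep_pairs(recombinant_alignment):
    region = recombinant_alignment.total_region()
    res = permutation_test(
        recombinant_alignment, region, "Dprime", n_perm=100, seed=0, keep_pairs=True
    )
    df = res.site_pairs
    assert df is not None
    assert set(df.columns) == {"pos_i", "pos_j", "distance", "Dprime"}
    assert len(df) == res.n_pairs


def test_significance_stars():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.2) == ""


def test_recombination_tests_reports_degenerate_rows():
    aln = CodonAlignment(("a", "b"), ("TTTAAA", "TTCAAA"))
    df = recombination_tests(aln, [aln.total_region()], n_perm=10, seed=0)
    assert len(df) == 3
    assert df["note"].str.startswith("not testable").all()
    assert df["p_value"].isna().all()


def test_hudson_kaplan_adjacent_incompatibilities():
    # sites at nt 1, 2, 3; pairs (1,2) and (2,3) incompatible, (1,3) compatible
    aln = CodonAlignment(
        ("a", "b", "c", "d"), ("AAA", "ACA", "CAC", "CCC")
    )
    scan = hudson_kaplan_scan(aln, aln.total_region())
    assert scan.minimal_intervals == ((1, 2), (2, 3))
    assert scan.intervals == ((1, 2), (2, 3))  # open intervals -> disjoint
    assert scan.rm == 2
    assert scan.overlaps(1.5)
    assert scan.overlaps(2.5)
    assert not scan.overlaps(0.5)
    assert not scan.overlaps(2.0)  # endpoints are exclusive


def test_hudson_kaplan_drops_nested_intervals():
    # (1,2) and (1,3) incompatible; (1,3) contains (1,2) and is dropped
    aln = CodonAlignment(
        ("a", "b", "c", "d"), ("AAA", "ACC", "CAA", "CCC")
    )
    scan = hudson_kaplan_scan(aln, aln.total_region())
    assert scan.minimal_intervals == ((1, 2),)
    assert scan.rm == 1


def test_hudson_kaplan_no_incompatibility():
    aln = CodonAlignment(("a", "b", "c"), ("AAA", "ACA", "CCA"))
    scan = hudson_kaplan_scan(aln, aln.total_region())
    assert scan.rm == 0
    assert scan.intervals == ()
    assert not scan.overlaps(1.5)
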