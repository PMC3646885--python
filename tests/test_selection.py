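"""Sitewise selection scan: counts, event inference, posteriors, results."""

import numpy as np
import pytest

from mhcscan.alignment_io import AlleleFrequencyTable, CodonAlignment, RegionSpec
from mhcscan.errors import InsufficientDataError, InvalidCodonError
from mhcscan.sitewise_selection import (
    CodonCounts,
    CodonEvents,
    SitewiseSelectionModel,
    classify_probability,
    codon_diff_counts,
    codon_event_counts,
    event_omega_posterior,
    omega_posterior,
    selection_profile,
)


def test_codon_diff_counts_synonymous_pair():
    aln = CodonAlignment(("a", "b"), ("TTT", "TTC"))
    counts = codon_diff_counts(aln, None, 1)
    assert counts.sd == pytest.approx(1.0)
    assert counts.nd == pytest.approx(0.0)
    assert counts.s_sites == pytest.approx(1 / 3)
    assert counts.n_sites == pytest.approx(8 / 3)
    assert counts.pairs_used == 1
    assert counts.n_alleles == 2


def test_codon_diff_counts_frequency_weighting():
    aln = CodonAlignment(("a", "b", "c"), ("TTT", "TTC", "TTA"))
    uniform = codon_diff_counts(aln, None, 1)
    skewed = codon_diff_counts(
        aln, AlleleFrequencyTable({"a": 0.98, "b": 0.01, "c": 0.01}), 1
    )
    # a-b is synonymous, a-c and b-c nonsynonymous; weighting toward a
    # shifts the mean toward the a-involved pairs but bounds stay [0, 3]
    assert 0.0 <= skewed.nd <= 3.0
    assert uniform.nd == pytest.approx((0 + 1 + 1) / 3)
    assert uniform.sd == pytest.approx(1 / 3)


def test_codon_diff_counts_skips_gapped_and_requires_two():
    aln = CodonAlignment(("a", "b", "c"), ("TTT", "---", "NNN"))
    with pytest.raises(InsufficientDataError):
        codon_diff_counts(aln, None, 1)
    # zero-frequency alleles are excluded
    aln2 = CodonAlignment(("a", "b"), ("TTT", "TTC"))
    with pytest.raises(InsufficientDataError):
        codon_diff_counts(aln2, AlleleFrequencyTable({"a": 1.0, "b": 0.0}), 1)


def test_codon_event_counts_single_derived_change():
    # five identical alleles, one carries a nonsynonymous change at codon 2:
    # parsimony must infer exactly one event regardless of allele count
    base = "TTTAAA"
    derived = "TTTACA"  # AAA (Lys) -> ACA (Thr), nonsynonymous
    aln = CodonAlignment(
        ("a", "b", "c", "d", "e"), (base, base, base, base, derived)
    )
    events = codon_event_counts(aln, boundary_codon=None)
    assert set(events) == {1, 2}
    assert events[1].nd == 0.0 and events[1].sd == 0.0
    assert events[2].nd == pytest.approx(1.0)
    assert events[2].sd == pytest.approx(0.0)
    assert events[2].n_changes == 1
    assert events[2].n_alleles == 5


def test_codon_event_counts_missing_data_is_wildcard():
    base = "TTTAAA"
    aln = CodonAlignment(
        ("a", "b", "c", "d"), (base, base, "TTT---", "TTTAGA")
    )
    events = codon_event_counts(aln, boundary_codon=None)
    # gapped allele never contributes a change; AAA->AGA (Lys->Arg) is one event
    assert events[2].nd == pytest.approx(1.0)
    assert events[2].n_alleles == 3


def test_codon_event_counts_omits_codons_without_two_states():
    aln = CodonAlignment(("a", "b", "c"), ("TTTAAA", "TTT---", "TTTNNN"))
    events = codon_event_counts(aln, boundary_codon=None)
    assert set(events) == {1}


def test_event_counts_recurrent_change_counted_per_branch():
    # two independent derived alleles sharing no ancestry for the change:
    # parsimony on any tree needs at least 2 events for this pattern
    aln = CodonAlignment(
        ("a", "b", "c", "d", "e", "f"),
        ("AAA", "AAA", "AAC", "AAA", "AAA", "AAG"),
    )
    events = codon_event_counts(aln, boundary_codon=None)
    assert events[1].nd + events[1].sd >= 2.0


def test_omega_posterior_bounds_and_errors():
    counts = CodonCounts(codon=1, nd=2.0, sd=0.5, n_sites=2.5, s_sites=0.5,
                         pairs_used=3, n_alleles=3)
    post = omega_posterior(counts, seed=0)
    assert 0.0 <= post.p_gt1 <= 1.0
    assert post.hpd_lo <= post.omega_median <= post.hpd_hi
    assert not post.prior_only
    bad = CodonCounts(codon=1, nd=0.0, sd=0.0, n_sites=0.0, s_sites=0.0,
                      pairs_used=0, n_alleles=2)
    with pytest.raises(InvalidCodonError):
        omega_posterior(bad, seed=0)


def test_event_omega_posterior_monotone_in_nd():
    rng = np.random.default_rng(0)
    lam_draws = rng.gamma(10.0, 1.0 / 100.0, size=5000)
    lam_hat = 0.1
    p = []
    for nd in (0.0, 2.0, 8.0):
        ev = CodonEvents(codon=1, nd=nd, sd=1.0, n_sites=2.5, s_sites=0.5,
                         n_changes=int(nd), n_alleles=10)
        post = event_omega_posterior(ev, lam_draws, lam_hat, seed=1)
        p.append(post.p_gt1)
    assert p[0] < p[1] < p[2]
    # no nonsynonymous events cannot reach the lowest support tier
    assert p[0] < 0.95


def test_event_omega_posterior_no_data_reverts_to_prior():
    # omega ~ Gamma(0.5, rate 0.5) has P(omega > 1) ~ 0.317; with lambda*n
    # near zero the posterior should sit near the prior
    lam_draws = np.full(2000, 1e-9)
    ev = CodonEvents(codon=1, nd=0.0, sd=0.0, n_sites=1e-6, s_sites=0.5,
                     n_changes=0, n_alleles=5)
    post = event_omega_posterior(ev, lam_draws, 1e-9, seed=0)
    assert post.p_gt1 == pytest.approx(0.3173, abs=0.01)
    assert post.prior_only
    assert post.tier == "none"


def test_classify_probability_tiers():
    assert classify_probability(0.2) == "none"
    assert classify_probability(0.96) == "0.95"
    assert classify_probability(0.995) == "0.99"
    assert classify_probability(0.9999) == "0.999"


def test_fit_is_deterministic(small_dataset):
    model = SitewiseSelectionModel(
        small_dataset.alignment,
        small_dataset.frequencies,
        boundary_codon=small_dataset.config.boundary_codon,
    )
    a = model.fit(n_samples=1000, seed=5)
    b = model.fit(n_samples=1000, seed=5)
    assert a.to_frame().equals(b.to_frame())
    assert a.lambda_hat == b.lambda_hat


def test_results_interface(small_dataset, tmp_path):
    res = selection_profile(
        small_dataset.alignment,
        small_dataset.frequencies,
        seed=2,
        n_samples=1000,
        boundary_codon=small_dataset.config.boundary_codon,
    )
    df = res.to_frame()
    assert {"codon", "Nd", "Sd", "p_gt1", "tier", "omega_median"} <= set(df.columns)
    assert res.codons == sorted(res.posteriors)
    codons, samples = res.samples_matrix()
    assert samples.shape == (len(codons), 1000)
    region = RegionSpec("total", 1, small_dataset.config.n_codons)
    assert np.isfinite(res.region_mean_omega(region))
    assert "pooled synonymous rate" in res.summary()
    out = tmp_path / "scan.tsv"
    res.to_tsv(out)
    assert out.exists()
    flagged = res.selected_codons(0.95)
    assert all(res.posteriors[c].p_gt1 >= 0.95 for c in flagged)


def test_fit_requires_data():
    aln = CodonAlignment(("a", "b"), ("---", "---"))
    with pytest.raises(InsufficientDataError):
        SitewiseSelectionModel(aln, boundary_codon=None).fit(n_samples=100, seed=0)
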