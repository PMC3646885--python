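"""Synthetic-data generator: determinism, validity, and ground-truth bookkeeping."""

import numpy as np
import pytest

from mhcscan import ng86
from mhcscan.alignment_io import read_codon_alignment, read_frequencies, read_genotypes
from mhcscan.errors import SimulationError
from mhcscan.synthetic_data import SimulationConfig, simulate_dataset, write_dataset

SMALL = dict(n_codons=30, boundary_codon=15, n_alleles=8, n_individuals=8,
             mutations_per_allele=4.0, selected_codons=(3, 7, 11))


def test_config_validation():
    with pytest.raises(SimulationError):
        SimulationConfig(seed=0, n_codons=30, boundary_codon=30)
    with pytest.raises(SimulationError):
        SimulationConfig(seed=0, recomb_rate_interdomain=1.5)
    with pytest.raises(SimulationError):
        SimulationConfig(seed=0, omega_background=0.0)
    with pytest.raises(SimulationError):
        SimulationConfig(seed=0, n_codons=30, boundary_codon=15,
                         selected_codons=(40,))


def test_omega_profile():
    cfg = SimulationConfig(seed=0, n_codons=30, boundary_codon=15,
                           selected_codons=(3, 7), omega_background=0.25,
                           omega_selected=4.0)
    profile = cfg.omega_profile
    assert len(profile) == 30
    assert profile[3] == 4.0 and profile[7] == 4.0
    assert profile[1] == 0.25


def test_simulation_is_deterministic():
    cfg = SimulationConfig(seed=99, **SMALL)
    a = simulate_dataset(cfg)
    b = simulate_dataset(cfg)
    assert a.alignment.sequences == b.alignment.sequences
    assert a.frequencies.frequencies == b.frequencies.frequencies
    assert a.genotypes.genotypes == b.genotypes.genotypes
    assert a.truth.crossovers == b.truth.crossovers


def test_alignment_validity():
    ds = simulate_dataset(SimulationConfig(seed=5, **SMALL))
    aln = ds.alignment
    assert aln.n_sequences == SMALL["n_alleles"]
    assert aln.length_nt == 3 * SMALL["n_codons"]
    assert len(set(aln.sequences)) == aln.n_sequences  # all distinct
    for idx in range(aln.n_sequences):
        for c in range(1, aln.codon_count + 1):
            assert aln.codon(idx, c) not in ng86.STOP_CODONS


def test_population_tables_consistent():
    ds = simulate_dataset(SimulationConfig(seed=11, **SMALL))
    assert sum(ds.frequencies.frequencies.values()) == pytest.approx(1.0)
    assert set(ds.frequencies.frequencies) == set(ds.alignment.allele_ids)
    assert ds.genotypes.n_individuals == SMALL["n_individuals"]
    for ind in ds.genotypes.individual_ids:
        alleles = ds.genotypes.alleles_of(ind)
        assert 1 <= len(alleles) <= 2
        assert set(alleles) <= set(ds.alignment.allele_ids)


def test_zero_rates_mean_strictly_vertical_inheritance():
    ds = simulate_dataset(
        SimulationConfig(seed=3, recomb_rate_interdomain=0.0,
                         recomb_rate_intradomain=0.0, **SMALL)
    )
    assert all(x == [] for x in ds.truth.crossovers.values())
    assert not any(ds.truth.is_interdomain_recombinant.values())


def test_interdomain_flag_matches_boundary_crossover():
    ds = simulate_dataset(SimulationConfig(seed=17, **SMALL))
    boundary_nt = 3 * SMALL["boundary_codon"]
    for name, flag in ds.truth.is_interdomain_recombinant.items():
        assert flag == (boundary_nt in ds.truth.crossovers[name])
    # with the default-like shuffle rate some recombinants must appear
    assert any(ds.truth.is_interdomain_recombinant.values())


def test_truth_mutation_totals():
    ds = simulate_dataset(SimulationConfig(seed=23, **SMALL))
    total = sum(ds.truth.codon_syn_counts.values()) + sum(
        ds.truth.codon_nonsyn_counts.values()
    )
    assert total == ds.truth.n_mutations_placed
    assert all(1 <= c <= SMALL["n_codons"] for c in ds.truth.codon_syn_counts)
    assert all(1 <= c <= SMALL["n_codons"] for c in ds.truth.codon_nonsyn_counts)


def test_selection_skews_nonsynonymous_fraction():
    # omega_selected >> background must raise the nonsynonymous share at
    # selected codons relative to background codons, aggregated over seeds
    sel_n = sel_s = bg_n = bg_s = 0
    overrides = dict(SMALL, selected_codons=(3, 7, 11), omega_selected=8.0,
                     omega_background=0.2)
    selected = overrides["selected_codons"]
    for seed in range(6):
        ds = simulate_dataset(SimulationConfig(seed=seed, **overrides))
        for c in range(1, SMALL["n_codons"] + 1):
            n = ds.truth.codon_nonsyn_counts.get(c, 0)
            s = ds.truth.codon_syn_counts.get(c, 0)
            if c in selected:
                sel_n, sel_s = sel_n + n, sel_s + s
            else:
                bg_n, bg_s = bg_n + n, bg_s + s
    assert sel_n / max(sel_n + sel_s, 1) > bg_n / max(bg_n + bg_s, 1)


def test_write_dataset_round_trip(tmp_path):
    ds = simulate_dataset(SimulationConfig(seed=2, **SMALL))
    paths = write_dataset(ds, tmp_path / "out")
    aln = read_codon_alignment(paths["alignment"])
    assert aln.sequences == ds.alignment.sequences
    freqs = read_frequencies(paths["frequencies"])
    for k, v in ds.frequencies.frequencies.items():
        assert freqs.frequencies[k] == pytest.approx(v)
    geno = read_genotypes(paths["genotypes"])
    assert geno.genotypes == ds.genotypes.genotypes
    assert paths["truth"].exists() and paths["config"].exists()


def test_from_dict_accepts_lists():
    d = dict(seed=1, **SMALL)
    d["selected_codons"] = [3, 7]
    cfg = SimulationConfig.from_dict(d)
    assert cfg.selected_codons == (3, 7)
    assert cfg.n_codons == SMALL["n_codons"]
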