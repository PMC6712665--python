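"""Properties of the synthetic community generator."""

import numpy as np
import pytest
from scipy import stats as sps

from emgekit.model import revcomp
from emgekit.simulate import (SimConfig, child_rng, count_motif,
                              generate_community, misassemble_tdr_as_circle,
                              reexpand_circle, simulate_abundance_matrix,
                              simulate_motif_profiles, simulate_reads,
                              simulate_reads_from_templates)
from emgekit.stats import spearman


def test_zero_phages_gives_empty_phage_set():
    truth = generate_community(SimConfig(n_phages=0, seed=1))
    assert truth.phages == []


def test_same_seed_is_byte_identical():
    cfg = SimConfig(seed=42)
    a, b = generate_community(cfg), generate_community(cfg)
    assert [c.sequence for c in a.chromosomes] == \
        [c.sequence for c in b.chromosomes]
    assert [p.sequence for p in a.plasmids] == \
        [p.sequence for p in b.plasmids]
    assert a.crispr_arrays == b.crispr_arrays
    ra, _ = simulate_reads(a, cfg)
    rb, _ = simulate_reads(b, cfg)
    assert ra == rb
    ma = simulate_abundance_matrix(a, cfg)
    mb = simulate_abundance_matrix(b, cfg)
    assert ma.counts.equals(mb.counts)


def test_different_seeds_differ():
    a = generate_community(SimConfig(seed=1))
    b = generate_community(SimConfig(seed=2))
    assert a.chromosomes[0].sequence != b.chromosomes[0].sequence


def test_phage_terminal_repeats_identical():
    truth = generate_community(SimConfig(seed=3))
    for phage in truth.phages:
        t = phage.tdr_length
        assert phage.sequence[:t] == phage.sequence[-t:]


def test_infeasible_tdr_config_rejected():
    with pytest.raises(ValueError):
        SimConfig(phage_length=(5000, 6000),
                  tdr_length=(3000, 4000)).validate()


def test_protospacers_traceable_to_resident_phage():
    truth = generate_community(SimConfig(seed=4))
    phage_by_host = {}
    for p in truth.phages:
        phage_by_host.setdefault(p.host_id, []).append(p.sequence)
    for host, spacers in truth.crispr_arrays.items():
        for sid, seq in spacers:
            if "decoy" in sid:
                continue
            assert any(seq in ph or revcomp(seq) in ph
                       for ph in phage_by_host[host])


# ------------------------------------------------------------------ reads

def test_read_count_scales_with_depth_and_length():
    cfg = SimConfig(seed=5, read_length_sigma=0.0)
    template = [("g", "ACGT" * 25_000, "circular", 1.0)]  # 100 kb
    _, alns = simulate_reads_from_templates(
        template, cfg, error_rate=0.0, depth=10.0,
        rng=child_rng(5, "count"))
    expected = 10.0 * 100_000 / 8_000  # depth * L / mean read length
    assert abs(len(alns) - expected) < 4 * np.sqrt(expected)


def test_error_free_reads_are_exact_substrings():
    cfg = SimConfig(seed=6)
    truth = generate_community(cfg)
    reads, alns = simulate_reads(truth, cfg, error_rate=0.0)
    seqs = {e[0]: s for e, s in zip(
        truth.elements(),
        [c.sequence for c in truth.chromosomes]
        + [p.sequence for p in truth.plasmids]
        + [p.sequence for p in truth.phages])}
    by_id = dict(reads)
    for aln in alns[:200]:
        tpl = seqs[aln.target_id]
        doubled = tpl + tpl
        assert by_id[aln.query_id] == \
            doubled[aln.target_start:aln.target_end]


def test_no_read_spans_from_right_tdr_into_left():
    # linear templates have no junction between the two repeat copies
    cfg = SimConfig(seed=7)
    truth = generate_community(cfg)
    _, alns = simulate_reads(truth, cfg, error_rate=0.0)
    phage_len = {p.id: len(p.sequence) for p in truth.phages}
    for aln in alns:
        if aln.target_id in phage_len:
            assert aln.target_end <= phage_len[aln.target_id]
            assert aln.target_start >= 0


def test_read_sampling_proportional_to_length_times_copy():
    # chi-square goodness of fit on ~1e4 reads
    cfg = SimConfig(seed=8, read_length_sigma=0.0, min_read_length=100,
                    read_length_median=1000.0)
    templates = [("a", "A" * 40_000, "circular", 1.0),
                 ("b", "C" * 20_000, "circular", 2.0),
                 ("c", "G" * 40_000, "circular", 2.5)]
    _, alns = simulate_reads_from_templates(
        templates, cfg, error_rate=0.0, depth=60.0,
        rng=child_rng(8, "gof"))
    counts = {"a": 0, "b": 0, "c": 0}
    for aln in alns:
        counts[aln.target_id] += 1
    total = sum(counts.values())
    assert total > 9_000
    weights = np.array([40_000 * 1.0, 20_000 * 2.0, 40_000 * 2.5])
    expected = weights / weights.sum() * total
    stat, p = sps.chisquare([counts["a"], counts["b"], counts["c"]],
                            expected)
    assert p > 0.001


# -------------------------------------------------------- mis-assembly

def test_misassembled_circle_arithmetic():
    truth = generate_community(SimConfig(seed=9))
    phage = truth.phages[0]
    circle, interval = misassemble_tdr_as_circle(phage)
    assert circle.length == len(phage.sequence) - phage.tdr_length
    assert interval == (0, phage.tdr_length)


def test_misassemble_requires_a_tdr():
    class NoTDR:
        sequence = "ACGT" * 100
        tdr_length = 0
    with pytest.raises(ValueError):
        misassemble_tdr_as_circle(NoTDR())


def test_reexpansion_inverts_misassembly():
    truth = generate_community(SimConfig(seed=10))
    for phage in truth.phages:
        circle, interval = misassemble_tdr_as_circle(phage)
        assert reexpand_circle(circle, interval) == phage.sequence


# ------------------------------------------------------- motif profiles

def test_plasmid_inherits_host_motif_methylation():
    cfg = SimConfig(seed=11)
    truth = generate_community(cfg)
    profiles = simulate_motif_profiles(truth, cfg)
    host = truth.host_of()
    motifs_of = {c.id: set(c.motifs) for c in truth.chromosomes}
    meth_ipds, unmeth_ipds = [], []
    for p in profiles:
        if p.sequence_id not in host or np.isnan(p.mean_ipd_ratio):
            continue
        if p.motif in motifs_of[host[p.sequence_id]]:
            meth_ipds.append(p.mean_ipd_ratio)
        else:
            unmeth_ipds.append(p.mean_ipd_ratio)
    assert np.mean(meth_ipds) > 3.0
    assert np.mean(unmeth_ipds) < 2.0


def test_methylated_draws_binarize_high():
    # Normal(4.0, 0.3) exceeds the 2.5 cutoff in >= 99% of draws
    rng = child_rng(12, "binarize")
    draws = rng.normal(4.0, 0.3, size=1000)
    assert np.mean(draws > 2.5) >= 0.99


def test_sequence_without_motif_occurrence_is_missing():
    cfg = SimConfig(seed=13)
    truth = generate_community(cfg)
    profiles = simulate_motif_profiles(truth, cfg)
    seqs = {c.id: c.sequence for c in truth.chromosomes}
    seqs.update({p.id: p.sequence for p in truth.plasmids})
    seqs.update({p.id: p.sequence for p in truth.phages})
    for p in profiles:
        occ = count_motif(seqs[p.sequence_id], p.motif)
        assert (occ == 0) == np.isnan(p.mean_ipd_ratio)


def test_count_motif_handles_iupac_and_overlap():
    assert count_motif("CCAGGCCTGG", "CCWGG") == 2
    assert count_motif("AAAA", "AA") == 3
    assert count_motif("GATC", "GATC") == 1


# ----------------------------------------------------------- abundance

def test_abundance_columns_sum_to_read_budget():
    cfg = SimConfig(seed=14, n_samples=10)
    truth = generate_community(cfg)
    matrix = simulate_abundance_matrix(truth, cfg)
    sums = matrix.counts.sum(axis=0)
    assert (sums == cfg.total_reads_per_sample).all()


def test_zero_coupling_noise_gives_near_perfect_correlation():
    cfg = SimConfig(seed=15, coupling_noise_sd=0.0, n_samples=30)
    truth = generate_community(cfg)
    matrix = simulate_abundance_matrix(truth, cfg)
    norm = matrix.normalized()
    host = truth.host_of()
    rhos = [spearman(norm.loc[p.id], norm.loc[host[p.id]])
            for p in truth.plasmids]
    assert np.median(rhos) > 0.98


def test_emge_couples_to_its_host_not_to_others():
    rho_host, rho_other = [], []
    for seed in range(5):
        cfg = SimConfig(seed=100 + seed)
        truth = generate_community(cfg)
        norm = simulate_abundance_matrix(truth, cfg).normalized()
        host = truth.host_of()
        for p in truth.plasmids:
            for c in truth.chromosomes:
                rho = spearman(norm.loc[p.id], norm.loc[c.id])
                (rho_host if c.id == host[p.id] else rho_other).append(rho)
    assert np.median(rho_host) > 0.7
    assert np.median(rho_other) < 0.3
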