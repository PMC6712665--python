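"""Clustering, abundance quantification, composition and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from emgekit.model import AlignmentRecord
from emgekit.quantify import (arg_summary, cluster_abundance, cluster_emges,
                              cog_enrichment, composition_concordance,
                              composition_from_contigs,
                              emge_to_chromosome_ratio, filter_by_coverage,
                              mapped_coverage)
from emgekit.model import GeneAnnotation
from emgekit.simulate import child_rng
from emgekit.stats import fisher_exact_2x2, qvalues, rank_sum_test, spearman

from oracles import (coverage_brute, fisher_brute, rank_sum_brute,
                     transitive_closure_clusters)


def aln(q, t, qs, qe, ts, te, ident=1.0):
    return AlignmentRecord(q, t, qs, qe, ts, te, identity=ident)


# ------------------------------------------------------------- coverage

def test_mapped_coverage_interval_union():
    a = [aln("r1", "e", 0, 300, 0, 300), aln("r2", "e", 0, 400, 200, 600)]
    assert mapped_coverage(a, 1000) == pytest.approx(0.6)
    assert mapped_coverage([aln("r", "e", 0, 590, 0, 590)], 1000) == \
        pytest.approx(0.59)
    assert mapped_coverage([], 1000) == 0.0


def test_coverage_exclusion_boundary():
    alns = {"keep": [aln("r", "keep", 0, 600, 0, 600)],
            "drop": [aln("r", "drop", 0, 599, 0, 599)]}
    kept = filter_by_coverage(alns, {"keep": 1000, "drop": 1000})
    assert kept == ["keep"]


def test_mapped_coverage_equals_position_marking_oracle():
    rng = child_rng(89, "coverage")
    for _ in range(20):
        length = int(rng.integers(100, 2000))
        ivs = []
        for i in range(int(rng.integers(0, 15))):
            s = int(rng.integers(0, length))
            e = min(length, s + int(rng.integers(1, 400)))
            if e > s:
                ivs.append((s, e))
        records = [aln(f"r{i}", "e", 0, e - s, s, e)
                   for i, (s, e) in enumerate(ivs)]
        assert mapped_coverage(records, length) == \
            pytest.approx(coverage_brute(ivs, length))


# ------------------------------------------------------------ clustering

def test_cluster_rules_on_simple_pairs():
    lengths = {"big": 100_000, "mid": 80_000, "small": 40_000}
    # big-mid: 95% identity, 85% coverage of the shorter -> one cluster
    pw = [aln("mid", "big", 0, 68_000, 0, 68_000, ident=0.95)]
    clusters = cluster_emges(pw, lengths)
    members = {frozenset(c.members) for c in clusters}
    assert frozenset({"big", "mid"}) in members
    assert frozenset({"small"}) in members  # singleton
    rep = next(c for c in clusters if "big" in c.members)
    assert rep.representative == "big"
    assert rep.representative_length == 100_000


def test_cluster_length_ratio_rule():
    # identical sequence content but length ratio 0.5 < 0.7: no cluster
    lengths = {"a": 100_000, "b": 50_000}
    pw = [aln("b", "a", 0, 50_000, 0, 50_000, ident=0.95)]
    clusters = cluster_emges(pw, lengths)
    assert all(len(c.members) == 1 for c in clusters)


def test_cluster_missing_length_is_error():
    with pytest.raises(ValueError, match="missing length"):
        cluster_emges([aln("x", "y", 0, 10, 0, 10)], {"x": 100})


def test_clusters_equal_transitive_closure_oracle():
    rng = child_rng(97, "clusters")
    n = 50
    lengths = {f"e{i}": int(rng.integers(5_000, 50_000)) for i in range(n)}
    all_pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    chosen = rng.choice(len(all_pairs), size=120, replace=False)
    records = []
    for idx in chosen:
        a, b = all_pairs[int(idx)]
        a_id, b_id = f"e{a}", f"e{b}"
        ident = float(rng.uniform(0.80, 1.0))
        shorter = min(lengths[a_id], lengths[b_id])
        cov = float(rng.uniform(0.4, 1.0))
        span = max(1, int(cov * shorter))
        records.append(aln(a_id, b_id, 0, span, 0, span, ident=ident))
    clusters = cluster_emges(records, lengths)
    got = {frozenset(c.members) for c in clusters}

    # oracle: re-derive the similarity relation independently, then close
    similar = []
    for r in records:
        la, lb = lengths[r.query_id], lengths[r.target_id]
        cov = (r.query_end - r.query_start) / min(la, lb)
        ratio = min(la, lb) / max(la, lb)
        if r.identity >= 0.90 and cov >= 0.70 and ratio >= 0.7:
            similar.append((r.query_id, r.target_id))
    want = transitive_closure_clusters(similar, list(lengths))
    assert got == want


def test_near_duplicate_pairs_stay_distinct_when_thresholds_fail():
    # two homologous but distinct replicons: high identity over only half
    # the shorter one must NOT collapse into one cluster
    lengths = {"p1": 60_000, "p2": 55_000}
    pw = [aln("p2", "p1", 0, 27_000, 0, 27_000, ident=0.99)]
    clusters = cluster_emges(pw, lengths)
    assert len(clusters) == 2


# ------------------------------------------------------- quantification

def read_aln(rid, member, ident, block=1000):
    matches = int(round(ident * block))
    return AlignmentRecord(rid, member, 0, block, 0, block,
                           identity=matches / block, aligned_length=block)


def make_cluster(cid, members, rep, rep_len):
    from emgekit.model import EMGECluster
    return EMGECluster(cluster_id=cid, members=frozenset(members),
                       representative=rep, representative_length=rep_len)


def test_cluster_abundance_normalises_by_representative_length():
    clusters = [make_cluster("C1", {"m1"}, "m1", 50_000)]
    sample = {"s1": [read_aln(f"r{i}", "m1", 0.99) for i in range(500)]}
    ab = cluster_abundance(sample, clusters)
    assert ab.loc["C1", "s1"] == pytest.approx(500 / 50.0)  # reads per kb


def test_cluster_abundance_identity_threshold_and_dedup():
    clusters = [make_cluster("C1", {"m1", "m2"}, "m1", 10_000)]
    sample = {"s1": [
        read_aln("r1", "m1", 0.99), read_aln("r1", "m2", 0.97),  # once
        read_aln("r2", "m1", 0.94),                              # below 95%
    ]}
    ab = cluster_abundance(sample, clusters)
    assert ab.loc["C1", "s1"] == pytest.approx(1 / 10.0)


def test_emge_to_chromosome_ratio_closed_form():
    assert emge_to_chromosome_ratio(100, 10_000, 50, 5_000) == \
        pytest.approx(1.0)
    assert emge_to_chromosome_ratio(2_000, 1e4, 1e4, 5e6) == \
        pytest.approx(100.0)
    with pytest.raises(ValueError):
        emge_to_chromosome_ratio(100, 1e4, 0, 5e6)


# -------------------------------------------------------- composition

def gene(contig, taxon, length=1000, i=[0]):
    i[0] += 1
    return GeneAnnotation(gene_id=f"g{i[0]}", contig_id=contig, start=0,
                          end=length, taxon=taxon)


def test_composition_single_taxon_is_one():
    genes = [gene("c1", ("P", "GenusA", "s"))]
    comp = composition_from_contigs(genes, {"c1": 10.0})
    assert comp.to_dict() == {"GenusA": 1.0}


def test_composition_weights_by_depth():
    genes = [gene("c1", ("P", "GenusA", "s")), gene("c2", ("P", "GenusB", "s"))]
    comp = composition_from_contigs(genes, {"c1": 10.0, "c2": 30.0})
    assert comp["GenusA"] == pytest.approx(0.25)
    assert comp["GenusB"] == pytest.approx(0.75)


def test_composition_empty_is_error():
    with pytest.raises(ValueError):
        composition_from_contigs([], {})


def test_composition_concordance():
    a = pd.Series({"x": 0.7, "y": 0.3})
    assert composition_concordance(a, a) == pytest.approx(1.0)
    b = pd.Series({"x": 1.0})
    c = pd.Series({"y": 1.0})
    assert composition_concordance(b, c) == pytest.approx(-1.0)
    const = pd.Series({"x": 0.5, "y": 0.5})
    assert math.isnan(composition_concordance(const, pd.Series({"x": 0.5,
                                                                "y": 0.5})))


# --------------------------------------------------------- enrichment

def cog_gene(contig, cog, cat, i=[0], arg=False):
    i[0] += 1
    return GeneAnnotation(gene_id=f"cg{i[0]}", contig_id=contig, start=0,
                          end=900, cog_id=cog, cog_category=cat, is_arg=arg)


def test_fisher_identical_proportions_p_one():
    assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)


def test_fisher_matches_enumeration_oracle():
    assert fisher_exact_2x2([[10, 0], [0, 10]]) == \
        pytest.approx(fisher_brute([[10, 0], [0, 10]]), abs=1e-10)
    assert fisher_brute([[10, 0], [0, 10]]) == \
        pytest.approx(2 / math.comb(20, 10))
    rng = child_rng(101, "fisher")
    for _ in range(60):
        t = rng.integers(0, 16, size=4).reshape(2, 2)
        if t.sum() == 0:
            continue
        assert fisher_exact_2x2(t) == pytest.approx(fisher_brute(t),
                                                    abs=1e-10)


def test_rank_sum_matches_exact_permutation_oracle():
    rng = child_rng(103, "wilcoxon")
    for _ in range(25):
        n = int(rng.integers(2, 8))
        m = int(rng.integers(2, 8))
        x = rng.integers(0, 10, size=n).astype(float)
        y = rng.integers(0, 10, size=m).astype(float)
        assert rank_sum_test(x, y) == pytest.approx(rank_sum_brute(x, y),
                                                    abs=1e-12)
    # fully separated small groups
    assert rank_sum_test([1, 2, 3], [10, 11, 12]) == \
        pytest.approx(rank_sum_brute([1, 2, 3], [10, 11, 12]), abs=1e-12)


def test_qvalues_are_bh_monotone():
    p = np.array([0.01, 0.02, 0.03, 0.5, 0.9])
    q = qvalues(p)
    assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)
    assert np.all(q >= p - 1e-12)


def test_cog_enrichment_plasmid_only_flag():
    plasmid = [cog_gene("p", "COG4264", "P") for _ in range(4)] + \
        [cog_gene("p", "COG0001", "G") for _ in range(16)]
    chrom = [cog_gene("c", "COG0001", "G") for _ in range(100)]
    result = cog_enrichment(plasmid, chrom)
    row = result["cogs"].set_index("cog_id").loc["COG4264"]
    assert bool(row.plasmid_only)
    assert row.enriched_in == "plasmid"
    cat = result["categories"].set_index("category")
    assert "P" in cat.index and "G" in cat.index


def test_cog_enrichment_empty_table_is_error():
    with pytest.raises(ValueError):
        cog_enrichment([], [cog_gene("c", "COG0001", "G")])


def test_arg_summary_rank_sum():
    genes = [cog_gene("p1", "COG1", "G", arg=True),
             cog_gene("p2", "COG1", "G")]
    abundance = pd.Series({"p1": 1.0, "p2": 5.0, "p3": 6.0, "p4": 7.0})
    out = arg_summary(genes, abundance)
    assert out["n_arg_positive"] == 1 and out["n_arg_negative"] == 3
    assert 0 < out["p_value"] <= 1
    with pytest.raises(ValueError):
        arg_summary([cog_gene("p1", "COG1", "G")], pd.Series({"p1": 1.0}))
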