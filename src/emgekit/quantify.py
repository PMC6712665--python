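"""Clustering, quantification and functional comparison of mobile elements.

Elements are dereplicated into clusters of mutually similar sequences
(identity >= 90%, coverage of the shorter sequence >= 70%, shorter/longer
length ratio >= 0.7; single linkage over the similarity graph).  Read
counts per cluster are normalised by the length of the longest
representative.  The element-per-chromosome ratio converts read counts
into molecule counts through average element and chromosome sizes.
Functional comparison contrasts COG frequencies between plasmid and
chromosome gene sets with Fisher's exact test and FDR q-values.
"""

from __future__ import annotations

from collections import defaultdict

import networkx as nx
import numpy as np
import pandas as pd

from .model import (AlignmentRecord, EMGECluster, GeneAnnotation,
                    interval_union_length)
from .stats import fisher_exact_2x2, pearson, qvalues, rank_sum_test


# ------------------------------------------------------------- coverage

def mapped_coverage(alignments: list[AlignmentRecord],
                    element_length: int) -> float:
    """Breadth of coverage: fraction of the element covered by >= 1
    aligned interval (union of target intervals)."""
    ivs = [(a.target_start, min(a.target_end, element_length))
           for a in alignments]
    return interval_union_length(ivs) / element_length


def filter_by_coverage(alignments_by_element: dict[str, list[AlignmentRecord]],
                       lengths: dict[str, int],
                       min_coverage: float = 0.60) -> list[str]:
    """Elements retained for quantification: mapped coverage >= 60% by
    default (poorly and unevenly covered elements excluded)."""
    kept = []
    for el, length in sorted(lengths.items()):
        cov = mapped_coverage(alignments_by_element.get(el, []), length)
        if cov >= min_coverage:
            kept.append(el)
    return kept


# ------------------------------------------------------------ clustering

def _pair_similarity(alignments: list[AlignmentRecord],
                     len_q: int, len_t: int) -> tuple[float, float]:
    """(weighted mean identity, coverage of the shorter sequence)."""
    wsum = sum(a.aligned_length for a in alignments)
    ident = sum(a.identity * a.aligned_length for a in alignments) / wsum
    if len_q <= len_t:
        cov = interval_union_length(
            (a.query_start, a.query_end) for a in alignments) / len_q
    else:
        cov = interval_union_length(
            (a.target_start, a.target_end) for a in alignments) / len_t
    return ident, cov


def cluster_emges(pairwise: list[AlignmentRecord], lengths: dict[str, int],
                  min_identity: float = 0.90, min_coverage: float = 0.70,
                  min_length_ratio: float = 0.7) -> list[EMGECluster]:
    """Single-linkage clusters over the pairwise similarity graph.

    A pair is similar iff identity >= ``min_identity``, union coverage of
    the shorter sequence >= ``min_coverage`` and shorter/longer length
    ratio >= ``min_length_ratio``.  The representative is the longest
    member (ties broken lexicographically).
    """
    by_pair: dict[tuple[str, str], list[AlignmentRecord]] = defaultdict(list)
    for a in pairwise:
        if a.query_id == a.target_id:
            continue
        for el in (a.query_id, a.target_id):
            if el not in lengths:
                raise ValueError(f"missing length for element {el!r}")
        by_pair[tuple(sorted((a.query_id, a.target_id)))].append(a)

    graph = nx.Graph()
    graph.add_nodes_from(lengths)
    for (a_id, b_id), alns in by_pair.items():
        la, lb = lengths[a_id], lengths[b_id]
        ratio = min(la, lb) / max(la, lb)
        if ratio < min_length_ratio:
            continue
        # orient records consistently: query = a_id
        oriented = []
        for r in alns:
            if r.query_id == a_id:
                oriented.append(r)
            else:
                oriented.append(AlignmentRecord(
                    query_id=a_id, target_id=b_id,
                    query_start=r.target_start, query_end=r.target_end,
                    target_start=r.query_start, target_end=r.query_end,
                    strand=r.strand, identity=r.identity,
                    aligned_length=r.aligned_length))
        ident, cov = _pair_similarity(oriented, la, lb)
        if ident >= min_identity and cov >= min_coverage:
            graph.add_edge(a_id, b_id)

    clusters = []
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(comps):
        rep = sorted(comp, key=lambda el: (-lengths[el], el))[0]
        clusters.append(EMGECluster(
            cluster_id=f"Cluster_{i}", members=frozenset(comp),
            representative=rep, representative_length=lengths[rep]))
    return clusters


# ---------------------------------------------------------- quantification

def cluster_abundance(read_alignments_by_sample: dict[str, list[AlignmentRecord]],
                      clusters: list[EMGECluster],
                      min_identity: float = 0.95) -> pd.DataFrame:
    """Reads per cluster per sample, normalised to the representative
    length (reads per kb).

    A read counts once, for its best alignment (highest identity, then
    fewest mismatches, then lexicographic cluster id) among alignments at
    ``min_identity`` or above to any cluster member.
    """
    member_to_cluster = {m: c.cluster_id for c in clusters for m in c.members}
    counts = pd.DataFrame(0.0, index=[c.cluster_id for c in clusters],
                          columns=sorted(read_alignments_by_sample))
    for sample, alns in read_alignments_by_sample.items():
        best: dict[str, tuple] = {}
        for a in alns:
            if a.identity < min_identity:
                continue
            cl = member_to_cluster.get(a.target_id)
            if cl is None:
                continue
            mismatches = a.aligned_length - a.matches
            key = (-a.identity, mismatches, cl)
            if a.query_id not in best or key < best[a.query_id]:
                best[a.query_id] = key
        for _, (_, _, cl) in best.items():
            counts.loc[cl, sample] += 1
    rep_kb = pd.Series({c.cluster_id: c.representative_length / 1000.0
                        for c in clusters})
    return counts.div(rep_kb, axis=0)


def emge_to_chromosome_ratio(reads_emge: float, mean_emge_size: float,
                             reads_chrom: float,
                             mean_chrom_size: float) -> float:
    """Molecules of element per chromosome: read densities scaled by the
    average molecule sizes."""
    if reads_chrom <= 0:
        raise ValueError("no chromosome reads: ratio undefined")
    if min(mean_emge_size, mean_chrom_size) <= 0:
        raise ValueError("mean sizes must be positive")
    return (reads_emge / mean_emge_size) / (reads_chrom / mean_chrom_size)


# ----------------------------------------------------------- composition

def composition_from_contigs(genes: list[GeneAnnotation],
                             contig_depths: dict[str, float],
                             rank: int = 1) -> pd.Series:
    """Relative taxon abundance from annotated contigs: each gene
    contributes its contig's read depth normalised by gene length; scores
    are summed per taxon (default rank: genus) and normalised to 1."""
    scores: dict[str, float] = defaultdict(float)
    for g in genes:
        if g.taxon is None:
            continue
        depth = contig_depths.get(g.contig_id)
        if depth is None:
            raise ValueError(f"missing depth for contig {g.contig_id!r}")
        scores[g.taxon[rank]] += depth / g.length
    if not scores:
        raise ValueError("no taxon-annotated genes")
    ser = pd.Series(scores, dtype=float).sort_index()
    return ser / ser.sum()


def composition_concordance(a: pd.Series, b: pd.Series) -> float:
    """Pearson correlation of two composition vectors over the union of
    taxa (absent taxa count as 0); NaN when either is constant."""
    taxa = sorted(set(a.index) | set(b.index))
    va = a.reindex(taxa, fill_value=0.0).to_numpy()
    vb = b.reindex(taxa, fill_value=0.0).to_numpy()
    return pearson(va, vb)


# ------------------------------------------------------------- enrichment

def cog_enrichment(plasmid_genes: list[GeneAnnotation],
                   chromosome_genes: list[GeneAnnotation],
                   qvalue_method: str = "bh") -> dict[str, pd.DataFrame]:
    """Per-COG and per-category Fisher comparisons of plasmid versus
    chromosome gene sets.

    Returns ``{"cogs": ..., "categories": ...}``; COGs never seen on
    chromosomes are flagged plasmid-only.
    """
    if not plasmid_genes or not chromosome_genes:
        raise ValueError("both gene tables must be non-empty")
    n_p, n_c = len(plasmid_genes), len(chromosome_genes)

    def tally(genes, attr):
        t: dict[str, int] = defaultdict(int)
        for g in genes:
            v = getattr(g, attr)
            if v:
                t[v] += 1
        return t

    rows = []
    cogs_p, cogs_c = tally(plasmid_genes, "cog_id"), \
        tally(chromosome_genes, "cog_id")
    for cog in sorted(set(cogs_p) | set(cogs_c)):
        a, c = cogs_p.get(cog, 0), cogs_c.get(cog, 0)
        table = [[a, n_p - a], [c, n_c - c]]
        p = fisher_exact_2x2(table)
        direction = "plasmid" if a / n_p > c / n_c else \
            ("chromosome" if a / n_p < c / n_c else "none")
        rows.append((cog, a, c, direction, p, c == 0 and a > 0))
    cog_df = pd.DataFrame(rows, columns=["cog_id", "plasmid_count",
                                         "chromosome_count", "enriched_in",
                                         "p_value", "plasmid_only"])
    cog_df["q_value"] = qvalues(cog_df["p_value"].to_numpy(), qvalue_method)

    rows = []
    cats_p, cats_c = tally(plasmid_genes, "cog_category"), \
        tally(chromosome_genes, "cog_category")
    for cat in sorted(set(cats_p) | set(cats_c)):
        a, c = cats_p.get(cat, 0), cats_c.get(cat, 0)
        p = fisher_exact_2x2([[a, n_p - a], [c, n_c - c]])
        direction = "plasmid" if a / n_p > c / n_c else \
            ("chromosome" if a / n_p < c / n_c else "none")
        rows.append((cat, a, c, direction, p))
    cat_df = pd.DataFrame(rows, columns=["category", "plasmid_count",
                                         "chromosome_count", "enriched_in",
                                         "p_value"])
    return {"cogs": cog_df, "categories": cat_df}


def arg_summary(plasmid_genes: list[GeneAnnotation],
                plasmid_abundance: pd.Series) -> dict:
    """Compare abundance of ARG-positive versus ARG-negative plasmids with
    the Wilcoxon rank-sum test."""
    arg_plasmids = {g.contig_id for g in plasmid_genes if g.is_arg}
    pos = [plasmid_abundance[p] for p in plasmid_abundance.index
           if p in arg_plasmids]
    neg = [plasmid_abundance[p] for p in plasmid_abundance.index
           if p not in arg_plasmids]
    if not pos or not neg:
        raise ValueError("need both ARG-positive and ARG-negative plasmids")
    p = rank_sum_test(pos, neg)
    return {"n_arg_positive": len(pos), "n_arg_negative": len(neg),
            "median_abundance_positive": float(np.median(pos)),
            "median_abundance_negative": float(np.median(neg)),
            "p_value": p}
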