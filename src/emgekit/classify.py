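"""Plasmid/phage classification of circular contigs from gene evidence.

Evidence combined per contig: the fraction of genes with strong hits to
phage orthologous groups (POGs), the presence of plasmid-diagnostic COGs
(replication, toxin-antitoxin, type IV secretion / mobilisation families),
an optional assignment to a reference plasmid or phage by whole-sequence
similarity, and optional external classifier verdicts.  Plasmid is the
default class; a contig is called phage only on positive phage evidence,
and a reference plasmid assignment overrides a phage call (flagged as a
conflict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import AlignmentRecord, GeneAnnotation, interval_union_length

#: COG families enriched on plasmids (replication, toxin-antitoxin and
#: type IV secretion system components) used as plasmid evidence.
PLASMID_COGS = frozenset({
    "COG1475", "COG2026", "COG2126", "COG2336", "COG2948", "COG3077",
    "COG3451", "COG3505", "COG3704", "COG3736", "COG3843", "COG5527",
    "COG5655",
})

#: External phage-detector categories treated as phage evidence; the
#: remaining categories (3 and 6) are prone to false positives and are
#: ignored.
PHAGE_VERDICT_CATEGORIES = frozenset({1, 2, 4, 5})


def pog_fraction(genes: list[GeneAnnotation],
                 min_hit_coverage: float = 0.90) -> tuple[float, bool]:
    """Fraction of genes with a POG hit covering strictly more than
    ``min_hit_coverage`` of the gene.  Returns (fraction, no_genes_flag)."""
    if not genes:
        return 0.0, True
    n_hit = sum(1 for g in genes
                if g.pog_hit and g.hit_coverage > min_hit_coverage)
    return n_hit / len(genes), False


def plasmid_cog_evidence(genes: list[GeneAnnotation]) -> frozenset[str]:
    """Plasmid-diagnostic COGs detected on the contig."""
    return frozenset(g.cog_id for g in genes
                     if g.cog_id in PLASMID_COGS)


@dataclass(frozen=True)
class ReferenceAssignment:
    reference_id: str
    reference_class: str  # plasmid | phage
    identity: float
    coverage: float


def reference_assignment(cc_id: str, cc_length: int,
                         alignments: list[AlignmentRecord],
                         reference_classes: dict[str, str],
                         min_identity: float = 0.90,
                         min_coverage: float = 0.70
                         ) -> ReferenceAssignment | None:
    """Assign the contig to the best reference meeting identity and
    contig-coverage thresholds.

    Coverage is the aligned fraction of the contig (overlapping alignment
    intervals merged); identity per reference is the alignment-length
    weighted mean.  Ties break by higher identity then lexicographic
    reference id.
    """
    by_ref: dict[str, list[AlignmentRecord]] = {}
    for aln in alignments:
        if aln.query_id != cc_id:
            continue
        by_ref.setdefault(aln.target_id, []).append(aln)
    best: ReferenceAssignment | None = None
    for ref in sorted(by_ref):
        alns = by_ref[ref]
        cov = interval_union_length(
            (a.query_start, a.query_end) for a in alns) / cc_length
        wsum = sum(a.aligned_length for a in alns)
        ident = sum(a.identity * a.aligned_length for a in alns) / wsum
        if ident < min_identity or cov < min_coverage:
            continue
        cand = ReferenceAssignment(ref, reference_classes.get(ref, "plasmid"),
                                   ident, cov)
        if best is None or (cand.coverage, cand.identity) > \
                (best.coverage, best.identity):
            best = cand
    return best


@dataclass
class Classification:
    label: str  # plasmid | phage
    rationale: list[str] = field(default_factory=list)
    conflict: bool = False


def classify_cc(pog_frac: float, plasmid_cogs: frozenset[str],
                reference: ReferenceAssignment | None = None,
                external_phage_category: int | None = None,
                external_plasmid_call: bool | None = None,
                phage_call_fraction: float = 0.5,
                no_genes: bool = False) -> Classification:
    """Combine the evidence into a phage/plasmid label with a rationale.

    Phage requires the POG fraction to reach ``phage_call_fraction`` or an
    accepted external phage verdict, with no overriding reference plasmid
    assignment.  Everything else is a plasmid — the default class.  When
    phage evidence coexists with a reference plasmid assignment the
    reference wins and the call is flagged as a conflict.
    """
    rationale = []
    phage_evidence = False
    if no_genes:
        rationale.append("no-genes")
    if pog_frac >= phage_call_fraction and not no_genes:
        phage_evidence = True
        rationale.append(f"pog_fraction={pog_frac:.3f}>="
                         f"{phage_call_fraction:g}")
    if external_phage_category in PHAGE_VERDICT_CATEGORIES:
        phage_evidence = True
        rationale.append(f"external_phage_category={external_phage_category}")
    if plasmid_cogs:
        rationale.append("plasmid_cogs=" + ",".join(sorted(plasmid_cogs)))
    if external_plasmid_call:
        rationale.append("external_plasmid_call")
    if reference is not None:
        rationale.append(
            f"reference={reference.reference_id}"
            f"({reference.reference_class},id={reference.identity:.3f},"
            f"cov={reference.coverage:.3f})")

    if reference is not None and reference.reference_class == "plasmid":
        return Classification("plasmid", rationale, conflict=phage_evidence)
    if phage_evidence:
        return Classification("phage", rationale, conflict=False)
    return Classification("plasmid", rationale, conflict=False)


def classify_genes_by_contig(genes: list[GeneAnnotation],
                             reference_alignments=None,
                             reference_classes=None,
                             contig_lengths=None,
                             external_phage_categories=None,
                             external_plasmid_calls=None,
                             phage_call_fraction: float = 0.5,
                             ) -> dict[str, Classification]:
    """Classify every contig appearing in a gene table."""
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    out = {}
    for cc_id, cc_genes in sorted(by_contig.items()):
        frac, no_genes = pog_fraction(cc_genes)
        cogs = plasmid_cog_evidence(cc_genes)
        ref = None
        if reference_alignments and contig_lengths:
            ref = reference_assignment(cc_id, contig_lengths[cc_id],
                                       reference_alignments,
                                       reference_classes or {})
        out[cc_id] = classify_cc(
            frac, cogs, ref,
            external_phage_category=(external_phage_categories or {}).get(cc_id),
            external_plasmid_call=(external_plasmid_calls or {}).get(cc_id),
            phage_call_fraction=phage_call_fraction, no_genes=no_genes)
    return out
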