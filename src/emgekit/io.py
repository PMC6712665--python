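"""Readers and writers for the plain-text formats the pipeline touches.

FASTA goes through Biopython.  The assembly graph uses a small GFA-1
dialect: S-lines are unitigs carrying a read depth (``dp:f``) and a bin
assignment (``bn:Z``); L-lines join unitig ends into junctions.  Alignments
are PAF: 12 tab-separated columns, 0-based half-open coordinates, identity
= matches / block length.  Tables (genes, motifs, spacers, abundance) are
TSV via pandas.
"""

from __future__ import annotations

import re
import warnings
from io import StringIO
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import AbundanceMatrix, AlignmentRecord, GeneAnnotation, \
    MotifProfile, Unitig, UnitigGraph


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- FASTA

def read_sequences(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercased sequence), order preserved."""
    path = Path(path)
    records = []
    with path.open() as fh:
        text = fh.read()
    # locate records for line-number reporting
    line_no = 0
    header_lines = {}
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">"):
            if line[1:].split() == []:
                raise ParseError(f"{path}:{i}: malformed FASTA header")
            header_lines[line[1:].split()[0]] = i
        elif line.strip() and line_no == 0 and not records:
            if not header_lines:
                raise ParseError(f"{path}:{i}: sequence before first header")
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(
                f"{path}:{header_lines.get(rec.id, '?')}: empty sequence "
                f"for record {rec.id!r}")
        records.append((rec.id, seq))
    return records


def write_sequences(path, records) -> None:
    recs = [SeqRecord(Seq(seq), id=str(name), description="")
            for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------- GFA-1

_CIGAR_RE = re.compile(r"^(\d+)M$")


def _parse_overlap(field: str) -> int:
    if field in ("*", "0M", ""):
        return 0
    m = _CIGAR_RE.match(field)
    if not m:
        raise ParseError(f"unsupported GFA overlap {field!r}")
    return int(m.group(1))


def read_unitig_graph(path) -> UnitigGraph:
    """Read a GFA-1 file into a UnitigGraph.

    Unbinned segments (no ``bn:Z`` tag) receive a fresh unique bin ID so
    that downstream bin-guided merging never joins two unbinned unitigs.
    A missing ``dp:f`` tag warns and defaults to depth 1.0.
    """
    path = Path(path)
    segments: dict[str, tuple[str, float, str]] = {}
    links: list[tuple[str, str, str, str, int]] = []
    with path.open() as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("H"):
                continue
            fields = line.split("\t")
            if fields[0] == "S":
                if len(fields) < 3 or not fields[2] or fields[2] == "*":
                    raise ParseError(f"{path}:{i}: S-line without sequence")
                name, seq = fields[1], fields[2].upper()
                depth = None
                bin_id = None
                for tag in fields[3:]:
                    if tag.startswith("dp:f:"):
                        depth = float(tag[5:])
                    elif tag.startswith("bn:Z:"):
                        bin_id = tag[5:]
                if depth is None:
                    warnings.warn(
                        f"{path}:{i}: segment {name!r} has no dp:f depth "
                        f"tag; assuming depth 1.0")
                    depth = 1.0
                if bin_id is None:
                    bin_id = f"UNBINNED:{name}"
                segments[name] = (seq, depth, bin_id)
            elif fields[0] == "L":
                if len(fields) < 5:
                    raise ParseError(f"{path}:{i}: truncated L-line")
                a, oa, b, ob = fields[1], fields[2], fields[3], fields[4]
                ov = _parse_overlap(fields[5]) if len(fields) > 5 else 0
                links.append((a, oa, b, ob, ov))

    graph = UnitigGraph()
    # one junction object per segment end, then union by links
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for name in segments:
        parent[(name, "L")] = (name, "L")
        parent[(name, "R")] = (name, "R")
    overlaps: dict[tuple[str, str], int] = {}
    for a, oa, b, ob, ov in links:
        for seg in (a, b):
            if seg not in segments:
                raise ParseError(f"L-line references unknown segment {seg!r}")
        end_a = (a, "R" if oa == "+" else "L")
        end_b = (b, "L" if ob == "+" else "R")
        union(end_a, end_b)
        if ov:
            overlaps[find(end_a)] = max(overlaps.get(find(end_a), 0), ov)

    jids: dict[tuple[str, str], str] = {}
    for name, (seq, depth, bin_id) in sorted(segments.items()):
        for side in ("L", "R"):
            root = find((name, side))
            if root not in jids:
                jids[root] = graph.new_junction()
        graph.add_unitig(Unitig(name, seq, depth, bin_id),
                         from_junction=jids[find((name, "L"))],
                         to_junction=jids[find((name, "R"))])
    for root, ov in overlaps.items():
        graph.overlaps[jids[root]] = ov
    return graph


def write_unitig_graph(path, graph: UnitigGraph) -> None:
    lines = ["H\tVN:Z:1.0"]
    for uid in sorted(graph.unitigs):
        u = graph.unitigs[uid]
        lines.append(f"S\t{u.id}\t{u.sequence}\tdp:f:{u.depth:.17g}\t"
                     f"bn:Z:{u.bin_id}")
    for jid in sorted(graph.junctions):
        atts = graph.attachments(jid)
        ov = graph.overlaps.get(jid, 0)
        cig = f"{ov}M"
        for i in range(len(atts)):
            for k in range(i + 1, len(atts)):
                (u, eu), (v, ev) = atts[i], atts[k]
                if eu == "to" and ev == "from":
                    lines.append(f"L\t{u}\t+\t{v}\t+\t{cig}")
                elif eu == "from" and ev == "to":
                    lines.append(f"L\t{v}\t+\t{u}\t+\t{cig}")
                elif eu == "to" and ev == "to":
                    lines.append(f"L\t{u}\t+\t{v}\t-\t{cig}")
                else:  # from/from
                    lines.append(f"L\t{u}\t-\t{v}\t+\t{cig}")
        if len(atts) == 2 and atts[0][0] == atts[1][0]:
            pass  # self-loop already emitted once by the pair loop
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------ PAF

def read_alignments(path) -> list[AlignmentRecord]:
    """Read PAF records (12+ tab-separated columns)."""
    out = []
    path = Path(path)
    with path.open() as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{i}: PAF line with {len(f)} columns")
            qlen, qs, qe = int(f[1]), int(f[2]), int(f[3])
            tlen, ts, te = int(f[6]), int(f[7]), int(f[8])
            matches, block = int(f[9]), int(f[10])
            if min(qs, qe, ts, te, qlen, tlen) < 0:
                raise ParseError(f"{path}:{i}: negative coordinate")
            out.append(AlignmentRecord(
                query_id=f[0], target_id=f[5],
                query_start=qs, query_end=qe,
                target_start=ts, target_end=te,
                strand=f[4], identity=matches / block if block else 0.0,
                aligned_length=block, query_length=qlen, target_length=tlen))
    return out


def write_alignments(path, records) -> None:
    lines = []
    for r in records:
        lines.append("\t".join(map(str, [
            r.query_id, r.query_length, r.query_start, r.query_end,
            r.strand, r.target_id, r.target_length, r.target_start,
            r.target_end, r.matches, r.aligned_length, 255])))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# --------------------------------------------------------------- tables

GENE_COLUMNS = ["gene_id", "contig_id", "start", "end", "strand", "cog_id",
                "cog_category", "pog_hit", "hit_coverage", "phylum", "genus",
                "species", "is_arg"]


def genes_to_frame(genes) -> pd.DataFrame:
    rows = []
    for g in genes:
        phylum, genus, species = g.taxon if g.taxon else (None, None, None)
        rows.append((g.gene_id, g.contig_id, g.start, g.end, g.strand,
                     g.cog_id, g.cog_category, g.pog_hit, g.hit_coverage,
                     phylum, genus, species, g.is_arg))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def frame_to_genes(df: pd.DataFrame) -> list[GeneAnnotation]:
    out = []
    for row in df.itertuples(index=False):
        taxon = None
        if isinstance(row.phylum, str):
            taxon = (row.phylum, row.genus, row.species)
        out.append(GeneAnnotation(
            gene_id=str(row.gene_id), contig_id=str(row.contig_id),
            start=int(row.start), end=int(row.end), strand=str(row.strand),
            cog_id=None if pd.isna(row.cog_id) else str(row.cog_id),
            cog_category=(None if pd.isna(row.cog_category)
                          else str(row.cog_category)),
            pog_hit=bool(row.pog_hit), hit_coverage=float(row.hit_coverage),
            taxon=taxon, is_arg=bool(row.is_arg)))
    return out


def read_gene_table(path) -> list[GeneAnnotation]:
    return frame_to_genes(pd.read_csv(path, sep="\t",
                                      float_precision="round_trip"))


def write_gene_table(path, genes) -> None:
    genes_to_frame(genes).to_csv(path, sep="\t", index=False,
                                 float_format="%.17g")


MOTIF_COLUMNS = ["sequence_id", "motif", "mod_type", "methylated_fraction",
                 "mean_coverage", "mean_ipd_ratio"]


def motifs_to_frame(profiles) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.sequence_id, p.motif, p.mod_type, p.methylated_fraction,
          p.mean_coverage, p.mean_ipd_ratio) for p in profiles],
        columns=MOTIF_COLUMNS)


def frame_to_motifs(df: pd.DataFrame) -> list[MotifProfile]:
    return [MotifProfile(
        sequence_id=str(r.sequence_id), motif=str(r.motif),
        mod_type=str(r.mod_type),
        methylated_fraction=float(r.methylated_fraction),
        mean_coverage=float(r.mean_coverage),
        mean_ipd_ratio=float(r.mean_ipd_ratio))
        for r in df.itertuples(index=False)]


def read_motif_table(path) -> list[MotifProfile]:
    return frame_to_motifs(pd.read_csv(path, sep="\t",
                                       float_precision="round_trip"))


def write_motif_table(path, profiles) -> None:
    motifs_to_frame(profiles).to_csv(path, sep="\t", index=False,
                                     float_format="%.17g")


def read_spacer_table(path) -> dict[str, list[tuple[str, str]]]:
    """TSV with columns host_id, spacer_id, sequence."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[tuple[str, str]]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.host_id), []).append(
            (str(r.spacer_id), str(r.sequence).upper()))
    return out


def write_spacer_table(path, spacers: dict) -> None:
    rows = [(h, sid, seq) for h, lst in spacers.items() for sid, seq in lst]
    pd.DataFrame(rows, columns=["host_id", "spacer_id", "sequence"]).to_csv(
        path, sep="\t", index=False)


def read_abundance_matrix(path) -> AbundanceMatrix:
    """TSV: first column element_id, second length, remaining samples."""
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    lengths = df["length"]
    counts = df.drop(columns=["length"])
    return AbundanceMatrix(counts, lengths)


def write_abundance_matrix(path, matrix: AbundanceMatrix) -> None:
    df = matrix.counts.copy()
    df.insert(0, "length", matrix.lengths)
    df.to_csv(path, sep="\t", index_label="element_id",
              float_format="%.17g")
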