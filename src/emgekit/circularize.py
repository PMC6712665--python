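"""Bin-guided untangling of a unitig graph and circular-contig recovery.

The rule: whenever a junction has exactly one incoming and exactly one
outgoing unitig and both carry the same bin ID, the two unitigs are merged
into one.  Because every unbinned unitig holds a distinct synthetic bin ID,
merges never create spurious self-loops from unbinned sequence.  Merging is
applied to a fixed point by default; the result is independent of the order
in which junctions are visited (merges at distinct junctions commute).

A merged unitig whose two ends meet at the same junction is a circular
contig; circles shorter than the assembler's minimum overlap (2.2 kb by
default) are not reportable and are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import CircularContig, Unitig, UnitigGraph, canonical_rotation

logger = logging.getLogger(__name__)

MIN_CIRCLE_LENGTH = 2200  # bp; assembler minimum read-overlap cutoff


@dataclass
class MergeReport:
    merges: list[tuple[str, str, str]] = field(default_factory=list)
    skipped_junctions: list[str] = field(default_factory=list)


def _copy_graph(graph: UnitigGraph) -> UnitigGraph:
    g = UnitigGraph()
    for uid, u in graph.unitigs.items():
        g.unitigs[uid] = Unitig(u.id, u.sequence, u.depth, u.bin_id)
        g.from_junction[uid] = graph.from_junction[uid]
        g.to_junction[uid] = graph.to_junction[uid]
    g.overlaps = dict(graph.overlaps)
    g._next_junction = graph._next_junction
    return g


def mergeable_pair(graph: UnitigGraph, junction: str):
    """Return (incoming uid, outgoing uid) if the junction admits a merge,
    else None.  Logs a warning for same-bin orientation conflicts."""
    atts = graph.attachments(junction)
    if len(atts) != 2:
        return None
    (u1, e1), (u2, e2) = atts
    if u1 == u2:
        return None  # self-loop: a circle candidate, not a merge
    ends = {e1, e2}
    same_bin = graph.unitigs[u1].bin_id == graph.unitigs[u2].bin_id
    if ends == {"to", "from"}:
        if not same_bin:
            return None
        return (u1, u2) if e1 == "to" else (u2, u1)
    if same_bin:
        logger.warning("junction %s: orientation conflict between %s and %s;"
                       " skipped", junction, u1, u2)
    return None


def _merge_at(graph: UnitigGraph, junction: str, incoming: str,
              outgoing: str, members: dict[str, list[str]]) -> str:
    a, b = graph.unitigs[incoming], graph.unitigs[outgoing]
    overlap = graph.overlaps.get(junction, 0)
    seq = a.sequence + b.sequence[overlap:]
    la, lb = a.length, b.length - overlap
    depth = (a.depth * la + b.depth * lb) / (la + lb)
    new_id = f"{incoming}+{outgoing}"
    while new_id in graph.unitigs:
        new_id += "'"
    from_j = graph.from_junction[incoming]
    to_j = graph.to_junction[outgoing]
    members[new_id] = members.pop(incoming) + members.pop(outgoing)
    graph.remove_unitig(incoming)
    graph.remove_unitig(outgoing)
    graph.add_unitig(Unitig(new_id, seq, depth, a.bin_id),
                     from_junction=from_j, to_junction=to_j)
    graph.overlaps.pop(junction, None)
    return new_id


def merge_by_bins(graph: UnitigGraph, to_fixed_point: bool = True,
                  report: MergeReport | None = None,
                  _members: dict[str, list[str]] | None = None,
                  junction_order=None) -> UnitigGraph:
    """Merge same-bin unitig pairs at 1-in/1-out junctions.

    ``to_fixed_point`` repeats until no junction admits a merge (default);
    with False a single sweep over the junctions is performed.
    ``junction_order`` fixes the processing order (testing hook; the fixed
    point does not depend on it).
    """
    g = _copy_graph(graph)
    members = _members if _members is not None else {}
    for uid in g.unitigs:
        members.setdefault(uid, [uid])
    rep = report if report is not None else MergeReport()

    def one_sweep() -> bool:
        changed = False
        order = list(junction_order) if junction_order else sorted(g.junctions)
        for j in order:
            if j not in g.junctions:
                continue
            pair = mergeable_pair(g, j)
            if pair is None:
                atts = g.attachments(j)
                if len(atts) == 2 and atts[0][0] != atts[1][0] and \
                        {atts[0][1], atts[1][1]} != {"to", "from"} and \
                        g.unitigs[atts[0][0]].bin_id == g.unitigs[atts[1][0]].bin_id:
                    rep.skipped_junctions.append(j)
                continue
            incoming, outgoing = pair
            new_id = _merge_at(g, j, incoming, outgoing, members)
            rep.merges.append((incoming, outgoing, new_id))
            changed = True
        return changed

    if to_fixed_point:
        while one_sweep():
            pass
    else:
        one_sweep()
    return g


def detect_circles(graph: UnitigGraph,
                   min_length: int = MIN_CIRCLE_LENGTH,
                   members: dict[str, list[str]] | None = None
                   ) -> list[CircularContig]:
    """Self-loop unitigs of at least ``min_length`` bp, reported with the
    sequence in canonical rotation so circles are comparable across runs."""
    circles = []
    for uid in sorted(graph.unitigs):
        if graph.from_junction[uid] != graph.to_junction[uid]:
            continue
        u = graph.unitigs[uid]
        overlap = graph.overlaps.get(graph.from_junction[uid], 0)
        seq = u.sequence[overlap:]
        if len(seq) < min_length:
            continue
        circles.append(CircularContig(
            id=uid, sequence=canonical_rotation(seq), depth=u.depth,
            member_unitigs=(members or {}).get(uid, [uid])))
    return circles


def circularize(graph: UnitigGraph, min_length: int = MIN_CIRCLE_LENGTH,
                to_fixed_point: bool = True
                ) -> tuple[list[CircularContig], MergeReport]:
    """Stage entrypoint: merge by bins, then report circular contigs."""
    report = MergeReport()
    members: dict[str, list[str]] = {}
    merged = merge_by_bins(graph, to_fixed_point=to_fixed_point,
                           report=report, _members=members)
    circles = detect_circles(merged, min_length=min_length, members=members)
    return circles, report
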