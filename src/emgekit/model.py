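"""Domain types shared by every pipeline stage.

Coordinates are uniformly 0-based half-open.  Sequences are stored in one
canonical orientation; reverse complement is always expressed through a
strand flag, never by storing the complemented string.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, who: str) -> None:
    if not seq:
        raise ValueError(f"{who}: empty sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{who}: non-DNA characters {sorted(bad)!r}")


@dataclass
class Unitig:
    """An assembly-graph edge: an unambiguous contiguous sequence with a
    mean read depth and an externally supplied bin assignment."""

    id: str
    sequence: str
    depth: float = 1.0
    bin_id: str = ""

    def __post_init__(self) -> None:
        _check_dna(self.sequence, f"unitig {self.id!r}")
        if self.depth < 0:
            raise ValueError(f"unitig {self.id!r}: negative depth")
        if not self.bin_id:
            raise ValueError(f"unitig {self.id!r}: empty bin_id")

    @property
    def length(self) -> int:
        return len(self.sequence)


class UnitigGraph:
    """Assembly graph in the edge-centric view: unitigs are edges, junctions
    are nodes.  Each unitig runs from ``from_junction`` (its 5' end) to
    ``to_junction`` (its 3' end) in stored orientation.
    """

    def __init__(self) -> None:
        self.unitigs: dict[str, Unitig] = {}
        self.from_junction: dict[str, str] = {}
        self.to_junction: dict[str, str] = {}
        # junction -> overlap (bp) trimmed from the successor on merging
        self.overlaps: dict[str, int] = {}
        self._next_junction = 0

    # -- construction -------------------------------------------------
    def new_junction(self) -> str:
        jid = f"J{self._next_junction}"
        self._next_junction += 1
        return jid

    def add_unitig(self, unitig: Unitig, from_junction: str | None = None,
                   to_junction: str | None = None) -> Unitig:
        if unitig.id in self.unitigs:
            raise ValueError(f"duplicate unitig id {unitig.id!r}")
        self.unitigs[unitig.id] = unitig
        self.from_junction[unitig.id] = from_junction or self.new_junction()
        self.to_junction[unitig.id] = to_junction or self.new_junction()
        return unitig

    def remove_unitig(self, uid: str) -> None:
        del self.unitigs[uid]
        del self.from_junction[uid]
        del self.to_junction[uid]

    # -- queries ------------------------------------------------------
    @property
    def junctions(self) -> set[str]:
        return set(self.from_junction.values()) | set(self.to_junction.values())

    def attachments(self, junction: str) -> list[tuple[str, str]]:
        """All (unitig id, end) incidences at a junction; end is 'from'
        (unitig leaves the junction) or 'to' (unitig arrives)."""
        out = []
        for uid in self.unitigs:
            if self.from_junction[uid] == junction:
                out.append((uid, "from"))
            if self.to_junction[uid] == junction:
                out.append((uid, "to"))
        return sorted(out)

    def total_length(self) -> int:
        return sum(u.length for u in self.unitigs.values())

    def canonical_form(self) -> tuple:
        """Relabel-invariant summary used to compare graphs for isomorphism
        in the loose sense that matters here: same unitig content and same
        junction partition of unitig ends."""
        names = {}  # junction -> frozenset of (sequence, end) incidences
        for uid, u in self.unitigs.items():
            for jid, end in ((self.from_junction[uid], "from"),
                             (self.to_junction[uid], "to")):
                names.setdefault(jid, []).append((u.sequence, u.depth,
                                                  u.bin_id, end))
        content = tuple(sorted((u.sequence, round(u.depth, 9), u.bin_id)
                               for u in self.unitigs.values()))
        parts = tuple(sorted(tuple(sorted(v)) for v in names.values()))
        return (content, parts)


@dataclass
class CircularContig:
    """A recovered circular element (plasmid candidate, or a linear genome
    whose terminal repeats were collapsed by the assembler)."""

    id: str
    sequence: str
    depth: float = 1.0
    member_unitigs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_dna(self.sequence, f"circular contig {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TDREvidence:
    """Read-mapping evidence for a terminal direct repeat collapsed into a
    circular contig: depth roughly doubles over the repeat, no read spans
    it with flanks on both sides, and read starts/ends pile up at its
    boundaries."""

    coverage_ratio: float
    spanning_reads: int
    start_excess: float

    def __post_init__(self) -> None:
        if self.coverage_ratio <= 0:
            raise ValueError("coverage_ratio must be positive")
        if self.spanning_reads < 0:
            raise ValueError("spanning_reads must be >= 0")


@dataclass
class LinearGenome:
    """A linear genome carrying identical terminal direct repeats."""

    id: str
    sequence: str
    tdr_length: int
    evidence: TDREvidence | None = None
    max_tdr_mismatch: int = 0

    def __post_init__(self) -> None:
        _check_dna(self.sequence, f"linear genome {self.id!r}")
        if self.tdr_length <= 0 or self.tdr_length * 2 > len(self.sequence):
            raise ValueError(f"linear genome {self.id!r}: invalid tdr_length")
        left, right = self.left_tdr, self.right_tdr
        mism = sum(a != b for a, b in zip(left, right))
        if mism > self.max_tdr_mismatch:
            raise ValueError(
                f"linear genome {self.id!r}: terminal repeats differ at "
                f"{mism} positions (> {self.max_tdr_mismatch} allowed)")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def left_tdr(self) -> str:
        return self.sequence[: self.tdr_length]

    @property
    def right_tdr(self) -> str:
        return self.sequence[len(self.sequence) - self.tdr_length:]


@dataclass
class AlignmentRecord:
    """Generic query-to-target interval alignment (PAF semantics).

    ``target_end`` may exceed the target length to express a wrap-around
    alignment on a circular target (coordinates taken modulo the length).
    Identity is matches / alignment block length.
    """

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str = "+"
    identity: float = 1.0
    aligned_length: int = 0
    query_length: int = 0
    target_length: int = 0

    def __post_init__(self) -> None:
        if self.query_end <= self.query_start or self.target_end <= self.target_start:
            raise ValueError("alignment interval end must exceed start")
        if min(self.query_start, self.target_start) < 0:
            raise ValueError("negative alignment coordinate")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0, 1]")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.aligned_length == 0:
            self.aligned_length = self.target_end - self.target_start

    @property
    def matches(self) -> int:
        return int(round(self.identity * self.aligned_length))


@dataclass
class GeneAnnotation:
    """A predicted gene with its functional (COG/POG) and taxonomic labels."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    cog_id: str | None = None
    cog_category: str | None = None
    pog_hit: bool = False
    hit_coverage: float = 0.0
    taxon: tuple[str, str, str] | None = None  # (phylum, genus, species)
    is_arg: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id!r}: end must exceed start")
        if not 0.0 <= self.hit_coverage <= 1.0:
            raise ValueError(f"gene {self.gene_id!r}: hit_coverage outside [0,1]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MotifProfile:
    """Methylation evidence for one motif on one sequence.

    ``mean_ipd_ratio`` is NaN when the motif never occurs on the sequence;
    the binary state is then "missing" (None)."""

    sequence_id: str
    motif: str
    mod_type: str = "m6A"
    methylated_fraction: float = float("nan")
    mean_coverage: float = float("nan")
    mean_ipd_ratio: float = float("nan")

    def binary_state(self, threshold: float = 2.5) -> int | None:
        if math.isnan(self.mean_ipd_ratio):
            return None
        return 1 if self.mean_ipd_ratio > threshold else 0


class AbundanceMatrix:
    """Elements x samples table of mapped-read counts with element lengths."""

    def __init__(self, counts: pd.DataFrame, lengths: pd.Series) -> None:
        counts = counts.astype(float)
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative abundance entry")
        missing = set(counts.index) - set(lengths.index)
        if missing:
            raise ValueError(f"lengths missing for elements {sorted(missing)}")
        self.counts = counts
        self.lengths = lengths.loc[counts.index].astype(float)

    @property
    def element_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def normalized(self, per: float = 1000.0) -> pd.DataFrame:
        """Counts normalised by element length (reads per `per` bp)."""
        return self.counts.div(self.lengths / per, axis=0)

    def subset(self, element_ids) -> "AbundanceMatrix":
        return AbundanceMatrix(self.counts.loc[list(element_ids)],
                               self.lengths)


@dataclass
class EMGECluster:
    """A cluster of mutually similar mobile elements; the representative is
    the longest member."""

    cluster_id: str
    members: frozenset[str]
    representative: str
    representative_length: int

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must belong to the cluster")
        if self.representative_length <= 0:
            raise ValueError("representative_length must be positive")


@dataclass
class HostPrediction:
    """One (eMGE, host) prediction by one method."""

    emge_id: str
    host_id: str
    method: str  # similarity | co-occurrence | crispr | methylation
    score: float
    taxon: tuple[str, str, str] | None = None
    evidence: tuple = ()


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and disjoint."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def interval_union_length(intervals) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def least_rotation(s: str) -> str:
    """Lexicographically minimal rotation (Booth's algorithm, O(n))."""
    ss = s + s
    n = len(ss)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k:k + len(s)]


def canonical_rotation(seq: str) -> str:
    """Canonical form of a circular sequence: the smaller of the minimal
    rotations of the sequence and of its reverse complement."""
    return min(least_rotation(seq), least_rotation(revcomp(seq)))
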