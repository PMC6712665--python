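"""Terminal-direct-repeat detection and genome linearization.

A linear genome whose two ends carry an identical ~2-kb repeat (TDR) is
collapsed by an overlap assembler into a circle in which the repeat appears
once.  Read mapping against that circle betrays the mistake in three ways:

* depth over the collapsed repeat is roughly twice the depth elsewhere
  (reads from both copies pile onto one);
* no read spans the repeat with flanking sequence on both sides, because
  no template molecule contains ``right-repeat + left-flank``;
* read starts pile up at the repeat's left boundary and read ends at its
  right boundary (molecule-terminal reads are truncated there).

``detect_tdr`` operationalizes this, ``linearize`` re-expands the circle,
and ``gc_skew``/``skew_transition`` profile replication strand asymmetry on
the resulting linear genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AlignmentRecord, CircularContig, LinearGenome, TDREvidence


def coverage_profile(alignments, contig_length: int) -> np.ndarray:
    """Per-position alignment depth on a circular contig.

    ``target_end`` beyond the contig length denotes wrap-around; all
    coordinates are interpreted modulo the length.
    """
    delta = np.zeros(contig_length + 1, dtype=np.int64)
    for aln in alignments:
        s = aln.target_start % contig_length
        length = aln.target_end - aln.target_start
        if length >= contig_length:  # covers the whole circle
            delta[0] += 1
            delta[contig_length] -= 1
            continue
        e = s + length
        if e <= contig_length:
            delta[s] += 1
            delta[e] -= 1
        else:  # wraps
            delta[s] += 1
            delta[contig_length] -= 1
            delta[0] += 1
            delta[e - contig_length] -= 1
    return np.cumsum(delta[:-1])


@dataclass
class StartProfile:
    """Windowed counts of alignment 5' start and 3' end positions."""

    window: int
    starts: np.ndarray
    ends: np.ndarray

    def start_count_at(self, position: int) -> int:
        return int(self.starts[position // self.window])

    def end_count_at(self, position: int) -> int:
        return int(self.ends[(position - 1) // self.window])


def read_start_profile(alignments, contig_length: int,
                       window: int = 100) -> StartProfile:
    """Counts of alignment start and end termini per window (both strands
    pooled; end positions are half-open so position ``e`` is attributed to
    the window containing ``e - 1``)."""
    n_win = -(-contig_length // window)
    starts = np.zeros(n_win, dtype=np.int64)
    ends = np.zeros(n_win, dtype=np.int64)
    for aln in alignments:
        s = aln.target_start % contig_length
        e = (aln.target_end - 1) % contig_length
        starts[s // window] += 1
        ends[e // window] += 1
    return StartProfile(window=window, starts=starts, ends=ends)


def spanning_count(alignments, interval: tuple[int, int],
                   contig_length: int, flank: int = 100) -> int:
    """Number of alignments containing the interval with at least
    ``flank`` bp on each side (circular coordinates)."""
    s, e = interval
    need_start = s - flank
    need_end = e + flank
    count = 0
    for aln in alignments:
        a_start = aln.target_start % contig_length
        length = aln.target_end - aln.target_start
        # unroll the alignment onto the line through need_start
        for shift in (-contig_length, 0, contig_length):
            st = a_start + shift
            if st <= need_start and st + length >= need_end:
                count += 1
                break
    return count


@dataclass
class TDRResult:
    interval: tuple[int, int] | None
    evidence: TDREvidence | None
    status: str  # detected | none | insufficient-coverage


def detect_tdr(circle: CircularContig, long_alignments,
               short_alignments=None, *, ratio_low: float = 1.6,
               min_depth: float = 10.0, min_tdr_length: int = 500,
               flank: int = 100, max_spanning: int = 0,
               start_excess_min: float = 3.0, min_pileup: int = 5,
               window: int = 100) -> TDRResult:
    """Find a collapsed terminal repeat on a circular contig.

    The primary signal is the terminus pileup: reads truncated at the
    ends of the linear molecule start exactly at the collapsed repeat's
    left boundary and end exactly at its right boundary, so the strongest
    start-position and end-position pileups delimit the candidate.  The
    candidate is accepted only when all evidence agrees:

    * both terminus pileups hold at least ``min_pileup`` reads and exceed
      ``start_excess_min`` times the background per-window terminus rate;
    * mean depth inside is at least ``ratio_low`` times the mean outside
      (the collapsed repeat carries reads from both copies);
    * no more than ``max_spanning`` alignments span the candidate with
      ``flank`` bp margins on both sides;
    * the candidate is ``min_tdr_length``..half-circle long.

    Short-read alignments, when given, must independently satisfy the
    depth-ratio and spanning checks.  The reported coverage ratio is
    measured on the pooled alignments.
    """
    n = circle.length
    depth = coverage_profile(long_alignments, n)
    if float(depth.mean()) < min_depth:
        return TDRResult(None, None, "insufficient-coverage")

    starts = np.zeros(n, dtype=np.int64)
    ends = np.zeros(n, dtype=np.int64)
    for aln in long_alignments:
        starts[aln.target_start % n] += 1
        length = aln.target_end - aln.target_start
        ends[(aln.target_start + length) % n] += 1
    s = int(np.argmax(starts))
    e = int(np.argmax(ends))
    n_windows = max(1, n // window)
    background = max(len(long_alignments) / n_windows, 1e-9)
    excess = min(int(starts[s]), int(ends[e])) / background
    if min(starts[s], ends[e]) < min_pileup or excess < start_excess_min:
        return TDRResult(None, None, "none")

    length = (e - s) % n
    if not min_tdr_length <= length <= n // 2:
        return TDRResult(None, None, "none")
    inside = np.zeros(n, dtype=bool)
    if s < e:
        inside[s:e] = True
    else:
        inside[s:] = True
        inside[:e] = True

    def _depth_ratio(alignments) -> float:
        d = coverage_profile(alignments, n)
        outside = float(d[~inside].mean())
        return float(d[inside].mean()) / outside if outside > 0 else 0.0

    # spanning is checked on every read set; the depth-ratio on the
    # densest set (short reads when present), which carries the coverage
    # resolution, while long reads carry the terminus/spanning evidence
    pooled = list(long_alignments) + list(short_alignments or [])
    span = spanning_count(pooled, (s, s + length), n, flank=flank)
    ratio = _depth_ratio(short_alignments if short_alignments
                         else long_alignments)
    if span > max_spanning or ratio < ratio_low:
        return TDRResult(None, None, "none")
    return TDRResult((s, s + length),
                     TDREvidence(coverage_ratio=ratio, spanning_reads=span,
                                 start_excess=excess),
                     "detected")


def linearize(circle: CircularContig, tdr_interval: tuple[int, int],
              evidence: TDREvidence | None = None) -> LinearGenome:
    """Re-expand a collapsed circle into its linear genome.

    The circle is rotated so the repeat starts the sequence and a verbatim
    second copy is appended: output length = circle length + repeat length.
    """
    s, e = tdr_interval
    if e <= s:
        raise ValueError("empty TDR interval")
    n = circle.length
    t = e - s
    if t >= n:
        raise ValueError("TDR interval covers the whole circle")
    s %= n
    rotated = circle.sequence[s:] + circle.sequence[:s]
    seq = rotated + rotated[:t]
    return LinearGenome(id=circle.id, sequence=seq, tdr_length=t,
                        evidence=evidence)


def gc_skew(sequence: str, window: int = 100, step: int = 50
            ) -> list[tuple[int, float | None]]:
    """(G - C) / (G + C) per sliding window; None where G + C = 0."""
    seq = sequence.upper()
    out = []
    for start in range(0, len(seq) - window + 1, step):
        win = seq[start:start + window]
        g = win.count("G")
        c = win.count("C")
        out.append((start, (g - c) / (g + c) if g + c else None))
    return out


def skew_transition(profile) -> dict | None:
    """Replication origin/terminus signal: the positions of the extrema of
    the cumulative GC skew.  Returns None when every window is missing."""
    positions = [p for p, _ in profile]
    values = [v for _, v in profile]
    if all(v is None for v in values):
        return None
    cum = np.cumsum([0.0 if v is None else v for v in values])
    i_min = int(np.argmin(cum))
    i_max = int(np.argmax(cum))
    primary = i_min if abs(cum[i_min]) >= abs(cum[i_max]) else i_max
    return {
        "position": positions[primary],
        "minimum_position": positions[i_min],
        "maximum_position": positions[i_max],
        "cumulative_skew": float(cum[primary]),
    }
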