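"""Three-way host prediction for mobile elements, and its consolidation.

* Co-occurrence: Spearman rank correlation of length-normalised abundance
  across samples; hosts with a correlation of at least 0.7 are predicted.
* CRISPR spacers: a host's spacer (>= 20 bp) matching a phage with at most
  one mismatch over more than 95% of its length implicates that host.
* Methylation motifs: chromosomal methylation motifs passing detection
  thresholds (methylated fraction >= 0.6, mean coverage >= 25, GATC/m6A
  excluded as ubiquitous) act as baits; mean IPD ratios are binarised at
  2.5 and an element links to a bin when they share at least one baited
  motif and agree on every motif present in both.

``consolidate`` lays the per-method predictions side by side with
taxonomic agreement flags; no method overrides another.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import AbundanceMatrix, HostPrediction, MotifProfile, revcomp
from .stats import spearman

RANKS = ("phylum", "genus", "species")


# ------------------------------------------------------------ co-occurrence

def cooccurrence_hosts(abundance: AbundanceMatrix, emge_ids, host_ids,
                       threshold: float = 0.7,
                       taxa: dict | None = None) -> list[HostPrediction]:
    """Predict hosts whose abundance profile rank-correlates with the
    element's at ``threshold`` or above.  Requires >= 3 samples; constant
    profiles are skipped."""
    if len(abundance.sample_ids) < 3:
        raise ValueError("co-occurrence needs at least 3 samples")
    norm = abundance.normalized()
    preds = []
    for emge in emge_ids:
        x = norm.loc[emge].to_numpy()
        for host in host_ids:
            y = norm.loc[host].to_numpy()
            rho = spearman(x, y)
            if np.isnan(rho):
                continue
            if rho >= threshold:
                preds.append(HostPrediction(
                    emge_id=emge, host_id=host, method="co-occurrence",
                    score=float(rho), taxon=(taxa or {}).get(host)))
    return preds


# ------------------------------------------------------------ CRISPR spacers

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _best_ungapped_match(spacer: str, target: str,
                         max_mismatch: int) -> int | None:
    """Minimum Hamming distance of the full spacer over all target windows
    (both strands), or None if no window achieves <= max_mismatch."""
    best: int | None = None
    t = _encode(target)
    n, m = len(target), len(spacer)
    if m > n:
        return None
    for probe in (spacer, revcomp(spacer)):
        p = _encode(probe)
        # windowed mismatch counts via cumulative equality sums
        eq = np.zeros(n - m + 1, dtype=np.int32)
        for j in range(m):
            eq += (t[j:n - m + 1 + j] == p[j])
        mism = m - int(eq.max())
        if mism <= max_mismatch and (best is None or mism < best):
            best = mism
    return best


def spacer_hits(spacers: dict[str, list[tuple[str, str]]],
                phages: list[tuple[str, str]], min_len: int = 20,
                max_mismatch: int = 1, min_coverage: float = 0.95,
                taxa: dict | None = None) -> list[HostPrediction]:
    """Match host CRISPR spacers against phage sequences.

    Spacers shorter than ``min_len`` are excluded before the search.  A
    match is an ungapped alignment of a spacer substring longer than
    ``min_coverage`` of the spacer with at most ``max_mismatch``
    mismatches, on either strand.  The prediction score is the mismatch
    count of the best hit.
    """
    preds = []
    for host in sorted(spacers):
        for spacer_id, seq in spacers[host]:
            L = len(seq)
            if L < min_len:
                continue
            min_window = int(np.floor(min_coverage * L)) + 1
            for phage_id, phage_seq in phages:
                best: int | None = None
                for w in range(L, min_window - 1, -1):
                    for off in range(0, L - w + 1):
                        m = _best_ungapped_match(seq[off:off + w],
                                                 phage_seq, max_mismatch)
                        if m is not None and (best is None or m < best):
                            best = m
                if best is not None:
                    preds.append(HostPrediction(
                        emge_id=phage_id, host_id=host, method="crispr",
                        score=float(best), taxon=(taxa or {}).get(host),
                        evidence=(spacer_id,)))
    return preds


# ------------------------------------------------------ methylation motifs

def filter_motifs(profiles: list[MotifProfile], bin_ids,
                  min_fraction: float = 0.6,
                  min_coverage: float = 25.0) -> set[str]:
    """Chromosome-bin motifs passing the detection thresholds (both
    inclusive), with the ubiquitous GATC/m6A motif always removed."""
    bin_ids = set(bin_ids)
    baits = set()
    for p in profiles:
        if p.sequence_id not in bin_ids:
            continue
        if p.motif == "GATC" and p.mod_type == "m6A":
            continue
        if np.isnan(p.methylated_fraction) or np.isnan(p.mean_coverage):
            continue
        if p.methylated_fraction >= min_fraction and \
                p.mean_coverage >= min_coverage:
            baits.add(p.motif)
    return baits


def binarize_ipd(profile: MotifProfile,
                 threshold: float = 2.5) -> int | None:
    """1 when the mean IPD ratio exceeds the threshold (methylated), 0
    otherwise, None when the motif never occurs on the sequence."""
    return profile.binary_state(threshold)


def _state_table(profiles, ids, baits, threshold) -> dict[str, dict[str, int]]:
    states: dict[str, dict[str, int]] = {i: {} for i in ids}
    for p in profiles:
        if p.sequence_id in states and p.motif in baits:
            b = binarize_ipd(p, threshold)
            if b is not None:
                states[p.sequence_id][p.motif] = b
    return states


def link_by_motifs(profiles: list[MotifProfile], emge_ids, bin_ids,
                   baits: set[str], ipd_threshold: float = 2.5,
                   taxa: dict | None = None) -> list[HostPrediction]:
    """Link an element to a chromosome bin when they share at least one
    methylation mark (a baited motif methylated on both) and every baited
    motif present on both has the same binary state (missing values
    compared as wildcards).  The score is the number of agreeing shared
    motifs.

    Requiring a shared mark — not merely a shared motif occurrence —
    prevents links supported only by jointly unmethylated contexts."""
    emge_states = _state_table(profiles, emge_ids, baits, ipd_threshold)
    bin_states = _state_table(profiles, bin_ids, baits, ipd_threshold)
    preds = []
    for emge in sorted(emge_states):
        for bin_id in sorted(bin_states):
            shared = set(emge_states[emge]) & set(bin_states[bin_id])
            if not any(emge_states[emge][m] == 1 == bin_states[bin_id][m]
                       for m in shared):
                continue
            if all(emge_states[emge][m] == bin_states[bin_id][m]
                   for m in shared):
                preds.append(HostPrediction(
                    emge_id=emge, host_id=bin_id, method="methylation",
                    score=float(len(shared)), taxon=(taxa or {}).get(bin_id),
                    evidence=tuple(sorted(shared))))
    return preds


# ------------------------------------------------------------- consolidation

def consolidate(predictions: list[HostPrediction],
                similarity: list[HostPrediction] | None = None
                ) -> pd.DataFrame:
    """One row per element listing each method's best host (highest score;
    for CRISPR, fewest mismatches) plus rank-by-rank agreement flags when
    two or more methods predicted a host."""
    all_preds = list(predictions) + list(similarity or [])
    methods = ("similarity", "co-occurrence", "crispr", "methylation")
    rows = []
    for emge in sorted({p.emge_id for p in all_preds}):
        row: dict = {"emge_id": emge}
        taxa_by_method = {}
        for method in methods:
            cands = [p for p in all_preds
                     if p.emge_id == emge and p.method == method]
            if not cands:
                row[f"host_{method}"] = None
                continue
            key = (lambda p: p.score) if method == "crispr" \
                else (lambda p: -p.score)
            best = sorted(cands, key=lambda p: (key(p), p.host_id))[0]
            row[f"host_{method}"] = best.host_id
            if best.taxon:
                taxa_by_method[method] = best.taxon
        flags = []
        for i, rank in enumerate(RANKS):
            values = [t[i] for t in taxa_by_method.values()
                      if t[i] is not None]
            if len(values) >= 2:
                flags.append(f"agree@{rank}" if len(set(values)) == 1
                             else f"conflict@{rank}")
        row["agreement"] = ";".join(flags)
        rows.append(row)
    return pd.DataFrame(rows)


def host_network(consolidated: pd.DataFrame,
                 taxa: dict | None = None) -> pd.DataFrame:
    """Bipartite host-element edge list from a consolidated table."""
    edges = []
    host_cols = [c for c in consolidated.columns if c.startswith("host_")]
    for _, row in consolidated.iterrows():
        seen = set()
        for col in host_cols:
            host = row[col]
            if host is None or (isinstance(host, float) and np.isnan(host)):
                continue
            if host in seen:
                continue
            seen.add(host)
            taxon = (taxa or {}).get(host)
            edges.append((host, row["emge_id"],
                          taxon[-1] if taxon else None))
    return pd.DataFrame(edges, columns=["host_id", "emge_id", "host_species"])
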