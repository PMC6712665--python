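"""Synthetic gut-community generator with ground truth.

Emulates the statistical structure each pipeline stage relies on: host
chromosomes carrying circular plasmids and linear phages with terminal
direct repeats; long reads sampled with wrap-around from circular
templates and truncation at the ends of linear ones; methylation-motif
profiles whose IPD ratios separate methylated from unmethylated contexts;
CRISPR arrays containing protospacers of resident phages; and cross-sample
read-count matrices in which elements covary with their hosts.

Chromosomes default to 50-100 kb — deliberately scaled-down stand-ins for
Mb-scale genomes that preserve every property the pipeline measures
(motif occurrence statistics, abundance coupling, read sampling) at a
fraction of the cost.

One root seed; every operation derives an independent child stream from a
stable label, so adding a stage never perturbs the output of another.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .classify import PLASMID_COGS
from .model import (AlignmentRecord, CircularContig, GeneAnnotation,
                    LinearGenome, MotifProfile, AbundanceMatrix, Unitig,
                    UnitigGraph, revcomp)
import pandas as pd

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
         "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT",
         "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT"}


def iupac_regex(motif: str) -> re.Pattern:
    return re.compile("".join(c if len(IUPAC[c]) == 1 else
                              f"[{IUPAC[c]}]" for c in motif))


def count_motif(sequence: str, motif: str) -> int:
    """Occurrences of a (possibly degenerate) motif, overlaps included."""
    pat = re.compile("(?=" + "".join(
        c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in motif) + ")")
    return len(pat.findall(sequence))


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Independent stream derived from the root seed by a stable label."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2 ** 31),
                                zlib.crc32(label.encode())]))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=int(n))].tobytes().decode()


# ------------------------------------------------------------- config

@dataclass
class SimConfig:
    """Study conditions of the synthetic community."""

    n_hosts: int = 5
    n_plasmids: int = 10
    n_phages: int = 3
    chromosome_length: tuple[int, int] = (50_000, 100_000)
    plasmid_length: tuple[int, int] = (5_000, 30_000)
    phage_length: tuple[int, int] = (25_000, 40_000)
    tdr_length: tuple[int, int] = (1_000, 3_000)

    # reads
    read_length_median: float = 8_000.0
    read_length_sigma: float = 0.4      # lognormal shape
    min_read_length: int = 500
    long_error_rate: float = 0.10
    short_error_rate: float = 0.002
    depth: float = 30.0

    # methylation / IPD model
    motifs_per_host: tuple[int, int] = (1, 3)
    motif_length: tuple[int, int] = (4, 6)
    include_gatc: bool = True
    ipd_methylated_mean: float = 4.0
    ipd_methylated_sd: float = 0.5
    ipd_unmethylated_mean: float = 1.0
    ipd_unmethylated_sd: float = 0.2
    fraction_methylated_beta: tuple[float, float] = (18.0, 2.0)
    fraction_unmethylated_beta: tuple[float, float] = (1.0, 19.0)
    motif_coverage_mean: float = 60.0

    # cross-sample abundance
    n_samples: int = 50
    total_reads_per_sample: int = 200_000
    host_abundance_sigma: float = 1.0
    coupling_noise_sd: float = 0.3
    plasmid_copy_number: float = 1.5
    phage_copy_number: float = 2.0

    # CRISPR
    spacers_per_phage: tuple[int, int] = (2, 4)
    spacer_length: tuple[int, int] = (25, 40)
    decoy_spacers_per_host: int = 5

    seed: int = 0

    def validate(self) -> None:
        for rate in (self.long_error_rate, self.short_error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("error rates must lie in [0, 1]")
        for lo, hi in (self.chromosome_length, self.plasmid_length,
                       self.phage_length, self.tdr_length):
            if lo <= 0 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")
        if 2 * self.tdr_length[1] >= self.phage_length[0]:
            raise ValueError("TDRs may not cover a whole phage genome")
        if self.depth < 0 or self.n_samples < 1:
            raise ValueError("invalid depth or sample count")


# ------------------------------------------------------------ community

_TAXON_POOL = ("Bacteroidetes", "Firmicutes", "Proteobacteria",
               "Actinobacteria")


@dataclass
class Chromosome:
    id: str
    sequence: str
    taxon: tuple[str, str, str]
    bin_id: str
    motifs: tuple[str, ...]


@dataclass
class Plasmid:
    id: str
    sequence: str  # circular
    host_id: str
    copy_number: float


@dataclass
class Phage:
    id: str
    sequence: str  # linear, TDR at both ends
    tdr_length: int
    host_id: str
    copy_number: float

    @property
    def genome(self) -> LinearGenome:
        return LinearGenome(self.id, self.sequence, self.tdr_length)


@dataclass
class CommunityTruth:
    chromosomes: list[Chromosome]
    plasmids: list[Plasmid]
    phages: list[Phage]
    crispr_arrays: dict[str, list[tuple[str, str]]]
    seed: int

    def host_of(self) -> dict[str, str]:
        out = {p.id: p.host_id for p in self.plasmids}
        out.update({p.id: p.host_id for p in self.phages})
        return out

    def chromosome_by_id(self) -> dict[str, Chromosome]:
        return {c.id: c for c in self.chromosomes}

    def elements(self) -> list[tuple[str, int, str, float]]:
        """(id, length, host_id or '', copy_number) for every replicon."""
        rows = [(c.id, len(c.sequence), c.id, 1.0) for c in self.chromosomes]
        rows += [(p.id, len(p.sequence), p.host_id, p.copy_number)
                 for p in self.plasmids]
        rows += [(p.id, len(p.sequence), p.host_id, p.copy_number)
                 for p in self.phages]
        return rows


def _sample_motifs(rng: np.random.Generator, config: SimConfig,
                   taken: set[str]) -> tuple[str, ...]:
    k = rng.integers(config.motifs_per_host[0],
                     config.motifs_per_host[1] + 1)
    out = []
    while len(out) < k:
        m = random_dna(rng, rng.integers(config.motif_length[0],
                                         config.motif_length[1] + 1))
        if m == "GATC" or m in taken:
            continue
        taken.add(m)
        out.append(m)
    return tuple(out)


def generate_community(config: SimConfig) -> CommunityTruth:
    config.validate()
    rng = child_rng(config.seed, "community")
    taken: set[str] = set()
    chromosomes = []
    for i in range(config.n_hosts):
        length = rng.integers(config.chromosome_length[0],
                              config.chromosome_length[1] + 1)
        phylum = _TAXON_POOL[i % len(_TAXON_POOL)]
        motifs = _sample_motifs(rng, config, taken)
        if config.include_gatc:
            motifs = motifs + ("GATC",)
        chromosomes.append(Chromosome(
            id=f"host{i}", sequence=random_dna(rng, length),
            taxon=(phylum, f"Genus{i}", f"Genus{i} species{i}"),
            bin_id=f"bin{i}", motifs=motifs))

    plasmids = []
    for i in range(config.n_plasmids):
        length = rng.integers(config.plasmid_length[0],
                              config.plasmid_length[1] + 1)
        host = chromosomes[i % config.n_hosts]
        plasmids.append(Plasmid(
            id=f"plasmid{i}", sequence=random_dna(rng, length),
            host_id=host.id, copy_number=float(config.plasmid_copy_number)))

    phages = []
    for i in range(config.n_phages):
        total = int(rng.integers(config.phage_length[0],
                                 config.phage_length[1] + 1))
        tdr_len = int(rng.integers(config.tdr_length[0],
                                   config.tdr_length[1] + 1))
        if 2 * tdr_len >= total:
            raise ValueError("drawn TDR longer than half the phage genome")
        tdr = random_dna(rng, tdr_len)
        core = random_dna(rng, total - 2 * tdr_len)
        host = chromosomes[i % config.n_hosts]
        phages.append(Phage(id=f"phage{i}", sequence=tdr + core + tdr,
                            tdr_length=tdr_len, host_id=host.id,
                            copy_number=float(config.phage_copy_number)))

    arrays: dict[str, list[tuple[str, str]]] = {c.id: [] for c in chromosomes}
    srng = child_rng(config.seed, "crispr")
    for phage in phages:
        k = srng.integers(config.spacers_per_phage[0],
                          config.spacers_per_phage[1] + 1)
        for j in range(k):
            L = int(srng.integers(config.spacer_length[0],
                                  config.spacer_length[1] + 1))
            pos = int(srng.integers(0, len(phage.sequence) - L + 1))
            seq = phage.sequence[pos:pos + L]
            if srng.random() < 0.5:
                seq = revcomp(seq)
            arrays[phage.host_id].append((f"{phage.id}_sp{j}", seq))
    for c in chromosomes:
        for j in range(config.decoy_spacers_per_host):
            L = int(srng.integers(config.spacer_length[0],
                                  config.spacer_length[1] + 1))
            arrays[c.id].append((f"{c.id}_decoy{j}", random_dna(srng, L)))
    return CommunityTruth(chromosomes=chromosomes, plasmids=plasmids,
                          phages=phages, crispr_arrays=arrays,
                          seed=config.seed)


# ---------------------------------------------------------------- reads

def _apply_errors(rng: np.random.Generator, seq: str,
                  rate: float) -> tuple[str, int]:
    """i.i.d. substitution (60%) / insertion (20%) / deletion (20%) error
    model; returns (mutated sequence, number of errors)."""
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    err_mask = rng.random(n) < rate
    n_err = int(err_mask.sum())
    if n_err == 0:
        return seq, 0
    kinds = rng.random(n)
    out = []
    err_positions = set(np.flatnonzero(err_mask).tolist())
    for i, b in enumerate(arr):
        if i not in err_positions:
            out.append(chr(b))
            continue
        k = kinds[i]
        if k < 0.6:  # substitution
            choices = [c for c in "ACGT" if c != chr(b)]
            out.append(choices[int(rng.integers(0, 3))])
        elif k < 0.8:  # insertion before the base
            out.append(random_dna(rng, 1))
            out.append(chr(b))
        # else deletion: emit nothing
    return "".join(out), n_err


def simulate_reads(truth: CommunityTruth, config: SimConfig,
                   error_rate: float | None = None,
                   depth: float | None = None,
                   label: str = "reads"
                   ) -> tuple[list[tuple[str, str]], list[AlignmentRecord]]:
    """Long reads from every replicon, with true source alignments.

    Read numbers per template are Poisson with mean proportional to
    length x copy number.  Circular templates wrap; linear templates are
    sampled with truncation at the molecule ends (reads can never span
    from the right terminal repeat into the left one, because no such
    molecule exists).
    """
    templates = []
    for c in truth.chromosomes:
        templates.append((c.id, c.sequence, "linear", 1.0))
    for p in truth.plasmids:
        templates.append((p.id, p.sequence, "circular", p.copy_number))
    for ph in truth.phages:
        templates.append((ph.id, ph.sequence, "linear", ph.copy_number))
    return simulate_reads_from_templates(
        templates, config, error_rate=error_rate, depth=depth,
        rng=child_rng(config.seed, label))


def simulate_reads_from_templates(templates, config: SimConfig,
                                  error_rate: float | None = None,
                                  depth: float | None = None,
                                  rng: np.random.Generator | None = None
                                  ) -> tuple[list[tuple[str, str]],
                                             list[AlignmentRecord]]:
    """templates: iterable of (id, sequence, topology, copy_number)."""
    if rng is None:
        rng = child_rng(config.seed, "reads")
    rate = config.long_error_rate if error_rate is None else error_rate
    target_depth = config.depth if depth is None else depth
    mean_len = config.read_length_median * \
        float(np.exp(config.read_length_sigma ** 2 / 2.0))
    reads: list[tuple[str, str]] = []
    alignments: list[AlignmentRecord] = []
    counter = 0
    for tid, seq, topology, copy in templates:
        L = len(seq)
        n_reads = rng.poisson(target_depth * copy * L / mean_len)
        lengths = np.exp(rng.normal(np.log(config.read_length_median),
                                    config.read_length_sigma,
                                    size=n_reads))
        lengths = np.clip(lengths, config.min_read_length, L).astype(int)
        for rl in lengths:
            rl = int(rl)
            if topology == "circular":
                start = int(rng.integers(0, L))
                end = start + rl
                raw = (seq + seq)[start:start + rl]
            else:
                lo = -(rl - config.min_read_length)
                hi = L - config.min_read_length
                u = int(rng.integers(lo, hi + 1))
                start = max(u, 0)
                end = min(u + rl, L)
                raw = seq[start:end]
            read_seq, n_err = _apply_errors(rng, raw, rate)
            rid = f"read{counter}"
            counter += 1
            block = end - start
            identity = max(0.0, 1.0 - n_err / block)
            reads.append((rid, read_seq))
            alignments.append(AlignmentRecord(
                query_id=rid, target_id=tid, query_start=0,
                query_end=len(read_seq), target_start=start,
                target_end=end, strand="+", identity=identity,
                aligned_length=block, query_length=len(read_seq),
                target_length=L))
    return reads, alignments


# ----------------------------------------------------- TDR mis-assembly

def misassemble_tdr_as_circle(phage: Phage | LinearGenome
                              ) -> tuple[CircularContig, tuple[int, int]]:
    """Collapse a TDR genome's two repeat copies into one, as an overlap
    assembler does, returning the resulting circle and the ground-truth
    repeat interval in circle coordinates."""
    t = phage.tdr_length
    if t <= 0:
        raise ValueError("genome has no terminal repeat to collapse")
    seq = phage.sequence
    circle = CircularContig(id=phage.id, sequence=seq[: len(seq) - t])
    return circle, (0, t)


def reexpand_circle(circle: CircularContig,
                    tdr_interval: tuple[int, int]) -> str:
    """Inverse of the mis-assembly: duplicate the recorded repeat interval
    back onto the end (exact for error-free sequence)."""
    s, e = tdr_interval
    rotated = circle.sequence[s:] + circle.sequence[:s]
    return rotated + rotated[: e - s]


def collapse_alignment(aln: AlignmentRecord, linear_length: int,
                       tdr_length: int) -> AlignmentRecord:
    """Project a read's true interval on the linear TDR genome onto the
    collapsed circle (wrap-around expressed as target_end beyond the
    circle length)."""
    C = linear_length - tdr_length
    start = aln.target_start
    if start >= C:
        start -= C
    return replace(aln, target_start=start,
                   target_end=start + (aln.target_end - aln.target_start),
                   target_length=C)


def misassembled_circle_with_reads(phage: Phage, config: SimConfig,
                                   error_rate: float = 0.0,
                                   depth: float | None = None,
                                   label: str | None = None
                                   ) -> tuple[CircularContig,
                                              tuple[int, int],
                                              list[AlignmentRecord]]:
    """Convenience: collapse a phage and return read alignments mapped to
    the collapsed circle's coordinates."""
    circle, interval = misassemble_tdr_as_circle(phage)
    _, alns = simulate_reads_from_templates(
        [(phage.id, phage.sequence, "linear", 1.0)], config,
        error_rate=error_rate, depth=depth,
        rng=child_rng(config.seed, label or f"tdr-reads:{phage.id}"))
    collapsed = [collapse_alignment(a, len(phage.sequence),
                                    phage.tdr_length) for a in alns]
    return circle, interval, collapsed


# ------------------------------------------------------- motif profiles

def simulate_motif_profiles(truth: CommunityTruth,
                            config: SimConfig) -> list[MotifProfile]:
    """IPD/methylation profiles for every (replicon, motif) pair over the
    union of host motifs.  Elements inherit the methylation state of
    their true host; motifs absent from a sequence yield missing values.
    """
    rng = child_rng(config.seed, "motifs")
    universe = sorted({m for c in truth.chromosomes for m in c.motifs})
    methylates: dict[str, set[str]] = {
        c.id: set(c.motifs) for c in truth.chromosomes}
    host = truth.host_of()
    seqs = [(c.id, c.sequence, methylates[c.id]) for c in truth.chromosomes]
    seqs += [(p.id, p.sequence, methylates[host[p.id]])
             for p in truth.plasmids]
    seqs += [(p.id, p.sequence, methylates[host[p.id]])
             for p in truth.phages]
    profiles = []
    for sid, seq, meth in seqs:
        for motif in universe:
            mod_type = "m6A" if "A" in motif else "m4C"
            occ = count_motif(seq, motif)
            if occ == 0:
                profiles.append(MotifProfile(sequence_id=sid, motif=motif,
                                             mod_type=mod_type))
                continue
            if motif in meth:
                ipd = rng.normal(config.ipd_methylated_mean,
                                 config.ipd_methylated_sd)
                frac = rng.beta(*config.fraction_methylated_beta)
            else:
                ipd = rng.normal(config.ipd_unmethylated_mean,
                                 config.ipd_unmethylated_sd)
                frac = rng.beta(*config.fraction_unmethylated_beta)
            cov = max(1.0, rng.normal(config.motif_coverage_mean,
                                      config.motif_coverage_mean * 0.1))
            profiles.append(MotifProfile(
                sequence_id=sid, motif=motif, mod_type=mod_type,
                methylated_fraction=float(np.clip(frac, 0.0, 1.0)),
                mean_coverage=float(cov),
                mean_ipd_ratio=float(max(ipd, 0.0))))
    return profiles


# --------------------------------------------------- abundance matrices

def simulate_abundance_matrix(truth: CommunityTruth,
                              config: SimConfig) -> AbundanceMatrix:
    """Read-count matrix over samples.

    Host cell abundances are log-normal per sample; each element's molar
    abundance is its host's times its copy number times log-normal
    coupling noise; expected read mass is molar abundance times length and
    counts are one multinomial draw of the per-sample read budget.
    """
    rng = child_rng(config.seed, "abundance")
    elements = truth.elements()
    ids = [e[0] for e in elements]
    lengths = np.array([e[1] for e in elements], dtype=float)
    hosts = [e[2] for e in elements]
    copies = np.array([e[3] for e in elements], dtype=float)
    host_ids = [c.id for c in truth.chromosomes]
    host_index = {h: i for i, h in enumerate(host_ids)}
    is_chrom = np.array([e[0] in host_index for e in elements])

    counts = np.zeros((len(ids), config.n_samples), dtype=float)
    for s in range(config.n_samples):
        host_ab = np.exp(rng.normal(0.0, config.host_abundance_sigma,
                                    size=len(host_ids)))
        molar = host_ab[[host_index[h] for h in hosts]] * copies
        # mean-one multiplicative noise so coupling leaves copy number unbiased
        sd = config.coupling_noise_sd
        noise = np.exp(rng.normal(-sd * sd / 2.0, sd, size=len(ids)))
        noise[is_chrom] = 1.0
        mass = molar * noise * lengths
        p = mass / mass.sum()
        counts[:, s] = rng.multinomial(config.total_reads_per_sample, p)
    frame = pd.DataFrame(counts, index=ids,
                         columns=[f"sample{s}"
                                  for s in range(config.n_samples)])
    return AbundanceMatrix(frame, pd.Series(lengths, index=ids))


# ------------------------------------------------------ gene annotation

_CATEGORIES = "CDEFGHIJKLMNOPQRSTUVWX"


def simulate_gene_annotations(truth: CommunityTruth, config: SimConfig,
                              arg_fraction: float = 0.3
                              ) -> list[GeneAnnotation]:
    """Gene tables with the signals the classifier and the enrichment
    stage expect: phage genes largely POG-positive at high hit coverage,
    plasmid genes carrying mobilisation/replication COGs and a bias toward
    ion-transport functions, chromosome genes carrying the host taxon and
    a bias toward carbohydrate metabolism.  A random subset of plasmids is
    ARG-positive."""
    rng = child_rng(config.seed, "genes")
    genes: list[GeneAnnotation] = []

    def tile(contig_id, seq_len):
        pos = 0
        out = []
        while pos + 600 <= seq_len:
            glen = int(rng.integers(600, 1201))
            end = min(pos + glen, seq_len)
            out.append((pos, end))
            pos = end + int(rng.integers(20, 120))
        return out

    arg_plasmids = {p.id for p in truth.plasmids
                    if rng.random() < arg_fraction}
    for c in truth.chromosomes:
        for k, (s, e) in enumerate(tile(c.id, len(c.sequence))):
            cat = "G" if rng.random() < 0.3 else \
                _CATEGORIES[int(rng.integers(0, len(_CATEGORIES)))]
            genes.append(GeneAnnotation(
                gene_id=f"{c.id}_g{k}", contig_id=c.id, start=s, end=e,
                cog_id=f"COG{int(rng.integers(1, 6000)):04d}",
                cog_category=cat, taxon=c.taxon))
    plasmid_cog_pool = sorted(PLASMID_COGS)
    for p in truth.plasmids:
        coords = tile(p.id, len(p.sequence))
        arg_genes = set()
        if p.id in arg_plasmids and coords:
            arg_genes = set(rng.choice(len(coords),
                                       size=min(2, len(coords)),
                                       replace=False).tolist())
        for k, (s, e) in enumerate(coords):
            if k < 2:
                cog = plasmid_cog_pool[int(rng.integers(0,
                                                        len(plasmid_cog_pool)))]
                cat = "X"
            elif rng.random() < 0.5:
                cog = f"COG{int(rng.integers(1, 6000)):04d}"
                cat = "P" if rng.random() < 0.4 else \
                    _CATEGORIES[int(rng.integers(0, len(_CATEGORIES)))]
            else:
                cog, cat = None, None
            genes.append(GeneAnnotation(
                gene_id=f"{p.id}_g{k}", contig_id=p.id, start=s, end=e,
                cog_id=cog, cog_category=cat, is_arg=k in arg_genes))
    for ph in truth.phages:
        for k, (s, e) in enumerate(tile(ph.id, len(ph.sequence))):
            hit = rng.random() < 0.8
            coverage = float(rng.uniform(0.91, 1.0)) if hit else \
                float(rng.uniform(0.2, 0.85))
            genes.append(GeneAnnotation(
                gene_id=f"{ph.id}_g{k}", contig_id=ph.id, start=s, end=e,
                pog_hit=True, hit_coverage=coverage))
    return genes


# ------------------------------------------------------- unitig graphs

def community_to_graph(truth: CommunityTruth, config: SimConfig,
                       n_noise_unitigs: int = 4) -> UnitigGraph:
    """Unitig graph as the assembler would leave it: chromosomes as
    same-bin chains, plasmids as same-bin cycles (their host's bin),
    phages as cycles of the TDR-collapsed circle under their own bin,
    plus unbinned noise unitigs."""
    rng = child_rng(config.seed, "graph")
    graph = UnitigGraph()
    host_bin = {c.id: c.bin_id for c in truth.chromosomes}

    def add_path(name, seq, bin_id, n_pieces, circular):
        cuts = sorted(rng.choice(np.arange(1, len(seq)),
                                 size=n_pieces - 1, replace=False).tolist()) \
            if n_pieces > 1 else []
        bounds = [0] + cuts + [len(seq)]
        junctions = [graph.new_junction() for _ in range(n_pieces + 1)]
        if circular:
            junctions[-1] = junctions[0]
        for i in range(n_pieces):
            graph.add_unitig(
                Unitig(f"{name}_u{i}", seq[bounds[i]:bounds[i + 1]],
                       depth=float(config.depth), bin_id=bin_id),
                from_junction=junctions[i], to_junction=junctions[i + 1])

    for c in truth.chromosomes:
        add_path(c.id, c.sequence, c.bin_id,
                 int(rng.integers(3, 6)), circular=False)
    for p in truth.plasmids:
        add_path(p.id, p.sequence, host_bin[p.host_id],
                 int(rng.integers(2, 5)), circular=True)
    for ph in truth.phages:
        circle, _ = misassemble_tdr_as_circle(ph)
        add_path(ph.id, circle.sequence, f"bin_{ph.id}",
                 int(rng.integers(2, 4)), circular=True)
    for i in range(n_noise_unitigs):
        graph.add_unitig(Unitig(f"noise{i}",
                                random_dna(rng, int(rng.integers(500, 3000))),
                                depth=1.0, bin_id=f"UNBINNED:noise{i}"))
    return graph


def random_unitig_graph(rng: np.random.Generator, n_unitigs: int,
                        n_bins: int = 3, n_junctions: int | None = None,
                        seq_length: tuple[int, int] = (80, 300)
                        ) -> UnitigGraph:
    """A random small unitig graph for exercising the bin-guided merger:
    random incidences and bin assignments produce a mix of mergeable
    junctions, conflicts, branches and self-loops."""
    graph = UnitigGraph()
    if n_junctions is None:
        n_junctions = int(rng.integers(max(2, n_unitigs // 2),
                                       n_unitigs + 2))
    junctions = [graph.new_junction() for _ in range(n_junctions)]
    for i in range(n_unitigs):
        seq = random_dna(rng, int(rng.integers(*seq_length)))
        bin_id = f"B{int(rng.integers(0, n_bins))}"
        fj = junctions[int(rng.integers(0, n_junctions))]
        tj = junctions[int(rng.integers(0, n_junctions))]
        graph.add_unitig(Unitig(f"u{i}", seq, depth=float(rng.uniform(5, 50)),
                                bin_id=bin_id),
                         from_junction=fj, to_junction=tj)
    return graph
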