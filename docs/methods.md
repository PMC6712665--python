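# Methods

This note records the models, parameter choices and numerical conventions
behind `emgekit`, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinate and sequence conventions

All intervals are 0-based half-open; the substring an interval names
always has length `end − start`.  Sequences are stored in one orientation
with reverse complement expressed by a strand flag.  Alignment identity is
matches / alignment block length (PAF semantics); every identity threshold
in the pipeline applies to this quantity.  Circular sequences are
compared through a canonical form: the lexicographically smaller of the
minimal rotations of the sequence and of its reverse complement (Booth's
algorithm).

## Bin-guided circularization

The merge rule is purely local: a junction with exactly one arriving and
one leaving unitig of equal bin ID concatenates them (successor trimmed by
the junction's recorded overlap, default 0), with depth merged as the
length-weighted mean.  Merges at distinct junctions commute, so the fixed
point is independent of processing order; the test suite checks this by
permuting orders and by exhaustively enumerating merge sequences on small
random graphs.  Orientation conflicts (head-to-head or tail-to-tail
meetings) are skipped with a warning rather than resolved by reverse
complementing — the conservative choice.  Merging is applied to a fixed
point by default; a single-sweep mode is exposed (`--single-pass`) for
users who want the most conservative behaviour.  Circles are self-loop
unitigs of at least 2 200 bp, the assembler's minimum overlap length,
below which a circle cannot be distinguished from an artefact of the
overlap cutoff.

## TDR detection

For a linear genome of length L with a terminal repeat of length t, the
collapsed circle has length C = L − t.  Three read-mapping signals
identify the repeat, and the detector requires all of them:

* **Terminus pileups (primary).**  Reads truncated at the molecule's ends
  map with their 5′ terminus exactly at the repeat's start and their 3′
  terminus exactly at its end.  The detector takes the strongest exact
  start-position and end-position pileups as candidate boundaries,
  requiring at least `min_pileup` (5) reads each and an excess of at
  least 3× the background per-window terminus rate.  With error-free
  reads this yields base-exact boundaries; with real data the window
  parameter absorbs mapping jitter.
* **Depth doubling.**  Mean depth inside the candidate must be at least
  1.6× the mean outside.  Long reads at moderate coverage (~30×, median
  8 kb) provide only ~100–150 reads per genome, making this ratio noisy
  (sd ≈ 0.25); when a short-read track is supplied the ratio is measured
  on it instead, since thousands of short reads estimate depth with a few
  per cent error.  The reported `coverage_ratio` is therefore the densest
  track's value.
* **Absence of spanning reads.**  No alignment may contain the candidate
  with 100-bp flanks on both sides (circular coordinates, alignments
  unrolled): no template molecule joins the right repeat copy to the left
  flank, so even reads longer than the circle cannot span.

Candidates must be 500 bp to half the circle long.  Linearization rotates
the circle to start at the repeat and appends a verbatim second copy, so
`linearize ∘ misassemble` is the identity on error-free sequence; no
consensus polishing between the two copies is attempted because observed
repeat copies are nearly identical.

GC skew uses 100-bp windows with 50-bp steps; windows without G or C are
missing.  The replication-strand transition is the extremum of the
cumulative skew (missing treated as 0), reported with both the minimum
and maximum positions.

## Classification

Phage calling uses the fraction of genes with POG hits covering strictly
more than 90 % of the gene; the calling threshold on that fraction is not
canonically fixed and defaults to 0.5 (configurable).  The 13
plasmid-diagnostic COGs (replication, toxin–antitoxin, type IV secretion)
and reference assignments (identity ≥ 0.90 weighted over alignment
blocks, contig coverage ≥ 0.70 after merging intervals) provide plasmid
evidence.  Plasmid is the default class; external phage verdicts in
categories 1, 2, 4, 5 count as phage evidence while 3 and 6 are ignored
as false-positive-prone.  A reference plasmid assignment overrides phage
evidence and flags the call as a conflict, mirroring how apparent
phage-like plasmids are resolved in practice.

## Host prediction

* **Co-occurrence**: Spearman rank correlation (average ranks for ties)
  of length-normalised abundance across ≥ 3 samples; hosts at ρ ≥ 0.7.
  Constant profiles are skipped rather than given an arbitrary ρ.
* **CRISPR spacers**: ungapped Hamming comparison of each spacer
  (≥ 20 bp) and its substrings longer than 95 % of the spacer against
  both phage strands, accepting ≤ 1 mismatch; gapped alignment is out of
  scope at these lengths.  Score = mismatch count.
* **Methylation motifs**: chromosomal motifs with methylated fraction
  ≥ 0.6 and mean coverage ≥ 25 serve as baits; GATC/m6A is always removed
  because it is near-universally methylated among bacteria and carries no
  host information.  Mean IPD ratios binarise at > 2.5.  An element links
  to a bin when (a) at least one baited motif is methylated on both —
  a shared methylation *mark*, not merely a shared motif occurrence, which
  prevents links supported only by jointly unmethylated contexts — and
  (b) no baited motif present on both disagrees (missing values are
  wildcards).  Thresholds 0.6 and 25 are inclusive; 2.5 is strict,
  following the convention that methylation means "higher than" the
  cutoff.

Consolidation lists each method's best host per element and flags
rank-by-rank agreement or conflict on the provided taxon strings; no
method overrides another, and no taxonomy database is consulted.

## Quantification and statistics

Breadth of coverage is the unioned aligned fraction of an element;
elements under 60 % are excluded from quantification as unevenly or
negligibly covered.  Dereplication marks a pair similar at identity
≥ 0.90 (alignment-length-weighted mean), coverage of the **shorter**
sequence ≥ 0.70, and length ratio ≥ 0.7; clusters are connected
components (single linkage).  Cluster abundance counts each read once at
its best ≥ 95 %-identity hit, normalised per kb of the longest
representative.  The element-per-chromosome ratio
`(reads_e / sizē_e) / (reads_c / sizē_c)` converts read densities to
molecule counts; it is exact when sizes are homogeneous and unbiased when
copy numbers and sizes are uncorrelated.  It errors on zero chromosome
reads rather than returning infinity.

Composition from contigs scores each taxon by Σ depth(contig)/length(gene)
over its genes and normalises; the score is proportional to sequence mass
per taxon.  Fisher tests are two-sided by the minimum-likelihood
definition (scipy); q-values are Benjamini–Hochberg by default with a
Storey-style option (π₀ estimated at λ = 0.5).  The rank-sum test
enumerates the exact permutation null by dynamic programming over the
(tie-averaged) rank multiset whenever C(n+m, n) ≤ 2·10⁵, with two-sided
p = 2·min(tails) capped at 1, and otherwise uses the tie-corrected normal
approximation with continuity correction.

## Synthetic community

Defaults define the study conditions: 5 host chromosomes (50–100 kb),
10 circular plasmids (5–30 kb, 2 per host at copy number 1.5, i.e. 3.0
plasmid copies per chromosome), 3 linear phages (25–40 kb) with 1–3-kb
terminal repeats copied verbatim to both ends, 50 samples, 2·10⁵ reads
per sample.  Chromosome lengths are scaled-down stand-ins for Mb genomes;
they preserve everything the pipeline measures (motif occurrence
statistics, abundance coupling, read-sampling proportionality) at a
fraction of the cost, and all sizes are configurable.

Reads: counts per replicon are Poisson with mean depth × copy ×
length / mean-read-length; lengths are log-normal (median 8 kb, shape
0.4; a short-read profile uses median 150 bp).  Circular templates are
sampled with wrap-around; linear templates with truncation at the
molecule ends, which is what creates the terminus pileups the TDR
detector exploits — and, by construction, no read crosses from the right
repeat into the left one.  Errors are i.i.d. substitution/indel
(60/20/20 %) without homopolymer bias — sufficient to stress identity
thresholds, not a kinetics model.

IPD ratios are Normal on the ratio scale: methylated mean 4.0 (sd 0.5),
unmethylated mean 1.0 (sd 0.2), so the 2.5 cutoff separates the classes
at ≈ 3σ; methylated fractions are Beta(18, 2) (≈ 0.9) versus Beta(1, 19)
(≈ 0.05).  Motifs are distinct random 4–6-mers per host plus the
ubiquitous GATC, which every host methylates and the bait filter must
remove.  Elements inherit their true host's methylation states; motifs
absent from a sequence yield missing profiles.

Cross-sample abundance: host cell abundances are log-normal (σ = 1) per
sample; element molar abundance is host × copy number × mean-one
log-normal coupling noise (σ = 0.3; the location −σ²/2 keeps the
coupling unbiased); expected read mass is molar abundance × length, and
counts are one multinomial draw of the per-sample budget, so columns sum
exactly to the budget.  CRISPR arrays receive 2–4 protospacers (25–40 bp,
either strand) of each resident phage plus 5 random decoys per host.

One root seed; every stage derives an independent generator stream from a
stable label (CRC of the label mixed into the seed sequence), so adding a
stage never perturbs another's output and equal seeds are byte-identical.

**What passing does and does not show.**  The generator reproduces the
statistical structure each stage assumes — not real data.  It has no
strain microdiversity, chimeric reads, GC bias, homopolymer errors,
inter-element homology (except where tests construct it), compositional
binning noise, or incomplete/contaminated bins.  Perfect recovery here
demonstrates correctness of the algorithms under their stated
assumptions, not field performance; thresholds inherited from practice
(2.2 kb, 90/70/0.7, 0.6/25/2.5, ρ 0.7) are used as given, not re-derived.

## Problem sizes in the automated runs

The test suite and `scripts/acceptance.py` run communities at the default
sizes above; TDR experiments use 20 genomes plus 20 circular negative
controls at 30× long-read and 30× short-read coverage; the ratio
estimator uses 10⁵ reads per community across 20 (tests) or 5 (script)
seeds; statistical oracles enumerate exactly up to N = 60 (Fisher) and
n + m ≤ 12 (rank-sum).  These sizes keep a full run within seconds to a
few minutes on one CPU.

## Known limitations

* The merge rule resolves only 1-in/1-out junctions; repeats that create
  higher-degree junctions within one bin are left untangled.
* TDR boundary refinement assumes reads map with exact termini; heavily
  soft-clipped alignments would blur the pileups (the window parameter
  mitigates, at the cost of boundary resolution).
* The host-prediction methods report all passing candidates; they do not
  model phylogenetically close non-hosts sharing methylation systems or
  spacer banks, which real communities contain.
* The per-COG Fisher test treats genes as independent observations, as is
  conventional, ignoring within-replicon correlation.
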