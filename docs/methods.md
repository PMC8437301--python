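# Methods

## Single-read junction detection

A breakpoint junction is evidenced by one split read: a read whose primary
alignment is soft-clipped and whose remaining portion maps elsewhere as a
supplementary alignment, cross-referenced by the SAM `SA:Z` tag. Because a
single read is the entire evidence, the filter is stringent by design and
every criterion is applied to **both** aligned segments:

- aligned read-span ≥ `min_segment_length` (default 40 bp);
- mapping quality equal to (not merely at least) the aligner's maximum,
  default 60 as produced by BWA-MEM; the value is configurable for other
  aligners;
- no segment clipped on both of its ends ("one-sided clip"). We interpret
  the one-sided-clip rule per segment: each alignment must be clipped only
  on its junction side, which guarantees the two segments jointly tile the
  read and makes signature classification well defined. The alternative
  per-read reading is switchable via `FilterConfig.forbid_double_clipped`.

Reads with more than one supplementary alignment (more than one `SA` entry)
are discarded and counted: the analysis is restricted to two-segment
junctions. All information is taken from the soft-clipped primary record's
CIGAR plus the `SA` entry; hard-clipped supplementary records are redundant
and need not even be present in the stream. Coordinates are 0-based
half-open internally (SAM converted at parse; BEDPE written 0-based);
breakends are ordered canonically by (contig rank, coordinate, strand).

On a circular contig (the mitochondrial chromosome), reads spanning the
linearisation point produce artefactual "junctions" joining the contig's
start and end. A junction is therefore dropped when both breakends lie on
the same circular contig with one within `end_window` of position 0 and the
other within `end_window` of the contig end. The window defaults to one
read length (126 bp); no principled larger value presents itself, since a
genuine split read cannot reach further than a read length across the
origin.

Indel-bearing reads — non-split mapped reads whose CIGAR contains at least
one I or D operation — are counted once per read as a parallel, NHEJ-
associated mutation channel.

## Breakpoint signatures

Classification is purely read-coordinate arithmetic on the two segments'
CIGAR-derived intervals: overlap = microhomology length, adjacency = blunt,
gap = insertion length. Working in read space rather than re-aligning
reference flanks makes the call tolerant of imperfect homology inside the
overlap (mismatches or small indels within the microhomology do not change
the interval arithmetic). Spectra index counts by signed length (negative =
insertion, 0 = blunt, positive = microhomology); lengths beyond 20 bp are
retained in the data and folded into a ">20" bin only for display, matching
the conventional reporting range for MMEJ-scale microhomology.

## Null models

*Random junction sets.* For intersection analyses, each observed replicate
set is matched by an equally sized simulated set whose breakends are drawn
uniformly over the nuclear genome (contig chosen proportionally to length,
position uniform within contig). Only nuclear junctions are used and
simulated.

*Admixture model.* Given per-contig mapped-read counts converted to
proportions p, each of n junctions draws its two ends independently (with
replacement) with those probabilities. The closed-form expectation for the
unordered pair (i, j) is n·2pᵢpⱼ for i ≠ j and n·pᵢ² on the diagonal;
1000 Monte-Carlo simulations provide means and standard deviations, and
expectations sum exactly to n. Sampling ends with replacement (rather than
permuting a fixed pool of ends) is the natural model for free DNA ends and
was chosen where the procedure was underspecified.

*Validation harness.* n random fragments (default 100 × 100 bp) are copied
from elsewhere in the reference and inserted at random sites, each creating
two flank junctions; reads spanning both flanks are synthesized and the full
calling pipeline is scored against the truth table with a ±5 bp breakend
tolerance (microhomology at a junction makes the breakpoint coordinate
ambiguous by up to its length, so exact equality would be too strict in
general; our synthetic reads are in fact recovered exactly). Because the
harness synthesizes already-aligned reads, it measures the pipeline's own
correctness: sensitivity is 1.0 by construction for recoverable events, and
the false-positive count is the meaningful output. Sensitivity through a
real read simulator and aligner would additionally fold in those tools'
losses and is out of scope.

## Hotspots

Junctions are binned by the window (default 20 kb, last partial window
included) containing each breakend's junction-proximal coordinate, giving a
symmetric count matrix per contig pair (upper-triangle storage; grand total
equals the junction count). The old/young ratio matrix divides the oldest
timepoint's matrices element-wise by the youngest's; a pseudocount (default
1) regularises empty young cells, and with pseudocount 0 zero-denominator
cells are masked instead of reported as infinite. A bin's global hotspot
score is the mean of its ratio row across all windows genome-wide,
including its own diagonal cell by default (toggleable); bins are ranked
descending. Distance distributions compare intra-chromosomal breakend
separations for junctions touching hotspot bins vs all others with a
two-sided rank-sum test. The coverage-ratio check (per-bin median depth,
old/young) guards against repeat expansion masquerading as a hotspot.

## Feature-level analyses and metrics

A junction intersects a feature when **either** breakend lies within it
(switchable to both); windows `feature ± flank` are half-open. Coding
depletion is tested one-sidedly (observed < expected) with the rank-sum U
across replicates against matched random sets. Gene-end profiles record
strand-oriented breakend offsets within ±500 bp of CDS starts/ends,
smoothed with a 10 bp sliding mean and binned at 250 bp; adjacent bins are
compared with paired t-tests across replicates. 3'UTR outliers are genes
whose junction count strictly exceeds mean + 2·population SD (divisor n) of
all UTR counts; a zero-variance population flags nothing.

JPMR and IPMR divide a sample's junction and indel-read counts by its
mapped reads. Genome-wide relative metrics divide by the **median** of the
same genotype's Day-0 samples; feature-level JPMR (junctions with a
breakend within feature ± 500 bp, per mapped read) is normalised to the
Day-0 **mean** per genotype — the two conventions deliberately differ,
following the respective analyses they implement. Day pairs are compared
with paired t-tests matched by replicate. Normalised feature coverage is
mean per-base depth over the feature span divided by total mapped reads,
with conditions compared by a one-sample t-test on per-feature differences.

## Synthetic data generator

The generator emulates the structure of an ageing-pool sequencing study: 6
timepoints × 8 replicates, 126 nt reads, a small (~20 kb) circular
mitochondrial contig beside nuclear contigs, and rare heterogeneous
junctions — each supported by exactly one chimeric read — accumulating with
age via per-day junction rates (events per mapped read). Signature
composition defaults to a microhomology spectrum peaked at 5–6 bp with
minority blunt and 1–5 bp insertion classes. Where the emulated study fixes
no value we chose field-realistic defaults once: GC 0.36 (fission-yeast
like), gene models of 200 bp 5'UTR + 1.2 kb CDS + 300 bp 3'UTR, ~1 tRNA
per 10 genes, and a configurable coding-depletion factor that thins CDS
breakends during sampling so intersection tests have genuine signal.

Key design choices: reads are emitted as already-aligned SAM (one
soft-clipped primary + one hard-clipped supplementary with consistent
`SA` tags) rather than FASTQ through an aligner, isolating the pipeline
from aligner version drift (an optional FASTQ export exists); chimeric
reads are single-end; base-call errors default to 0 with a configurable
substitution rate; and microhomology is planted by editing the reference so
both loci genuinely share the seed sequence — the classifier is tested
against real sequence structure, not relabelled coordinates. Events whose
segments cannot reach the 40 bp filter minimum are emitted anyway and
flagged unrecoverable in the truth table.

What passing these tests shows — and does not. The generator produces
structurally clean reads: constant base quality, no mapping ambiguity, no
PCR duplicates, no paired-end insert modelling, uniform background
coverage. Green tests therefore demonstrate the pipeline's arithmetic and
filtering are exact under the stated evidence model; they do not bound
sensitivity on real libraries, where aligner behaviour, repeats and library
artefacts dominate losses.

## Problem sizes and numerics

The shipped test suite and acceptance script use sizes chosen to exercise
each property convincingly while remaining desk-scale: a 2.7 Mb + 20 kb
genome with 200 planted junctions for round-trip calling; ten 10⁵-read
clean fixtures for null purity; 1000 admixture simulations at n = 10⁴;
twenty seeded hotspot series on a 1 Mb genome (25 partner bins, onset day
3); 8 replicates × 500 junctions for depletion power plus 100 null runs for
type-I control. All randomness flows from explicit seeds; identical seeds
give byte-identical outputs. Rank-sum tests use the exact null distribution
when min(n) ≤ 10 without ties and the tie-corrected normal approximation
otherwise; degenerate statistics (zero-variance differences) propagate NaN
rather than failing.

## Limitations

- Two-segment junctions only; complex events with >1 supplementary
  alignment are counted but not analysed.
- No multi-read assembly or genotyping: a junction is a single read's
  observation, and recurrence across reads is not collapsed.
- MAPQ equality assumes a BWA-MEM-like aligner with a fixed maximum score.
- The exact sensitivity of the upstream aligner is not modelled; the
  validation harness isolates pipeline correctness from aligner losses.
- Motif discovery and gene-set enrichment are external: the package only
  exports junction-flank FASTA and outlier gene lists for those tools.
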