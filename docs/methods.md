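# Methods

## Scope and data model

`tepirna` analyses three data streams against one reference frame, a TE
consensus library (RepeatMasker-dialect FASTA, `id#subclass/superfamily`):

1. a low-coverage genomic skim (FASTQ/FASTA reads);
2. assembled transcripts with a protein-domain hit table
   (GAG/PROT/INT/RT/RH with optional RT clade labels);
3. a small-RNA pool (FASTQ).

Coordinates are 0-based half-open in memory and 1-based inclusive in TSV
exports (stated in each file's header).  Subclasses come from a closed
vocabulary (LTR, LINE, SINE, DNA, Helitron, Penelope, rRNA, satellite,
unclassified); unknown labels map to `unclassified`.

## Internal aligner

Both alignment modes are **ungapped**.  Divergence landscapes are
dominated by substitutions, and excluding indels keeps the
transition/transversion bookkeeping exact — a deliberate trade-off noted
under limitations.

**Genomic mode** (skim reads, consensus-vs-consensus): exact k-mer seeds
(default `seed_k = 12`) on both strands, extended on the seed diagonal to
the maximum-scoring window (match +1, mismatch −1; the optimum is found
in one vectorized pass over prefix sums, so no X-drop heuristic is
needed).  One best hit per read; ties break by lowest target id, then
lowest target start, then + strand.  Hits scoring below `min_score = 20`
are rejected: a chance 12-mer seed in multi-Mb random background extends
to a score near 12, and without this floor such hits would deposit
spurious low-divergence mass in the landscape.  True hits from reads
≥ 50 bp inside a copy score far above the floor at any divergence the
K2P estimator can handle.

**Small-RNA mode** (reads ≤ 50 nt): end-to-end, both strands, reporting
*all* placements in the best mismatch stratum with ≤ `max_mismatch`
(default 3) mismatches — the behaviour of `bowtie -v 3 -a`.  Sensitivity
is guaranteed by pigeonhole seeding: the read is cut into
`max_mismatch + 1` disjoint segments and any qualifying alignment must
contain one exact segment.  (A fixed 14-mer seed cannot give this
guarantee for 23-nt reads at 3 mismatches, so the segment length is
derived from the read, `len // (max_mismatch + 1)`.)

Alignment columns containing N never match; they are excluded from
`aligned_len` and the match/transition/transversion counts, so
`matches + mismatches = aligned_len` holds exactly.  Multi-mapped reads
carry weight `1 / (n_targets × n_placements_within_target)`: each target
family receives `1/n_targets` and total read mass is 1, so every
downstream total is conserved regardless of how the split is arranged.

## K2P distance and landscapes

For transition fraction `P` and transversion fraction `Q` (transitions
are A↔G and C↔T):

    K = −½ · ln((1 − 2P − Q) · √(1 − 2Q))

Arguments outside the domain (`1 − 2P − Q ≤ 0` or `1 − 2Q ≤ 0`) raise a
saturation error; saturated alignments are tallied separately by the
landscape, never silently dropped, so landscape mass plus the excluded
tally equals the quantified genome proportion exactly (this conservation
is property-tested).  Bins are 1% wide over [0, 35)%, weighted by
aligned bases over total sampled bases, aggregated per subclass.

**Resolution.**  A read of length `L` aligned to a consensus at mismatch
fraction `p` estimates K2P with standard deviation ≈
`K′(p)·√(p(1−p)/L)` — about 2.4 percentage points for `L = 150`,
`p = 0.08`.  Resolving 1%-wide bins therefore needs long alignments:
the landscape-recovery analyses use 500 bp fragments (merged-pair /
long-fragment scale), for which the sd drops to ~1.3 points and the
modal bin is stable.  The skim simulator's default read length elsewhere
is 150 bp (short-read scale), which is fine for quantification but
smears landscapes — a property of the statistic, not of the
implementation.

## Skim quantification

`g_f` = (weighted aligned bases of family *f*) / (total sampled bases);
`N̂_f = round(g_f · G / L_f)`.  `G` may come from a C-value with the
standard cytogenetic constant 1 pg = 978 Mbp.  This estimator is exactly
invertible under the simulator's generative model, which is what makes
closed-loop recovery meaningful.  Shared families use reciprocal best
consensus matches with an "80/80" rule (≥ 80% identity over ≥ 80% of the
shorter consensus; both thresholds are parameters) plus a copy-number
floor applied in both species.  Coverage profiles stack hit intervals
per consensus position; `scaled_depth` divides by sampled Gbp so skims
of different depth are comparable.

## Transcript classification and expression

The classifier orients hits by majority strand, orders them by
coordinate, and requires **all three** of INT, RT, RH for an LTR call:
INT before RT → Ty1_copia; INT after RH → Ty3_gypsy; INT between RT and
RH → unclassified.  GAG and PROT corroborate but never decide.  Without
the triplet, an RT hit with clade LINE or Penelope assigns those
classes.  Conflicting clade labels on one transcript emit a warning and
yield `unclassified` — never a silent guess.  Classification is
invariant to a global strand flip (tested).

TPM is computed over the full transcriptome before any subsetting, so
columns sum to 10⁶ (checked to 10⁻⁶ relative).  Tissue contrasts are
Welch two-sided t-tests on the TPM scale; class-level tests aggregate a
class's transcripts by per-sample **sum** (mean and log2 options exist).
No multiple-testing correction is applied by default; a BH option is
available in the caller's hands via the returned raw p-values.  Note
that TPM is compositional: a surge in one class necessarily depresses
the others' TPM slightly, which matters when few transcripts are
analysed.  piRNA-pathway gene expression (HENMT, AGO3, PIWI2, PIWI3) is
the per-gene sum over mapped transcripts; unmapped genes get a zero row
plus a warning.

## Small-RNA pipeline

Fixed order: trim/length-filter → contaminants → miRNA → piRNA.  A read
matching both an rRNA reference and a TE is a contaminant.  Retained
reads are 18–31 nt; piRNAs are 23–31 nt with ≥ 1 best-stratum TE hit.
Adapter trimming cuts at the leftmost exact match of the adapter's first
10 nt, falling back to a ≥ 5 nt terminal overlap — a simplified scheme;
pre-trimmed input is accepted directly.  Contaminant and miRNA mapping
use ≤ 1 mismatch (configurable).  The RPM denominator is the
**retained** read count (after length filtering, before contaminant
removal); a "clean" (post-contaminant) denominator is available, and the
chosen denominator is recorded in the result object.  The 1U statistic
is read-weighted (each read once, whatever its mapping weight), computed
on DNA-space T at position 1.

## The simulator

The generator produces the study conditions, not a tunable benchmark:

* **Library**: uniform random consensus per family at the requested
  length (GC ≈ 0.5).
* **Genome and skim**: each copy is the consensus with i.i.d. per-site
  substitutions at rate `d` (mixtures of two rates produce bimodal
  "ancient + recent burst" landscapes); a substituted site becomes a
  transition with probability `kappa/(kappa+2)` (default kappa = 2).
  The realized mismatch fraction of a copy equals `d` in expectation,
  so the K2P estimate of a realized alignment slightly *exceeds* `d`
  (the multiple-hit correction applied to single-hit data): d = 0.02 →
  K ≈ 2.0%, d = 0.08 → K ≈ 8.5%, d = 0.12 → K ≈ 13.1%.  Copies are
  interleaved with random background; reads are sampled uniformly on
  both strands, `round(coverage·G/read_len)` of them.
* **Transcriptome**: domains laid out in architecture order (reverse
  coordinate order on the minus strand), negative-binomial counts
  (variance `m + φm²`).
* **Small RNA**: class counts are exact rounded fractions; piRNAs are
  consensus substrings (sense or antisense) with the 5′ base forced to
  T with probability `u1_prob` and to a uniform non-T base otherwise —
  leaving the reference base on the failure branch would inflate the
  emitted 1U fraction by `(1−u1_prob)/4` and break exact recovery.
  Default length distribution peaks at 27–28 nt (locust-testis-like);
  miRNAs are exact 22-nt hairpin-arm copies; contaminants are substrings
  of the rRNA/tRNA-like references.

Everything is deterministic given the seed (child streams via
`SeedSequence`).  **What the simulator does not emulate**: sequencing
error and quality profiles, PCR duplicates, indels, TE nesting and
segmental duplication, compositional bias, hairpin secondary structure,
and real piRNA cluster architecture.  Recovery results therefore show
that the estimators are correct under the declared generative model —
not that real libraries are free of the biases above.

## Recovery analyses: problem sizes

The validation suite uses desk-scale problems chosen so each recovery
is statistically decisive: landscape recovery uses 300–400 copies of a
10 kb consensus at 0.1× with 500 bp fragments (~600–800 informative
alignments; the unimodal d = 0.08 center at 8.5% sits mid-bin, making
the modal-bin check robust, while the bimodal peaks are checked within
±1 bin of their K2P-corrected centers, the same tolerance the
modal-bin-recovery invariant states); copy-number recovery uses a
500-copy, 5 kb family in a 100 Mb genome at 0.1× with 150 bp reads;
the species-pair comparison uses 10 orthologues (5% between-species
consensus divergence) plus 5 private families per species at ~600–700
copies in 26 Mb genomes; the small-RNA recovery uses 33,334 reads with
10/40/30% contaminant/miRNA/piRNA composition; the balanced/impaired
contrast uses 30 families, 20% piRNA-output noise CV and 20,000 small
RNAs.

## Known limitations

* Ungapped alignment understates homology for indel-rich families and
  cannot place reads across deletion breakpoints.
* The genomic-mode score floor (`min_score = 20`) discards read-consensus
  overlaps shorter than ~20 bp, a small negative bias (< 2%) in genome
  proportion at copy boundaries.
* The skim copy-number estimator assumes the library consensus matches
  the genomic copies' length distribution; fragmented or chimeric
  consensus entries bias `N̂` accordingly.
* Landscape bins below ~1% resolution are only meaningful for long
  alignments (see Resolution above).
* The classifier trusts the domain-hit table; it performs no homology
  search of its own, and domain false negatives push transcripts to
  `unclassified` rather than to a wrong class.
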