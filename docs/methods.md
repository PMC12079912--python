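# Methods

## Model

`coversize` estimates genome size from the coverage signal of a read
mapping. The model assumes shotgun sequencing fragments DNA nearly at
random, so aligned reads are distributed approximately uniformly over
the genome. Under that assumption the depth observed at a genuinely
single-copy position is an unbiased measure of the genome-wide coverage
*C*, and the genome size is

N = L / C,

with *L* the total number of aligned bases, computed as the sum of
per-position depths over the assembly. Regions present in the genome *m*
times but assembled once receive *m*·*C* depth; their reads are fully
counted in *L*, so *N* includes the collapsed copies even though the
assembly does not. Reads from contaminating organisms never align
(unless the contaminant itself was assembled) and therefore never enter
*L*: contamination is discarded without being identified.

What breaks the assumption, and how the tool responds:

* **Organellar sequences** (plastome, chondrome) are present at
  hundreds of copies per cell and attract correspondingly extreme
  depth. They are blacklisted automatically (below) or excluded
  explicitly; the reported *N* is the nuclear genome.
* **Multi-copy or missing reference regions** would bias *C*; the
  recommended reference set is complete single-copy BUSCO genes, with
  all annotated genes as the fallback.
* **Coverage decay at contig ends** and **GC-dependent coverage bias**
  are not corrected. End decay is negligible for high-contiguity
  assemblies (N50 ≫ read length); GC correction is a known limitation.

## Averaging and robustness

*C* is the mean or median of per-position depths pooled over all
reference-region positions (each position counted once — overlapping
regions are merged first; zero-depth positions are retained). The
median is the default: it is invariant to the magnitude of a small
fraction of inflated positions (residual collapsed paralogs inside
reference genes), whereas the mean is not. The even-length median is
the midpoint of the two central values.

## Blacklisting

A sequence is blacklisted when its mean depth exceeds b × A, where A is
the assembly-wide pooled mean depth (total aligned bases over total
positions, user pre-exclusions removed first) and b defaults to 1.5.
The rule is applied in a single pass — A is not recomputed after
removals — so the result is deterministic and independent of sequence
order. Blacklisted and user-excluded sequences are removed from both
the reference regions and *L*: their aligned bases would otherwise
inflate the nuclear estimate, which is the same reason they are removed
from the region set.

For an assembly that resolves p haplotypes or subgenomes, most of the
genome legitimately carries p-fold coverage. The ploidy heuristic
counts, per BUSCO id, its Complete + Duplicated hits, histograms the
copy numbers, and reports the modal copy number as a *pseudo ploidy* p
(ties break toward the smaller copy number — the conservative choice
that keeps the blacklist stricter; fragmented hits are not copy
evidence and are ignored). The recommended blacklist factor is then
1.5 × p; alternatively blacklisting can be disabled outright for highly
repetitive polyploids. The mode-of-histogram statistic is this
package's interpretation of the "pseudo ploidy number"; it is exact on
assemblies where a majority of single-copy orthologs share the ploidy's
copy number.

## Saturation analysis

To locate the minimum sequencing effort that supports a stable
estimate, the coverage track is thinned to a ladder of fractions f
(default 100/75/50/25/10/7.5/5/2.5/1/0.5 %) and re-estimated at each
level. Thinning is per-position binomial — each depth d is replaced by
a Binomial(d, f) draw, the depth distribution that keeping each read
independently with probability f induces — a fast surrogate for
read-level subsampling plus re-mapping, equivalent in expectation for
everything the estimator consumes. Each fraction uses a derived seed
(base seed + fraction index) so individual rows are reproducible in
isolation; the fraction-1.0 row uses the untouched track and therefore
equals the full estimate bitwise. A level whose thinned coverage cannot
support an estimate (zero median in the reference regions) is flagged,
never fatal. The reported `minimum_bases` is the smallest sampled-bases
value from which the estimate stays within a relative tolerance
(default 5 %) of the full-data estimate, scanning from the deepest
level down and stopping at the first violation; it is NA when only the
full data set qualifies.

## File dialects and conventions

* Coverage TSV: `sequence  position(1-based)  depth` with complete
  consecutive enumeration per sequence; a gap is an error rather than
  an implicit zero, so truncated files fail loudly.
* SAM text (via pysam): only FLAG/RNAME/POS/CIGAR are interpreted.
  CIGAR M/=/X/D consume reference positions and count as coverage — D
  included so small deletions do not punch holes through covered genes
  (trivially switchable in `io._COVERING`); N consumes without
  covering. Secondary and supplementary records are skipped so each
  read contributes one placement; unmapped records are skipped
  (contamination exclusion).
* BUSCO full table: the canonical reference-region input, because the
  status column (Complete/Duplicated/Fragmented/Missing) drives both
  single-copy reduction and ploidy. "Single copy" means status
  Complete; Duplicated records are included only in `--all-busco` mode.
  A GFF3 path (`--gff`, `--feature gene|exon`) covers all-gene/exon
  region sets.
* All internal coordinates are 0-based half-open; 1-based inclusive
  inputs are converted at the parsing boundary. Strand is ignored.

## Synthetic scenarios

The simulator generates per-position depth directly (fast, exact
ground truth): uniform nuclear depth c — exact or Poisson(c) i.i.d. per
position — with collapsed repeat blocks at m·c, an optional organelle
sequence at a high multiplier, and single-copy BUSCO genes placed
outside the repeats. Contaminant bases are recorded in the truth but
never appear in the track, mirroring reads that never map. The true
genome size is nuclear-only: nuclear_length + Σ (m−1)·repeat_length.
An alignment-level generator emits SAM records that tile the expected
depth exactly, to exercise the SAM-to-coverage path without an external
mapper.

Deliberately not modeled: read-length autocorrelation of real depth
(adjacent positions share reads; i.i.d. Poisson understates the
variance of regional means), GC bias, mapping ambiguity, PCR
duplicates, and sequencing error. Passing tests therefore demonstrate
the estimator's arithmetic and its robustness to the modeled
distortions — collapsed repeats, organelles, contamination, Poisson
depth noise — not its behaviour under mapper-specific artifacts.

## Default scenario sizes

Validation scenarios use genomes of 10⁵–2×10⁶ bp at 10–40× depth with
BUSCO regions covering 2–5 % of the genome (e.g. 100 genes of 1 kb on
2 Mb) — the region-to-genome ratio typical of real BUSCO sets — and 20–50
replicate seeds for stochastic checks. The noisy recovery check uses a
1 Mb genome, 20×, one 10 kb repeat at 3 copies, 50 seeds; observed mean
relative error is ~0.02 % because the pooled median over 10⁵ region
positions locks onto the true depth. These sizes keep the full suite in
seconds while leaving every statistical check far from its threshold.

## Numerical choices and degenerate inputs

Depths are exact int64 throughout; *L* is an exact integer sum, so
scaling every depth by an integer k scales *L* and *C* by k and leaves
*N* bit-identical up to float division. Zero average coverage, an empty
reference-region set, and zero aligned bases are errors (CLI exit code
3), as are dialect violations (exit code 2). Estimate TSVs contain no
timestamps or paths — identical inputs and seeds give byte-identical
outputs — and every output is paired with a log carrying the tool
version, input SHA-256 digests, parameters and timestamp.
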