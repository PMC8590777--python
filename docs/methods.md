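# Methods

## Data model and conventions

All internal coordinates are 0-based half-open; every user-facing
report (CLI output, methylKit export, region strings) is 1-based
inclusive. A read's sequence is stored in aligned (reference-forward)
orientation, as in SAM. Modification scores are kept in a sparse map
keyed by *stored-sequence* offsets: on a forward read a scored offset
addresses a `C`; on a reverse read the template cytosine appears as a
stored `G`. This matches the coordinate convention pysam uses when
decoding MM/ML tags, and the SAM writer/parser round-trip is
cross-checked against pysam's own decoder in the test suite. Strand
logic lives in exactly one place (projection); upstream of it, scores
are carried verbatim as the basecaller emitted them.

The TSV dialect (one row per read: id, placement, strand, CIGAR,
sequence, scored offsets, scores, four optional kinetics columns)
exists so that the full pipeline is exercisable and diffable without
any binary alignment file.

## Score scale and thresholds

Scores are integers in [0, 255] encoding 5-mC likelihood as s/255. A
base is *modified* iff s > 128 — strictly greater, so 128 is the
largest unmodified score. The rate-mode methylation call is
methylated iff percent ≥ 0.20; the boundary is deliberately inclusive
(20% is read as the smallest accepted value) so the caller is
deterministic at the cutoff. Both constants are configurable
parameters with these defaults.

## Projection rules

Projection walks the CIGAR and emits one observation per scored read
cytosine landing on a match column whose reference context is CpG on
the read's strand. Insertions contribute nothing (their columns have
no reference position); scored cytosines over deletions or clips are
dropped. CpG context is defined on the **reference**, not the read:
positions must be comparable across reads, so a mismatched read base
over a reference CpG still counts when it carries a score. A scored
cytosine whose reference context is not CpG is discarded (CHG/CHH
contexts are out of scope). Unscored read bases over reference CpGs
are *not* counted by default — the observation count per read never
exceeds its scored-cytosine count — but an `include_unscored` switch
emits them as score-0 (canonical) observations for basecallers that
only tag confident 5-mC calls. Projection against an
expansion-allele consensus uses identical logic with consensus
coordinates; reads placed on homologous decoy contigs are excluded and
counted.

Reverse-strand observations anchor to the forward-strand C
(`cpg_anchor = pos − 1`), enabling optional strand-combined pileups;
strand-split is the pileup default, and the trio workflow combines
strands explicitly.

## Methylation calling

The Fisher caller tests the observed (n_mod, n_canon) against a
pseudo-count null population of 1,000 sites at a 5% modified fraction,
one-sided (alternative: the site's modified fraction exceeds the null
error rate), methylated iff p < 0.01. A literal "no chance of being
methylated" null (0%) would make any exact test degenerate — every
observed modified base would be infinitely surprising — so the null
error floor encodes the basecaller's false-positive rate instead; both
parameters are exposed. The implementation uses
`scipy.stats.fisher_exact`; tests compare it to an independent
rational-arithmetic hypergeometric enumeration for every table with
coverage ≤ 30 at 1e-9.

The methylKit export writes the per-base dialect (chrBase, chr, base,
strand F/R, coverage, freqC, freqT) with freqC = percent *methylated*,
i.e. the bisulfite-protected-C analogue, so the file drops directly
into methylKit-style downstream tooling. Default per-site reporting
coverage floor is 10, aligned with common methylKit practice (the
trio workflow uses 20 for boundary calls).

## In-silico bisulfite conversion

Scored cytosines with s ≤ 128 are rewritten to T (forward reads) or A
(reverse reads, written in stored reference orientation — how
bisulfite reverse-strand reads appear in browsers); s > 128 leaves the
base intact. Unscored CpG-context cytosines default to converted
(score 0): absence of a modification call is taken as evidence of
canonical C, and the behaviour is switchable. Non-CpG cytosines
without scores are never touched, keeping non-CpG sequence identity
for the viewer. Conversion is idempotent: surviving (methylated)
cytosines keep their scores, converted positions are no longer
read-sense cytosines. The emitted SAM preserves placement and CIGAR;
`XO`/`XC` tags keep the original sequence and substitution count, so
conversion is lossless.

## Repeat genotyping and composition

The copy-number caller requires the read to span the locus widened by
a 100 bp flank margin on both sides (both flanks anchored); the
relative change is the net inserted-minus-deleted base count within
that window divided by the unit length, rounded half away from zero
(symmetric for expansions and contractions), and absolute copies add
the reference count, floored at zero. Soft-clipped bases never count;
non-spanning reads are reported, not silently dropped — contractions
and expansions must be measured on spanning evidence only. Phasing
splits per-read calls at a relative change of 50 (< 50 non-expanded,
≥ 50 expanded). Allele summaries use the midpoint median, sample SD
(n−1), and linear-interpolation quartiles; a singleton group reports
SD 0 with a defined-ness flag.

Composition decomposition is a greedy left-to-right longest-match
scan with priority named insertions > repeat unit > interruption
motifs > single-base fallback, merging adjacent identical motifs.
Greedy beats optimal segmentation here because it is deterministic,
linear, and matches how waterfall plots are drawn; the reconstruction
identity (concatenating runs reproduces the input exactly) is
property-tested on random strings. The waterfall table sorts tracts
by length descending with read-id tie-breaks and emits
(class, offset, length) segments for horizontal bar rendering.

## Kinetics

Per-position replication cycle time is the mean over reads of
IPD + PW, in frames, separately per strand (fi/fp = forward template,
st 0; ri/rp = reverse, st 1). Kinetics arrays are taken as
allele-coordinate-aligned inputs: every contributing read must supply
arrays of exactly the allele length, and the synthetic kinetics cohort
is therefore generated at the allele's consensus copy number
(consensus-aligned HiFi kinetics are effectively error-free, so this
matches the data such arrays come from). Positions without coverage
are NaN in the per-position track and imputed as 0 in the cumulative
curve (which must stay continuous); the imputation is logged. Rates
in bases/second divide window length by total cycle time over the
window converted via the frame rate. **No default frame rate is
asserted** — the kinetics literature reports bases/second but the
frame rate is instrument-specific — so it is a required parameter;
the synthetic generator owns a 100 frames/s convention for its own
data.

## Multi-sample comparison

The percent matrix takes the union of sites over samples, with cells
below the coverage floor missing; analyses are complete-case (no
imputation). PCA is centered but not variance-scaled — percent
scales are already commensurate across sites — with a deterministic
sign convention (largest-magnitude loading positive). Ward clustering
runs on Euclidean distances over samples ordered by id, so ties
resolve deterministically. Differential bases use the two-sided
Fisher's exact test per shared site and Benjamini–Hochberg q-values
with q < 0.01 significant. BH was chosen over sliding-linear-model
q-values as a transparent, exactly testable control with the same
cutoff semantics. Feature annotation assigns half-open BED intervals
(multiple covering classes are reported jointly, absence is class
"none"); the nearest-TSS distance is signed negative upstream on the
gene strand, with equidistant ties broken by lexicographic gene name.

## Synthetic trio generator

The generator emulates the study conditions end to end: a 4,039 bp
locus (2,000 bp random flanks around 13 GGC copies) with an
unmethylated core spanning 700 bp upstream of the repeat through
1,000 bp downstream (≈2.2 kb), the 4 CpGs immediately upstream and 8
immediately downstream of the core designated transitional-zone CpGs
with per-read methylation probability 0.5, and fully methylated flanks
beyond them. Haplotypes: mother 2 × (median 13, SD 1); father
(13, SD 1) plus a hypermethylated-en-bloc expansion (median 520,
SD 170) with 10% of expanded reads escaping methylation (epigenetic
mosaicism, reverting to the normal profile); patient (13, SD 1) plus a
contracted, unmethylated expansion (median 140, SD 15). Expanded
haplotypes carry 2 GGA interruption units at the 3′ end of the pure
GGC stretch, constant across reads of a haplotype; a named-insertion
option and a bimodal copy-number mixture (for two-cell-population
somatic mosaicism) are available. Copy numbers are truncated-normal
draws per read.

Score emission: methylated CpGs draw > 128 with probability 0.95,
unmethylated ≤ 128 with probability 0.95 (uniform within each half).
Sequencing noise (substitution 0.01, single-base indel 0.002 per
column) is injected *after* composition and scoring so truth is
defined pre-error; scored columns are exempted from substitution and
deletion so the score map always addresses cytosines. Reads span the
whole locus (the enrichment protocol excises the full fragment), half
on each strand. Three cohorts per haplotype: 100 noisy score-carrying
reads, 15 error-free reads for composition/waterfall, and 20
error-free consensus-length reads carrying Poisson-sampled kinetics
(baseline 35 + 15 frames/base; ×2.2 over the repeat tract of
hypermethylated haplotypes — with the 100 frames/s convention this
yields ≈2.0 vs ≈0.9 bases/s). One seeded generator drives everything;
identical seeds give byte-identical fixture files.

What the generator does **not** emulate: signal-level errors,
homopolymer- or context-specific error profiles, mapping ambiguity
from segmental duplications, within-read methylation autocorrelation
beyond the block structure, or partially spanning reads. Passing
recovery tests therefore demonstrates correctness of the measurement
logic under the stated statistical structure, not robustness to every
real-data failure mode.

## Problem sizes and numerical choices

The default trio is 600 score-carrying reads (~264 strand-combined
CpG sites at coverage ≥ 20), 90 composition reads and 120 kinetics
reads — sizes at which phasing accuracy, medians (±2 copies), block
boundaries (±1 CpG) and the father-vs-rest PCA/Ward split are stably
recovered in seconds on one CPU. Oracle sweeps use 1,000 random toy
alignments (≤ 50 bp references, all CIGAR op mixes) and all 495
Fisher tables with coverage ≤ 30. Copy-number rounding is half away
from zero; percent values are reported to 4 decimals but compared
unrounded at the cutoff; boundary recovery takes the longest
contiguous unmethylated run, which is robust to isolated miscalls at
mosaic sites.

## Known limitations

* The copy-number caller reproduces the contract of
  tandem-genotypes-like callers, not any tool's exact internals; reads
  must span both flanks.
* The Fisher null-population construction is this package's explicit
  parameterization (null_error, null_n); published tools leave the
  contingency construction unspecified.
* Kinetics analysis is descriptive (tracks, curves, rates); it does
  not infer base modification from IPD ratios.
* No basecalling, alignment, consensus generation or FAST5/POD5
  parsing; alignments with modification tags are the entry point.
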