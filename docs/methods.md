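# Methods

## Chimerism model

A complemented embryo is modeled as a two-component cell mixture: a fraction
*f* of cells from a donor line heterozygous at two informative SNPs (each
donor chromosome carries the informative base with probability 1/2) and a
fraction 1 − *f* of host cells homozygous for the reference base. Amplicon
reads are draws from this mixture; at each SNP the expected informative-read
fraction is *f*/2, so the donor percentage is estimated by the doubling rule
`donor% = 2 · mean(p₁, p₂) · 100`, clamped to [0, 100] with an explicit
over-/under-range flag rather than silent truncation.

The mean over SNPs is unweighted: the readout is defined as the average of
the two per-SNP percentages, not a pooled read count, so a depth imbalance
between SNP positions does not tilt the estimate. A read-weighted pooled
alternative would be trivial to add but is deliberately not the default.

### Error-floor correction

With a uniform per-base substitution rate *e*, any specific wrong base
appears at frequency *e*/3. The observed informative fraction is therefore

    E[p] = f·(1 − e) + (1 − f)·(e/3),

which biases the doubled estimate and, near *f* = 0, places the whole
confidence interval above the truth. The two bases at each SNP that are
neither the host nor the donor allele arise only from error, so their mean
frequency `b` estimates *e*/3 from the sample itself, and

    f̂ = (p − b) / (1 − 4b)

is unbiased under the substitution model (substituting the expectations
above reproduces *f* exactly). This background correction is the default
(`error_correction="background"`); `"none"` gives the raw read fraction.

### Uncertainty

The confidence interval is a Wilson score interval on the pooled informative
reads across SNPs. Under the default simulation model the per-SNP draws are
independent, so pooling is valid. The interval bounds are passed through the
same background correction, widened by the normal-approximation standard
error of `b` (the background is itself estimated), then doubled and clamped.
If donor cells were simulated with phased SNPs (both informative alleles on
the same chromosome), the two SNP counts would be almost perfectly
correlated and the pooled interval would be ~√2 too narrow; the default
generator is unphased, and the phased variant is listed as a limitation
below.

## Host genotype from the edited locus

Donor cells are unedited, so every non-wild-type indel signature at the
edited locus is host-derived: `host% = 100 · (1 − WT fraction)`. The call
logic, with defaults:

| rule | call |
|---|---|
| host compartment `100 − donor%` ≤ 2 points | indeterminate (no host to genotype) |
| host% ≤ 2 points | WT host |
| non-WT reads < 200 | indeterminate (insufficient evidence) |
| ≥ 2 signatures, or 1 covering ≥ 80% of the compartment, and `|donor% + host% − 100|` ≤ 10 points | bi-allelic KO |
| host% within ±5 points of half the compartment | mono-allelic / mosaic |
| otherwise | indeterminate, with a consistency warning when the accounting gap exceeds 10 points |

The single-signature branch exists because two cuts can resolve to one
deletion allele on both chromosomes; such calls carry an explicit note. The
thresholds (percentage points throughout) are conservative screening values,
not fitted quantities.

## Read processing

Reads are assigned to samples by their two 12-bp terminal tags: a read is
kept iff exactly one sample places both tags within `max_mismatch`
(default 1) in either orientation; ties go to the unassigned bin. Default
barcodes are generated with pairwise Hamming distance ≥ 3, which makes
1-mismatch assignment unambiguous. Only the tags are trimmed: the 20-bp
primer-homology arms are template sequence (the amplicon termini) and are
kept so global alignment stays anchored end to end.

Alignment is global with affine gaps (match +2, mismatch −3, gap open −5,
gap extend −1 — typical CRISPR-amplicon scoring) via Bio.Align's
PairwiseAligner against both amplicon references in both orientations; reads
scoring below half the perfect-match score are excluded as unalignable and
reported in the spectrum's filtered count. A read's allele signature is its
left-aligned (VCF-style) indel operations; mismatches are ignored for allele
identity because substitution errors dominate them. Signatures below
`min_allele_fraction` (default 1%, below the integer-percent reporting
granularity of the assay) are folded into the nearest major allele by edit
distance, or into a noise bin when nothing is within 10 edits.

Because per-read dynamic programming dominates runtime at depths of tens of
thousands of reads, `call_sample` batches reads by length and matches them
by Hamming distance (≤ 12 by default, far above the ~1–2 errors expected per
read at the modeled error rates) against the set of already-discovered
allele sequences, initially the two references. Any unmatched read falls
back to the full DP aligner, and each novel indel signature it yields is
registered so subsequent reads match vectorized. The test suite pins this
fast path to the per-read DP route: exactly on error-free runs, and on
erroneous runs up to the provably ambiguous reads — a substitution at an
indel junction can create an equally- or better-scoring alternative
alignment, in which case either representation is a legitimate optimum and
the classification difference is bounded by the number of such reads.

## Synthetic data

The generator emulates the assay's data-generating process: per read, origin
is Bernoulli(*f*); donor SNP reads carry each informative allele
independently with probability 1/2; host edit reads draw one of the
configured KO indel alleles (default: a 2-bp deletion and a 1-bp insertion
at the nominal cut site, 50:50); 12-bp tags are attached to both ends; and
substitution errors hit every base, tags included, at a uniform rate.
Defaults: depth 50,000 reads per amplicon (a round figure that gives
sub-point binomial noise on the doubled estimate), error rate 0.5% (typical
short-read amplicon quality), amplicon lengths 257/187 bp with
polymorphic positions ≥ 30 bp from the ends, constant Phred-40 qualities.
Identical truth + seed reproduces byte-identical FASTQ; seeds are
per-sample so any sample regenerates independently.

Not emulated: PCR bias and chimeras, instrument-specific error spectra,
quality-score degradation along the read, sequencing indel errors (off by
default so that indel signatures are unambiguous truth; an indel error rate
can be enabled to stress the classifier), and phased donor SNPs. Passing
recovery tests therefore demonstrates estimator correctness under the
mixture-plus-substitution-noise model, not robustness to amplification
artifacts in real libraries.

Read layout is single-end full-amplicon (both amplicons are well inside one
short read); the config accepts only this layout and rejects paired-end
explicitly rather than half-supporting it.

## Edit models

Cas9 cuts are modeled blunt, 3 bp 5′ of the PAM (standard SpCas9,
configurable per guide); a guide with zero or multiple placements is a hard
error, never a heuristic choice. The dual-guide deletion fuses the two cut
ends directly, as a stitch repair template dictates, with no micro-homology
trimming. HDR insertion splices the template payload at a stated point; the
stop cassette `TAAGCTT` contains the HindIII site `AAGCTT` as its own
substring, so the knock-in is HindIII-diagnosable wherever it lands (one
site, provided the flanks don't already contain or complete another).

Premature-stop detection lifts the annotated coding intervals through the
allele's edit operations (deletion interiors collapse; insertions at an
interval's start are excluded, interior ones included), concatenates and
translates them, and reports the first in-frame stop strictly before the
lifted position of the annotation's own first stop. Translation is not
extended past the annotated region, so a frameshift whose first new stop
lies beyond the natural stop correctly returns "absent".

The digest engine matches an IUPAC recognition pattern on both strands
(overlapping matches included; an N in the sequence matches only a pattern
N), converts each double-strand site to one top-strand cut (reverse-strand
matches mirror the cut index; a reverse match coinciding with a forward
match is the same palindromic site and counts once), deduplicates cut
positions and applies them simultaneously — partial digestion is out of
scope. Fragment lengths always sum to the input length. HindIII ships
bundled; other enzymes (e.g. BslI for the mouse locus) are user-supplied
config, keeping the engine enzyme-agnostic. RFLP genotyping compares band
patterns as sets within a ±tolerance (default 5 bp, gel resolution), calling
WT / bi-allelic edited / heterozygous (union pattern) / inconclusive, and
refuses designs whose WT and edited patterns coincide.

## Experiment summaries

Stage records (blastocysts transferred ≥ embryos recovered ≥ GFP⁺) are
summarized as percentages of transferred and of recovered, computed at full
precision and rounded half-up to one decimal only for display (trailing
".0" trimmed, matching how such tables are printed); the totals row is
computed from summed counts and is invariant under row order. "Survival
beyond stage X" counts GFP⁺ embryos recovered at X or later — the only
reading consistent with the published totals. Division-by-zero cells are
flagged, not fabricated.

## Problem sizes

The bundled recovery experiment (acceptance script) runs 200 replicates per
donor fraction in {0, 0.23, 0.87, 1.0} at depth 50,000 and 0.5% error; the
test suite runs a 50-replicate, depth-25,000 version of the same check,
sized so binomial noise keeps the mean-absolute-error bound meaningful (the
doubled-estimate standard error at pooled depth 50,000 is ≈ 0.6 points).

## Known limitations

* The error correction assumes substitution errors uniform across bases and
  positions; motif-dependent error spectra would leak into the background
  estimate.
* Chimerism is measured on whole-lysate DNA: no tissue-level deconvolution,
  no copy-number or aneuploidy handling, no maternal-contamination
  correction.
* The aligner is exact DP (via the fast path's guarantees) only up to
  junction-ambiguous reads, as described above.
* No off-target search, editing-efficiency prediction, or genome-scale
  scanning; the two configured amplicons are the whole universe.
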