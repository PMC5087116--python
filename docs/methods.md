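# Methods

## The analysis model

A cohort of m independent EMS-derived mutants of one gene is sequenced
(after flow sorting of the carrier chromosome) and each line's reads are
mapped to a repeat-masked wild-type assembly summarised as samtools
mpileup text. Under the standard EMS model — almost exclusively G/C→A/T
transitions, approximately uniform over the genome, at a density of one
mutation per several hundred kilobases — an induced lesion in every line
on the same contig is overwhelming evidence that the contig contains the
target gene. The pipeline is therefore: per-line near-fixed SNV calling,
position-level cross-line filtering, per-contig counting of mutated lines,
QC against two realistic failure modes, and an analytic false-positive
probability for the winning contig.

### SNV calling

A call is emitted at a position iff (i) the assembly base there is
uppercase A/C/G/T — lowercase (repeat-masked) and N positions are skipped
entirely; (ii) column depth ≥ `min_coverage` (default 15 reads); (iii) the
single most frequent non-reference base has frequency ≥
`min_allele_frequency` (default 0.9999) where the denominator is the
number of A/C/G/T-supporting reads in the column. Deleted bases ("*") and
reference skips/ambiguity codes are excluded from the denominator: the
filter targets substitutions, and such symbols reflect alignment
artifacts. Ties between alternates yield no call (neither can reach the
threshold). At the default threshold and depths below 10,000 the frequency
test is equivalent to requiring zero dissenting substitution reads, which
is the correct expectation for a homozygous mutant with error-free
near-fixed columns; the threshold is configurable because real data with
sequencing error and residual heterogeneity may need looser settings.

`callable_bases` — the denominator of every density statistic — counts
unmasked positions with passing depth, not total assembly length, making
densities robust to uneven coverage. Base and mapping qualities are parsed
and ignored: the upstream pileups are expected to be produced with BAQ
disabled, and all filters operate on counts.

### Cross-line integration

Any position carrying a call in more than `max_mutants_sharing_position`
(default 2) distinct lines is discarded from all of them before any
per-line statistic is computed. Independent EMS hits essentially never
coincide at a position, so shared positions indicate pre-existing cultivar
variation or systematic mapping error. The discard threshold is distinct
from the reporting threshold `min_mutants_per_contig` (default 3): the
former operates on positions (artifact removal), the latter on contigs
(evidence strength). Both are exposed because the natural-language
description of this filter in the field is ambiguous between the two
readings.

Contigs are ranked by number of mutated lines (descending), then total
surviving SNVs (descending), then contig id (ascending) — fully
deterministic. Every assembly contig receives a report; contigs with no
calls populate bin k=0 of the count histogram, whose bins always sum to
the contig total.

### QC

*Contaminant lines.* A line not descended from the mutagenised parent
shows natural variation at orders of magnitude higher density (observed
contrast: ~1/1,580 bp against 1/380,000–1/741,000 bp) and a mixed
substitution spectrum. A line is flagged when its bases-per-SNV falls
below the cohort median divided by `ratio_threshold` (default 20). The
default sits far from both sides of the observed ~240× contrast; the
cohort median makes the decision scale-invariant. Fewer than three lines
is no cohort: QC is skipped with a warning. Flagged lines are excluded and
integration reruns without them. Densities feeding this decision are
computed *after* the shared-position filter — positions shared across many
lines (pre-existing variation, artifact divergence) would otherwise
inflate every line's density and could mask the contrast at small scales.

*Assembly artifacts.* A chimeric or mis-assembled contig disagrees with
the wild type's own reads. Running the caller on the wild-type
self-mapping pileup and counting near-fixed disagreements per unmasked kb
flags contigs above `disagreement_per_kb_threshold` (default 0.5/kb). At
99.99 % required frequency, sequencing error alone essentially never
produces a fixed disagreement, so even 5 positions on a 10-kb contig far
exceeds background; 1 % divergence produces ~10/kb. Flagged contigs are
reported but barred from candidacy. Both QC thresholds are engineering
choices (the field practice is manual inspection) and are exposed in
configuration.

### False-positive probability

For one line with canonical mutation density d per callable bp over
callable sequence with G/C fraction g, the per-G/C-site mutation
probability is μ = d/g. A contig containing n unmasked G/C bases then
carries ≥1 chance mutation with probability p = 1 − (1 − μ)^n, computed
via expm1/log1p to avoid cancellation; the complement form is exact under
per-site independence and agrees with the linear approximation μ·n within
1 % whenever μ·n ≤ 0.01. Across m independent lines the joint probability
is the product of per-line probabilities. μ is estimated from all
canonical SNVs genome-wide, including the causal contig's (one SNV among
hundreds; the bias is negligible). The "1 in X" rendering rounds 1/p to
one significant figure (half-up) and switches to mantissa × 10^exponent
notation at X ≥ 10,000.

## The simulator

The generative model mirrors the study conditions: 600 contigs with
log-normal lengths (median 7 kb, σ 0.6, truncated below 500 bp by
resampling — the assembly reporting floor), i.i.d. bases at GC 0.44, 10 %
of positions lowercased in contiguous ~100–500 bp blocks, one randomly
placed 10-kb causal contig; six mutant lines at a background density of
1/500,000 per callable bp (middle of the observed 1/380k–1/741k range);
Poisson(30) read depth (observed runs: 27–35×) and error-free reads by
default, with a uniform per-base miscall model available. Defaults are
fixed study conditions, not tuning knobs.

EMS mutagenesis is per-site Bernoulli at unmasked G/C sites with
probability density/g, G→A and C→T only, making realized counts binomial
with mean density × unmasked bases and the probability module's analytic
forms exact by construction. The causal contig additionally receives
exactly one canonical lesion per line at distinct sites (sampled without
replacement). The contaminant line substitutes every unmasked site with
probability 1/1,580, alternate uniform over the three non-reference bases
(expected canonical fraction g/3 ≈ 0.15). The artifact scenario diverges
the second half of one ≥2-kb contig by 1 % in the *true* sample sequence —
wild type and all mutants — so the wild-type self-mapping disagrees with
the assembly there.

Pileup columns are synthesized directly from the line's genome (depth
Poisson, reads reporting the line base or, with the error rate, a uniform
other base); no read simulation or alignment is performed, since the
pipeline consumes mpileup and mapping is out of scope. Determinism: the
master seed drives reference construction and causal/artifact placement;
line i's mutagenesis stream is seeded seed+i and its pileup stream
seed+10000+i, so identical configurations give byte-identical output
files.

What the simulator does **not** emulate — and what passing tests therefore
do not establish about real data: read-level effects (mapping bias,
paired-end anomalies, PCR/MDA amplification bias), chromosome-sorting
impurity, context-dependent EMS rates beyond the global G/C fraction,
indels, heterozygosity, and reference errors other than the one chimera
scenario. Results on real data depend on the upstream mapping and the
filter thresholds chosen for its quality.

## Numerical and design choices

* Positions are 1-based and closed throughout, matching mpileup.
* The mpileup writer emits one canonical dialect (".", uppercase
  alternates, "*", ">", constant quality "I"); the reader accepts the full
  read-base grammar including `^q`, `$`, `±n<seq>` indel suffixes, case
  folding, and "<"/">" skips, and verifies decoded counts against the
  stated depth.
* Degenerate inputs: zero-SNV lines report density as absent (never
  infinite) and are never contaminant-flagged; empty probability lists and
  non-positive denominators raise domain errors; histogram bins cover
  k = 0..m even when empty.
* Problem sizes in the validation suite are chosen for single-CPU runs:
  density recovery uses one 40-Mb mutant (≈105 expected background
  mutations, so one binomial SE is ~10 % of the recovered density — the
  acceptance band is 3 SE); contaminant recovery uses 2 Mb (≈1,266
  expected variants, SE ~3 %); the 100-replicate causal-recovery check
  runs mutagenesis truth through the shared-position filter, integration
  and ranking directly, with caller-vs-truth exactness established
  separately on synthesized columns — the composition covers the full
  path without synthesizing 3 × 10⁹ read columns.
* The joint-probability worked example (twelve lines at 0.11) is exact
  arithmetic: 0.11¹² = 3.14 × 10⁻¹², rendered "1 in 3 × 10^11".

## Known limitations

Indels and heterozygous variants are out of scope. The contaminant
criterion assumes a majority of genuine EMS lines in the cohort (a median
of contaminants would invert it). The artifact check requires a wild-type
self-mapping pileup; without it, chimeric contigs can only be caught by
the shared-position filter when their divergence is shared across lines.
The probability model assumes a single genome-wide G/C fraction; strongly
atypical contigs are better served by their own G/C counts, which the API
accepts.
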