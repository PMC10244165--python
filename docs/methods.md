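# Methods

This note documents the models behind `ubtftd`: what each component
assumes, the parameters that matter, what the synthetic data do and do not
emulate, and the numerical choices made where the design was open.

## The locus model

All coordinates are 0-based half-open genomically and 1-based (HGVS c.)
in coding space; conversions happen only through `GeneModel`. The packaged
fixture is a synthetic, seeded, forward-strand stand-in for the UBTF
exon 12–14 region: three exons of 120/189/120 bp with introns of 152 and
140 bp, 400-bp flanks, and a screening amplicon of exactly 617 bp between
primer positions in exons 12 and 14. The sequence is random under a fixed
seed except for anchored codons: the 21-nt core at c.1306–c.1326 encoding
ELLTRLA (Glu436…Ala442), the deletion-prone Trp445/Asn446/Asp447 codons,
and a downstream 42-nt segment encoding GLCLRFNQLDLDQA (the one observed
duplication class that does not contain the core). Reverse-strand gene
models are normalized to forward at load time; a FASTA + exon-TSV loader
accepts real loci.

Interpreting "the minimal duplicated region" as c.1306–c.1326 gives 21 nt
(7 codons), which is what the annotation reports; the module never
hard-codes a region length, it computes the interval intersection.

## Synthetic cohorts

`CohortSpec` defaults encode the study conditions: discrete size mass at
48/51/54 bp with weights 18/59, 10/59, 6/59 and a log-uniform tail over
[39, 950]; internal deletions with probability 0.64 for TDs > 100 bp and
0.13 below, drawn as 3/6/9-nt codon-multiples targeting codons 445–447;
non-templated junction inserts of 0–6 random nt for exonic TDs; allele
fractions logit-normal with median 0.45 and σ(logit) = 0.335 (matches the
reported IQR 0.37–0.48); co-mutation indicators drawn independently at the
reported per-gene rates (WT1 0.63, FLT3-ITD 0.53, trisomy 8 0.28, …) —
co-mutation *correlation* structure is not modeled. One patient class in
~59 is the non-core 42-bp duplication.

TDs up to 120 bp are placed wholly inside exon 13 and constrained to
total length ≡ 0 (mod 3); larger TDs span the flanking introns, carry no
junction insert, and have their breakpoints shifted (by at most ±250 bp,
preferring the smallest shift) so that the *spliced* inserted length is a
multiple of 3 and no splice dinucleotide is split — mirroring the
observation that large duplications need not be length-3 multiples
genomically yet are in-frame after splicing.

## Read simulation

Reads are emitted pre-aligned (SAM written via pysam): alignment of
simulated reads is not the method under test, and the known junction
geometry determines the CIGAR a correct aligner would produce. Paired
150-bp reads are drawn from fragments (N(350, 50²) length) placed uniformly
per haplotype; a haplotype's share of fragments is its DNA fraction times
its TD-lengthened locus length, so per-base molecule density is equal
across alleles — without this, junction-read VAFs would be biased low for
long duplications. A read crossing the duplication junction is represented
as `M I M` when the whole inserted segment plus ≥10-bp anchors fits inside
it, otherwise the longer flank aligns and the remainder is soft-clipped
(ties go to the left flank); reads wholly inside the copy align as pure
matches to the original interval, with `D` operations at internal
deletions. Substitution errors are uniform at 0.1%; indel errors and base-
quality structure are not modeled, so tests passing here say nothing about
indel-noise robustness on real data. Default depth 500× and read length
150 bp are configurable; the targeted panel's true parameters are unknown.

Consequences of this geometry that the caller must live with: for a TD
shorter than the read length, the junction yields right-clips at the 3'
breakpoint plus CIGAR insertions (left-clips never reach the 10-bp clip
threshold); for a TD longer than the read length, evidence is exactly one
left-clip cluster at the duplication start and one right-clip cluster at
the 3' breakpoint, plus coverage excess.

## TD calling

Soft-clips ≥ 10 bp are clustered by (side, breakpoint ± 3 bp); consensus is
per-column majority, ties to the lexicographically smallest base, columns
with fewer than two supporting reads trimmed when the cluster has ≥ 3
reads. A right-clip consensus (= junction insert + start of the copy) is
re-aligned into a window upstream of the breakpoint; candidate insert
lengths k = 0…8 are tried exact-first, then by seeded semi-global dynamic
programming. The DP is Gotoh affine (match +1, mismatch −1, gap open −4,
extend −1) with free reference end gaps and leftmost placement on ties; a
linear −2 gap cost was tried first and rejected because a genuine 6-bp
internal deletion then scores below a spurious two-insertion/two-mismatch
alignment. Alignments are accepted at ≥ 85% matched bases; the best score
wins, smallest k on ties, so junction inserts are not absorbed as
mismatches. CIGAR-insertion strings are resolved identically with the
alignment anchored to end at the breakpoint. Candidates agreeing within
the cluster tolerance merge (insertion evidence, which sees the whole
copy, outranks right clips, which outrank left clips); one-sided
reconstructions are flagged "partial evidence", and consensus that
re-aligns nowhere in the ±1500-bp search window is reported as
"no-duplication" rather than guessed. Because the duplicated copy is
sequence-identical to the original, deletion placement inside a repeat can
be ambiguous; the caller reports the leftmost equivalent placement, and
equivalence is checked at the haplotype-sequence level.

The mismatch suspicion scan (same-base pileup above max(3 reads, 2% of
depth), or any clustered indel/clip) is a cheap pre-filter: no call is
emitted from a sample that does not trip it.

### VAF estimation

`vaf_breakpoint = support / (support + spanning_ref_reads)`, where support
counts junction evidence (clips at either breakpoint + insertion reads)
and `spanning_ref_reads` is the *contamination-corrected* count of clean
reads crossing the 3' breakpoint with ≥ 10 bp on both sides: reads wholly
contained in the duplicated copy cross that breakpoint as pure matches
(the copy's end abuts the downstream sequence in the reference), so the
observed spanning count is reduced by the expected number of such reads,
`support × w_c / (R − 2a + 1)` with `w_c = max(0, min(m, R − a) − a + 1)`
(read length R, anchor a = 10, duplication length m). Without the
correction the estimator converges to f/(1 + f)-type values (≈ 0.40 at
f = 0.45 for a 48-bp TD) — a structural bias, not noise. Reads with any
soft-clip are excluded from spanning for the same reason. With the
correction the estimator is unbiased (mean absolute error ≤ 0.03 over
f ∈ [0.1, 0.9] at 2000×).

`vaf_coverage = depth(duplicated interval)/depth(flanks) − 1`, flanks of
equal width adjacent to the interval but at least 400 bp (≈ one fragment
length) from the locus ends, where simulated coverage ramps down. This
estimator is only informative for duplications on the order of the read
length or longer: shorter insertions live in CIGAR `I` operations and add
no reference depth. The reported VAF is therefore the junction estimate
whenever support ≥ 3 reads, with coverage as the fallback for sparse
junction evidence; both are always reported side by side. Calls below 1%
VAF — the screen's stated sensitivity floor — are suppressed.

## Fragment screen

Traces are modeled as Gaussian peaks (σ = 0.25 bp on a 0.25-bp grid —
single-base resolution, which the screen requires to size TDs exactly)
with heights proportional to allele fractions, uniform baseline noise, and
optional ±1-bp stutter satellites. Peak calling takes local maxima above
max(5% of the trace maximum, 10 units) with mild prominence filtering; the
peak nearest the expected wild-type size (±2 bp) is wild-type, satellites
within 1.5 bp of a ≥ 6.7-fold taller peak are stutter, and remaining
larger peaks are mutant with TD size = round(peak − wild-type). A missing
wild-type peak is a flag (possible homozygous/hemizygous mutant or failed
reaction), not an exception; mutant peaks above 1200 bp are flagged as
beyond the size-standard range. Ladder calibration and raw trace-file
parsing are out of scope — sizes are assumed calibrated.

## Splice-aware annotation

The mutant haplotype is projected through the exon model: duplicated
exonic bases are retained, duplicated intronic bases spliced out, and the
junction insert is retained only when both its neighbours (the base before
the 3' breakpoint and the copy's first base) are exonic. The spliced
inserted length decides frame; the inserted peptide is translated from the
codon-aligned window around the insertion. A duplication spanning both
introns around exon 13 yields a transcript carrying exon 13 twice — the
exon13–exon13 fused product — and is in-frame whenever its exonic content
is a multiple of 3. Breakpoints or deletions splitting a GT/AG
dinucleotide are annotated "splice-disrupting" with frame undefined.
Cohort-level structure uses CDS coordinates under the caller's leftmost
placement convention, so the minimal-region intersection is well defined
across patients.

## Clonal inference

CCF = VAF × CN/m with purity fixed at 1 (blast-enriched assumption; no
purity estimate is attempted — a documented limitation). Variants are
inserted in decreasing CCF (founding ties favour UBTF-TD-class variants,
then diagnosis CCF, then variant id) and nest into the smallest clone
dominating them at every timepoint, strict dominance preferred over
tolerance-assisted dominance; two variants whose CCFs sum above their
container's CCF + 0.1 at any timepoint are forced onto one lineage.
Whether a variant *joins* an existing clone is a depth-aware decision: the
per-timepoint CCF differences are pooled into a chi-square statistic using
binomial standard errors (2 df, threshold 11.0, absolute cap 0.25), so
deep data separates clones that shallow data cannot. Inconsistent
configurations are returned with explicit violation messages
("unresolvable"), never silently forced. Presence/absence calls
(gained/lost/persistent, WT1 class, relapse patterns) use the 1% VAF
floor. The planted-architecture generator used in recovery tests draws
jittered chain/branch templates and rejects draws that are not uniquely
recoverable from noise-free CCFs (crossing sibling trajectories, ≥ 0.14
separation margins) — recovery failures thus measure the builder, not the
degeneracy of two-sample bulk data, which genuinely cannot distinguish a
small subclone's possible parents when every candidate dominates it.

## Contingency statistics

The two-sided Fisher exact test uses the probability-mass rule (sum of all
margin-consistent tables no more probable than the observed one), which is
the convention that reproduces the printed remission-rate p-values; exact
integer binomial coefficients are used for totals ≤ 200 and log-gamma
beyond. Benjamini–Hochberg q-values are the step-down minimum, capped at
1. The sample odds ratio ad/bc is reported (no conditional-MLE OR).

## Problem sizes used by the tests and acceptance script

Simulated depths are 300–2000×, cohort draws up to n = 5000, 50-replicate
Monte-Carlo runs for VAF and clone-tree recovery — sizes chosen so the
full suite and the acceptance script each complete in a couple of minutes
while leaving the binomial noise floor well below the tolerances tested.

## Known limitations

- Read simulation omits indel sequencing errors, PCR duplicates and
  base-quality structure; caller robustness to those is untested here.
- Coverage-based VAF is structurally uninformative for TDs much shorter
  than the read length (see above).
- Co-mutations are drawn independently; real co-occurrence/exclusivity
  structure is not emulated.
- Clonal inference assumes purity 1, two timepoints, and copy-number
  states supplied as input (UPD/deletion status is not inferred from the
  data).
- The fixture locus is synthetic; positions quoted genomically are fixture
  coordinates, while c. coordinates follow the real transcript numbering.
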