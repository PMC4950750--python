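# Methods

This note records the models, parameter choices and numerical decisions
behind `conswes`, and what the synthetic-data validation does and does not
demonstrate.

## Coordinates and intervals

All internal coordinates are 1-based fully closed, the convention in which
clinical breakpoint junctions are printed; a deletion written
`chr1:g.213396378-213592823` spans `end − start + 1` = 196,446 bp.  BED I/O
converts to the 0-based half-open on-disk convention at the boundary only.
Region strings with commas, an HGVS `g.` prefix, or a trailing assembly tag
are accepted; chromosome names are normalised to `chr`-prefixed form, and
mixed-dialect input is tolerated.  Both printed region styles
(`chr…:g.a-b[hg19]` and bare `chr…:a-b`) are treated as 1-based inclusive —
the closed-interval reading is the only one that reproduces the two
published junction sizes from their coordinates.

## AOH model

The B-allele frequency at a called variant site is the fraction of reads
supporting the alternate allele.  The analysis works on the signed deviation
`BAF − 0.5` over the sample's *called non-reference* sites only: homozygous-
reference positions are absent from a per-sample call set, so the −0.5 tail
does not arise, heterozygous sites sit near 0, and homozygous-alternate
sites near +0.5.  A segment mean > 0.45 is therefore effectively a
"no heterozygous calls" criterion — the hallmark of autozygosity.

Thresholds are applied exactly as published: mean signal **> 0.45** (strict)
and genomic span **> 1 kb** (strict) for an AOH call; summary statistics
(count, max, min, median, mean, total length) cover AOH regions
**≥ 0.5 Mb** (inclusive).  A segment's genomic span runs from its first to
its last member site (the span convention is otherwise unspecified, and the
first/last-site reading is the most conservative).  Sites with fewer than 10
total reads are dropped for signal stability; indel sites are excluded by
default (both configurable).  Multi-allelic records are skipped rather than
decomposed.  Summaries cover autosomes only: the hemizygous male X is one
long run without heterozygous calls and would otherwise dominate every
total.  AOH *calls* are still made on chrX, where they legitimately support
hemizygous deletion calling.

### Segmentation

Circular binary segmentation in its standard form: for each segment, the
max over all arcs (i, j] of the t-like statistic comparing the arc mean with
the complement mean (single within-segment variance estimate), assessed by
permutation, splitting recursively at the best arc's boundaries while the
permutation p-value `(1 + exceedances) / (1 + n_perm)` is ≤ α.  Defaults:
α = 0.01, 1,000 permutations, minimum 10 markers in any arc or complement.
The permutation seed is a fixed CRC-derived function of (sample, chromosome)
plus the pipeline seed, so results are reproducible and independent of
sample order.

Numerical choices:

* The observed statistic always scans every admissible arc (O(n²) via
  cumulative sums).  For segments longer than 256 markers the *permutation*
  scan is restricted to arcs anchored on a 64-point boundary grid; this
  slightly underestimates the null maximum (mildly anti-conservative), in
  the spirit of the arc-sampling used by standard CBS implementations for
  long chromosomes.  Below 256 markers the null scan is exact.
* Permutations run in blocks of 128 with early stopping once the p-value
  can no longer reach α; the accept/reject decision is unchanged.
* Ties in the arc scan break toward the shortest, then leftmost arc.  An
  arc and its complement induce the same split.
* Constant segments (zero variance) and segments shorter than twice the
  marker floor are leaves.

The test suite cross-checks the vectorised arc scan against an exhaustive
plain-loop scan on short tracks, and verifies that called changepoints
achieve the brute-force minimal within-segment sum of squares.

## Exon-deletion calling

Depth is normalised per exon to RPKM = `(count / (length/1000)) /
(total_mapped_reads / 10⁶)`.  The three published criteria are applied with
strict inequalities: sample RPKM **< 0.5**; fraction of samples that low at
the exon **< 0.5 %**; exon located within an AOH region **> 1 kb**.  Because
a ~31-sample cohort alone cannot produce frequencies below 0.5 %, the
frequency denominator is the cohort pooled with a reference-panel RPKM
matrix (default 1,000 samples) supplied as an input, standing in for the
large exome database such cohorts are jointly called with.  The frequency
numerator uses the same RPKM < 0.5 definition of "low".  "Located within"
means fully contained — partial overlap does not count (conservative).  The
AOH regions used are the called 0.45-mean segments; no looser segment set is
maintained.  Runs of consecutively flagged exons merge within a gene only;
a single unflagged exon splits a run; male-X calls are labelled hemizygous.
Heterozygous deletions and duplications are out of scope (external callers
handle those; a BED-like adapter ingests their output for the SNV+CNV logic
and comparison tables).

## Segregation models

Variants pass a rarity filter (AF ≤ threshold in every configured database;
missing annotation counts as novel) and an effect filter (loss-of-function
always; other damaging classes when ≥ 2 prediction programs concur — the
predictors themselves are upstream annotations, not reimplemented).
Defaults: AF ≤ 0.001 for recessive screening, ≤ 0.0001 for de novo; these
are configurable screening conventions, not published values.  Filters
commute, so their order is irrelevant.

Model contracts (explicit pass / fail / not-testable; missing genotypes and
inapplicable pedigree structure are *not testable*, never failures):

* **Homozygous recessive** — every genotyped affected homozygous-alternate
  (or hemizygous), every genotyped parent a heterozygous carrier, no
  unaffected sibling homozygous.
* **De novo** — proband carries the allele; both parents genotyped
  homozygous-reference with depth ≥ 10.
* **X-linked hemizygous** — affected males hemizygous on chrX with carrier
  (heterozygous) mothers.
* **Compound heterozygous** — two variants of one gene, proband
  heterozygous for both, each parent transmitting exactly one (in trans by
  trio phasing; no population phasing attempted).

The SNV+CNV compound-heterozygote detector fires on the genotype pattern
alone — proband homozygous-alternate, exactly one parent heterozygous, the
other homozygous-reference — because that pattern is Mendelian-inconsistent
for a true homozygote; an overlapping deletion call in the apparently
wild-type parent (or the proband) upgrades the flag to corroborated.  It
never fires when both parents carry the allele.  Male-X hemizygous calls
are written as diploid genotypes in the VCF and re-coded from pedigree sex
at parse time, which is robust to the ploidy conventions of different
callers.

A documented rescue mode exists in spirit for quality-filtered variants
(poor-quality indels can be re-examined when a sibling's genotype supports
segregation); the quality flags are carried on each record for this purpose.

## Candidate ranking and classification

The eight evidence criteria and weights (3, 2, 2, 1, 2, 1, 1, 1; maximum 13)
are fixed.  The pipeline auto-fills only what it can observe — multiple
families, loss of function, multi-program deleteriousness, rarity in ≥ 2
databases — and takes the four curated criteria (human interactor/paralog
phenotype, animal models, region association, tissue expression) from an
optional evidence TSV, defaulting to false: literature and expression
evidence is curation, not computation.  Ranking is descending by score with
alphabetical tie-breaks for determinism; the red/orange/yellow/green bands
are quartiles of 0–13 and purely presentational.  Variants in novel
candidate genes are confined to VUS / VUS-favoring-likely-pathogenic;
requesting a definitive label for one raises an error.

## Cohort report

Percentages are computed at one decimal and rounded half-up to integers,
with both retained.  Published figures occasionally round differently
(11/31 = 35.48 % appearing as 36 %; 12/31 = 38.7 % appearing as both 38 %
and 39 %); the report emits the exact one-decimal value alongside the
half-up integer so such discrepancies are visible rather than forced into
agreement.  Category counts partition the cohort; phenotype groups overlap
by design, so their percentages need not sum to 100.

## Synthetic cohort generator

The generator is a first-class module emulating the statistical structure
the pipeline assumes, on a miniature genome chosen so the full suite runs in
seconds on one CPU: three autosomes of 8/6/5 Mb plus a 4 Mb chrX, ~44 genes
of 4–15 exons (150 bp exons, 2 kb introns), variant sites as a Poisson
process with 2.5 kb mean spacing, and common population allele frequencies
uniform on (0.05, 0.95).

* **Families** are father–mother–proband trios; 28/31 consanguineous and
  13/31 male probands by default, matching the cohort composition the
  pipeline is designed for.
* **Autozygosity**: each proband receives non-overlapping tracts
  (≥ 0.6 Mb each) summing to a target drawn from the published consanguineous
  (86.5–507.5 Mb) or outbred (97.1–118.8 Mb) whole-genome totals scaled by
  the miniature-to-hg19 autosome ratio (19/2881).  Targets are drawn from
  the central 76 % of the configured range so that tract-placement
  rounding and first/last-site span quantisation keep *measured* totals
  inside the configured envelope; tract lengths sum exactly to the target.
  Causal genes are anchored inside a tract.  Inside a tract the proband is
  homozygous for an ancestral allele that both parents are forced to carry,
  preserving Mendelian consistency.
* **Depths and allele fractions**: site depth is Poisson around 80× (halved
  on the single-copy male X and in heterozygous-deletion spans); allele
  fractions are the exact dosage fraction plus Gaussian noise of sd 0.05
  (the binomial sampling scale at ~80×), clipped to [0, 1].  Exon counts
  are negative binomial (dispersion 60) around depth × length / read-length
  with log-normal exon- and sample-effects; a homozygous deletion retains
  0.05 % residual coverage, a heterozygous one 50 %.  The reference panel
  is drawn per exon with 20 % log-normal spread and a 0.05 % per-exon
  deletion rate, making the < 0.5 % frequency filter non-trivial.
* **Planted events**: a two-exon homozygous deletion in a 15-exon gene
  inside an AOH tract, a single-exon homozygous deletion, a hemizygous
  single-exon male-X deletion, and a paternally inherited heterozygous
  deletion over the last seven exons of a gene with a maternal SNV inside
  the deleted span — the proband's VCF genotype at that site is
  homozygous-alternate, reproducing the deletion-uncovered-SNV signature;
  the heterozygous deletion is emitted through the external-CNV adapter
  (such calls are outside this caller's scope).  Planted SNVs cover
  homozygous-by-descent, de novo (4 families), compound-heterozygous and
  X-linked inheritance, with AF 0 annotations; per-family diagnostic
  categories follow the 2 : 9 : 6 : 11 : 3 proportions.
* **Determinism**: all randomness flows from one seed through named
  CRC-keyed substreams per sample and purpose, so identical configurations
  yield byte-identical files.

### What passing the synthetic suite does and does not show

The generator reproduces the *signal structure* the method exploits —
BAF bimodality, depth collapse at deletions, Mendelian transmission,
tract-scale autozygosity — but not read-level artefacts (mapping bias,
GC waves, capture batch effects, contamination), population LD, or
recombination-map realism of tract placement.  Recovery of 100 % of planted
tracts ≥ 1 Mb at ≥ 95 % reciprocal overlap, 100 % deletion recall with zero
out-of-AOH calls, and zero false segregation passes therefore validate the
implementation logic and thresholds, not expected performance on real
exomes, where noise sources the generator omits will erode all three
numbers.

## Problem sizes

Default validation runs use 31 trio families (93 samples), ~7,600 variant
sites, ~350 exons, and a 1,000-sample reference panel; the complete test
suite runs in about half a minute and the acceptance script in about
fifteen seconds on one CPU.  All sizes are configuration, not constants.

## Known limitations

* No heterozygous-CNV or duplication calling from depth; no breakpoint
  assembly.
* No variant annotation: allele frequencies, effect classes and damaging
  prediction counts are expected as VCF INFO fields.
* AOH segmentation assumes a jointly called multi-sample VCF with allelic
  depths; single-sample gVCFs would first need merging.
* The CBS permutation grid approximation can, in principle, split a long
  segment slightly too eagerly; with the 0.45-mean AOH filter downstream
  this has no observed effect on calls.
* Shared-AOH mapping across families (homozygosity mapping proper) is out
  of scope; AOH is reported per proband.
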