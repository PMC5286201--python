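# Methods

This note documents the models and procedures implemented in
`pombesv`, the defaults and why they were chosen, what the synthetic
data do and do not emulate, and the numerical choices made where the
design was genuinely open.

## Coordinates and formats

Internal coordinates are 1-based inclusive (VCF-like) everywhere; BED
input/output converts at the I/O boundary, so a BED span `chr1 999
2000` becomes `start=1000, end=2000` internally and round-trips
unchanged. SV length is `end − start + 1` for deletions, duplications
and inversions; an insertion's length is that of the inserted
sequence. A translocation is one two-locus record internally; on VCF
output it is written as a single CHR2/POS2 record (the dialect the
reader treats as canonical), with breakend (BND) mate pairs available
as an option and accepted on input, where each mate pair collapses
back to one translocation. SVLEN is written only for insertions: for
symbolic span alleles htslib derives END from SVLEN under the
`END = POS + SVLEN` convention, which conflicts with inclusive
lengths, and END alone fully determines the span.

## SV simulation

`plan_svs` places the requested number of events of each type
uniformly on the reference, rejecting placements that (a) come within
`min_gap_bp` (default 1000 bp) of another event or a chromosome end,
or (b) contain N runs. Each event gets up to 1000 placement attempts
before the simulator fails loudly rather than silently under-delivering.
Duplications are tandem — the extra copies sit immediately after the
source segment — because tandem events are what read-depth genotyping
sees as a contiguous dosage change. Translocations are reciprocal
exchanges of two internal segments on distinct chromosomes; both
junctions are recorded in the truth record. Truth coordinates are
reported on *reference* coordinates, which is what comparing caller
output against truth requires; the altered genome is a separate
artifact. Applying events works right-to-left per chromosome as local
splices, so per-chromosome length accounting holds exactly:

    len(out) = len(ref) − ΣDEL + ΣINS + Σ(copies−1)·len(DUP)

with translocations exchanging segment lengths between the two
chromosomes and inversions length-neutral.

Background point mutations use Binomial(L, rate) substitution counts
(substituted bases never equal the reference base) plus small 1–10 bp
indels, all recorded on pre-mutation coordinates. The `paperlike_spec`
preset draws a total SV count uniformly in 30–170 and splits it across
DEL/DUP/INV/TRA in the proportions 45/35/8/12 — the type composition
of curated SV catalogues in fission yeast population data. The default
size range for desk-scale genomes is 500–5000 bp; real yeast CNVs are
larger (kb–hundreds of kb), but placement density, not event size,
drives every behaviour tested here.

## Benchmarking

The match predicate (same type, same chromosome(s), |Δstart| ≤ tol and
|Δend| ≤ tol, default tol = 1000 bp; translocation loci compared as
unordered pairs because callers disagree on which breakend is "start")
is the single primitive behind both evaluation and merging. Counting
is deliberately many-to-many: a truth record is a true positive if any
call matches it, and a call is a false positive if it matches nothing.
No one-to-one assignment is attempted — the predicate alone does not
justify one, and set-level counting makes sensitivity monotonically
non-decreasing and FDR non-increasing in the tolerance, which is
property-tested. Empty truth leaves sensitivity undefined (NaN with a
warning) rather than silently 0 or 1; likewise FDR for empty callsets.

## Consensus merging and filters

Within-caller duplicates and cross-caller clusters are both formed by
single-linkage closure of the match predicate — the natural closure of
a pairwise rule, at the documented cost that a chain of pairwise
matches can span more than the tolerance end-to-end. Consensus
coordinates are the per-coordinate median of cluster members
(fractional midpoints floored to keep coordinates integral): the
median is order-independent, robust to a single outlier member, and
always within tolerance of a member on each coordinate. Consensus
support counts *distinct caller labels*, so two calls from one caller
never masquerade as two-caller support. The representative's
paired-end support is the maximum over members.

Filters run in pipeline order consensus → paired-end support → regions,
each logging in/out counts to an audit record:

* **pe_support ≥ 11** (i.e. support of 10 or less discarded). Calls
  with *unknown* support are stored as absent — never coerced to 0 —
  and are dropped by this filter with a logged count, since unknown
  support cannot satisfy the threshold.
* **Region filter:** a call is dropped if *either* breakpoint falls in
  a low-mapping-quality region, or if *both* breakpoints fall inside
  annotated LTR intervals. One breakpoint in an LTR is not
  disqualifying.

## CNV allele calling

Coverage is summarised in fixed-width windows (default 100 bp);
windows overlapping a region boundary are excluded so diluted edge
signal cannot leak in, and a region with fewer than two fully
contained windows — or zero mean reference coverage — is flagged
uncallable rather than guessed. The duplication rule requires, against
*each* of the two reference strains independently: one-sided Wilcoxon
rank-sum P < 1e-10 *and* mean-coverage ratio > 1.8. Deletions mirror
this with direction "less" and ratio < 0.2. The direction of the
one-sided test is bound to the candidate class (greater for DUP, less
for DEL): this is the only reading consistent with a one-sided test
plus a two-sided ratio gate. Ratios use window *means* (matching the
rank-sum location-shift alternative); the reported copy number is the
window-wise *median* of alt/mean(refs), which is more stable for a
single reported value.

The rank-sum P value uses exact enumeration for tie-free samples below
30 observations per group and the normal approximation with tie and
continuity correction otherwise (the two agree within 0.01 on random
small samples, which is verified against a brute-force enumeration
oracle in the tests). At window counts ≥ 60 and sequencing depth 40
the decision rule separates copy classes {0, 1, 2, 4} essentially
perfectly; the binding constraint is the ratio gate, not the P value.

A CNV *segregates* within a clonal cluster when at least two distinct
allele calls occur among cluster members with callable regions.

## Transience

For each CNV region, `extract_flank_snps` collects SNPs from 20 kb
on each side of the region (outer boundaries inclusive, region
interior excluded); a CNV with no flanking SNPs is legitimate and
flagged, not an error. SNP trees are built by neighbour joining on
Hamming distances normalised by shared typed sites — an approximate
maximum-likelihood builder would also serve, but branch-length totals,
not topologies, drive the analysis, and NJ keeps the package
self-contained; externally built newick trees can be substituted since
trees are scikit-bio `TreeNode` objects.

Neighbour joining is the standard Saitou–Nei algorithm with two
deterministic conventions: ties in the Q criterion resolve to the
lowest index pair, and a negative branch length is clamped to zero
with the deficit moved to its sister edge (preserving the pair's
summed length). Additive matrices are recovered exactly, which the
tests verify against path-length oracles on random 4–8 taxon trees.

Relative transience of a CNV within a clonal cluster is
σ_rc = σ_ic/σ_oc, the ratio of the sample standard deviations (n−1
denominator — the estimator convention chosen here) of copy number
inside vs outside the cluster. σ_oc = 0 leaves the ratio undefined:
it is flagged and excluded from summaries, never reported as infinite.
σ_rc is scale-invariant (multiplying all copy numbers by c > 0 leaves
it unchanged) and 0 when the CNV is fixed within the cluster. Note
that as a ratio of sample SDs its expectation exceeds 1 for matched
inside/outside distributions at small group sizes (Jensen bias of
1/s); comparisons between clusters of similar size are unaffected.
Across CNV panels, per-CNV copy-number SD and per-CNV NJ-tree total
branch length are strongly rank-correlated (Spearman ρ > 0.8 on the
synthetic panels here), which is why the SD is a usable summary of
transience.

## Viability correlations

Pairwise strain distances are counts of variants at which both strains
are genotyped and differ; CNVs are first merged when their reciprocal
overlap exceeds 50% — both overlap fractions must exceed the
threshold, the unambiguous reading of ">50% overlap" — *and* their
allele vectors are identical. Kendall correlations are tau-b
(tie-corrected) throughout, because distance counts are heavily tied
and tau-a would be misleading. The first-order partial tau is
evaluated from the three pairwise tau-b values; its P value uses the
normal approximation z = 3τ√(n(n−1)/(2(2n+5))), two-sided, the
convention of the R `ppcor` package. A partial tau is undefined
(flagged) when a control correlation is ±1. The two-covariate linear
model of viability on SNP and rearrangement distance is reported as a
descriptive OLS r² only.

## Synthetic data

The generators in `pombesv.synth` define the study conditions used by
the tests and the acceptance script:

* `random_genome` — i.i.d. bases at 36% GC (yeast-like). It has no
  repeats, so the LTR/low-MQ filters and repeat-mediated breakpoint
  artefacts of real data are exercised only through explicit interval
  fixtures.
* `mock_caller` — a three-parameter error model (sensitivity,
  breakpoint jitter SD, uniform false positives avoiding truth ±1 kb).
  Jitter is truncated at ±3 SD, so at the 150 bp default every emitted
  breakpoint stays well inside the 1 kb match tolerance; the model has
  no caller-specific biases (size-dependent sensitivity, systematic
  breakpoint shifts, shared artefacts), so consensus results on it are
  the *independent-errors* baseline: with per-caller sensitivity
  p = 0.8, 2-of-3 consensus sensitivity is 3p²(1−p) + p³ = 0.896, and
  random false positives from different callers essentially never
  co-cluster (birthday-collision probability at 100 FPs per caller on
  12 Mb is ≪ 1), driving consensus FDR below 0.01. Real callers'
  errors are correlated, so real consensus gains are smaller.
* `synth_coverage` — Poisson window counts with mean depth × copy
  number (depth 40 by default, matching typical downsampled panels), or
  negative binomial for over-dispersion. Poisson is the default because
  it has closed-form checks; real coverage is over-dispersed and
  GC-biased, so real-data accuracy will be below the near-perfect
  recovery seen here.
* `synth_clonal_population` — clusters with founder SNP haplotypes,
  per-member private mutations capped so intra-cluster pairwise SNP
  distances stay below 150 by construction, and CNV states flipping
  away from the founder at a configurable rate (flips produce
  segregating CNVs).
* `synth_viability_crosses` — 58 crosses (the panel size the analysis
  is designed for) with viability = clip(1 − 0.4·u_snp − 0.4·u_rearr +
  N(0, 0.15²)) and an independent CNV distance. Effect sizes were set
  by an upfront power calculation: they yield partial τ ≈ 0.4, whose
  normal-approximation z at n = 58 is ≈ 4.4, so both controlled
  correlations are significant at α = 0.05 in well over 90% of seeds
  while the independent CNV distance stays non-significant in ~95%.

Everything is deterministic given its seed and returns its ground
truth alongside the data. Passing tests on these generators
demonstrate the *logic* of the pipeline (matching, clustering,
thresholds, statistics) under known conditions, not performance on
real sequencing data with correlated caller errors, repeats and
mapping artefacts.

## Problem sizes

The test-suite and acceptance-script simulations use: a 2 Mb
three-chromosome genome with 60 SVs for round-trip scoring; a 12 Mb
genome with 500 truth events for the consensus closed form and with
100 events × 100 seeds × 3 callers for false-positive suppression; 500
random small samples for rank-sum agreement; 400 regions of 60–120
windows at depth 40 for CNV class recovery; 100 random 4–8 taxon trees
for NJ; 60-CNV × 24-strain panels for the SD/branch-length
correlation; and 100 seeds × 58 crosses for the viability pattern.
These sizes give Monte-Carlo error comfortably below the assertion
margins (for example the 2-of-3 consensus check uses 3 binomial SDs,
±0.041 at n = 500) while the whole suite runs in well under a minute.

## Known limitations

* Single-linkage chains can drift: a cluster's end-to-end span can
  exceed the tolerance, and the median representative is then only
  per-coordinate (not jointly) within tolerance of every member.
* The simulator places events uniformly; real SVs cluster near
  chromosome ends and repeats.
* The CNV caller assumes two reference strains at copy 1 and constant
  per-window capture efficiency; no GC correction is applied.
* σ_rc compares SDs, not allele frequencies; a CNV at high copy number
  variance outside all clusters yields small σ_rc everywhere even if
  it segregates within a cluster.
* Genotype handling in VCF I/O is limited to presence/absence (0/1/
  missing); ploidy-aware genotypes are out of scope.
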