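# Methods

## Coordinates and domain model

All internal coordinates are 0-based half-open on the forward genome
strand; GTF converts at the I/O boundary (1-based inclusive), BED and
bedGraph pass through unchanged.  A transcript model is an ordered,
non-overlapping exon chain with a strand; TSS and PAS are the strand-aware
outer coordinates, and the junction chain is the ordered list of intron
intervals.  Using a single convention everywhere removes the usual
off-by-one failure modes, and every window rule below is applied to these
canonical coordinates.

## End validation

Evidence pools are unions: 5' = CAGE-like peak midpoints ∪ reference TSSs;
3' = end-evidence positions with ≥ `min_pas_reads` (default 5) supporting
reads ∪ reference PASs; junctions = read counts summed over all provided
junction tables, keyed by exact intron coordinates.  Support windows are
inclusive: a TSS or PAS within ≤ `end_window` (default 50 nt) of the
nearest same-strand pool position is supported; a junction is supported by
≥ `min_junction_reads` (default 2) exact-match reads.  Junction matching is
exact rather than fuzzy: short-read junction calls are base-precise, and
exactness is conservative and reproducible.

Deduplication groups isoforms with identical junction chains whose PASs
chain within the window (single linkage; mono-exon isoforms group only
when both ends are mutually within the window, since they have no chain to
compare).  Within a group the keeper minimizes TSS distance to the 5'
pool; ties keep the 5'-most TSS (preserving the longest 5' UTR), then the
lexicographically smallest id, making the operation deterministic and
idempotent.

FLNC read assignment requires an identical junction chain and both ends
within the window (mono-exon reads match mono-exon isoforms only); among
multiple candidates the smallest summed end distance wins and residual
ties are left unassigned, so per condition assigned + unassigned always
equals the input read count.

## Structural classification

A decision cascade assigns exactly one of eight categories: FSM (chain
equals a same-strand reference chain), ISM (chain is a consecutive —
not merely subset — sub-chain of one), then fusion (the isoform overlaps
≥ 2 same-strand reference genes whose own spans are disjoint, tested
before the novelty categories so multi-gene isoforms are not mislabelled
NIC/NNC), NIC (all donors and acceptors annotated, same-strand gene
overlap), NNC (≥ 1 unannotated splice site), then genic / antisense /
intergenic by overlap.  Mono-exon isoforms can only be FSM (a mono-exon
reference transcript with both ends within 50 nt), genic, antisense or
intergenic, because junction-based definitions are vacuous for them.

Internal priming follows the A-rich rule: the 20 nt immediately downstream
of the PAS, read in transcript orientation (complemented T-runs on the
minus strand), trigger the flag on ≥ 6 consecutive A or an A fraction
strictly greater than 60 % (12/20 exactly does not trigger).  Windows
truncated at a chromosome edge are evaluated over the available bases.
The pipeline excludes flagged non-FSM isoforms by default
(`ip_exempt_fsm=True`): an isoform whose chain exactly matches the
reference is most plausibly a real transcript that happens to end in an
A-rich context, while novel isoforms get no such benefit of the doubt.
Setting the flag to False drops every flagged isoform.

## Abundance dynamics

Abundance = FLNC(isoform)/FLNC(gene) per condition.  Classes: the largest
fraction is major (ties: larger raw count, then smaller id), abundance
< 0.1 is inactive, the rest minor; a gene with zero FLNC reads has all
isoforms inactive at abundance 0, which keeps the inactive↔active
transitions countable.  Status between conditions: |Δ| ≥ 0.1 inclusive
(an epsilon of 1e-9 keeps the inclusive boundary inclusive under float
subtraction).  The changed-usage percentage is
100·(Up + Down)/(Total − Inactive-in-both), reported to one decimal.

## Promoters

Promoter identity is the strand-aware first intron, exactly — not a TSS
clustering — so promoter calls inherit the base precision of junction
evidence; mono-exon transcripts are excluded because junction-count
activity is undefined for them.  Absolute activity per sample is the
first-junction count divided by the sample size factor (default:
per-sample total junction count scaled to mean 1); relative activity is
the within-gene fraction; classes come from the mean relative activity
across all samples (major = highest; < 0.1 inactive; else minor).

The differential test is an exact conditioned binomial: pooled
first-junction counts per condition, with the null success probability
given by the per-condition total junction counts, and two-sided p by tail
doubling.  This replaces a negative-binomial regression with a
self-contained, oracle-checkable exact test; the pooling discards
between-replicate dispersion, which is acceptable for the Poisson-like
counts the generator produces but anticonservative for overdispersed real
libraries.  DRP requires |FC| > 1.5 (log2 fold change of normalized pooled
counts with pseudocount 0.5) and BH-adjusted p < 0.05.  AP additionally
requires mean relative activity > 0.1 in at least one condition (the
per-condition reading of an ambiguous rule; documented, configurable), a
between-condition relative-activity shift > 0.1, and gene FPKM > 1 in at
least one condition.  AP direction is the sign of the expression fold
change; a gene with up- and down-APs is a switching gene.

## Splicing

Local events come from pairwise within-gene chain comparison, merged by
(type, defining coordinates): SE (internal exon vs. flank-to-flank
intron), A5/A3 (intron pairs sharing one boundary whose differing-side
flanking exons overlap — the alternative site lies within an exon body;
strand decides donor vs. acceptor), MX (mutually exclusive internal exons
between shared flank coordinates), IR (an exon spanning another chain's
intron with shared outer boundaries), AF/AL (both-first / both-last
introns sharing the inner boundary with non-overlapping outer exons;
first/last are strand-aware).  Intron pairs that satisfy neither the
exon-overlap condition nor the AF/AL condition — e.g. a skip junction
against its own flank — produce no donor/acceptor event, which keeps an
SE structure from spawning spurious A5/A3 calls.  Inclusion-form
conventions (the exon-retaining, shorter-intron, 5'-proximal, or
5'-distal form, by type) are fixed and deterministic.

PSI = ΣTPM(inclusion)/ΣTPM(inclusion ∪ exclusion) per sample, NA at zero
denominator; Δ PSI is the difference of per-condition means over defined
samples.  The differential test splits `count_scale` (default 100)
pseudo-counts per condition proportionally to pooled inclusion/exclusion
TPM and applies a Fisher exact test, BH-corrected.  `count_scale` is the
sensitivity knob: it decouples the test from library-size conventions
(raw TPM sums would make significance depend on how many genes are in the
table) and at 100 makes a ΔPSI of ~0.3 detectable while leaving
replicate-noise-sized fluctuations insignificant.

## APA

PAS positions cluster by single-linkage chaining at ≤ 50 bp; the
representative is the maximum-support member (ties: 5'-most).  A cluster
is known when its representative is within 50 nt of a same-strand
reference PAS.  The two-PAS region model takes, per gene, the cluster
representatives on the longest terminal exon; proximal = 5'-most and
distal = 3'-most candidate (intermediate PASs are ignored — the
underlying two-segment model has no canonical multi-PAS extension);
common region = terminal-exon start → proximal, extended region =
proximal → distal, requiring ≥ 50 nt of extended region.

PDUI = mean(extended coverage)/mean(common coverage), clamped to [0, 1],
NA at zero common coverage.  Under uniform within-transcript coverage
this is exact: the extended region is covered only by distal isoforms and
the common region by all, so the ratio is the distal weight.  The
differential test builds integer read proxies round(mean depth × region
length / read_length) (read_length default 150 nt) per region and
condition and applies a Fisher exact test; calls require BH-adjusted
p < 0.05 and |ΔPDUI| ≥ 0.2.

Sequence context: the nucleotide profile covers offsets −flank..+flank−1
around representatives (offset −1 = last transcribed base), strand-
corrected by reverse complement; the poly(A)-signal scan reports the
fraction of clusters with AATAAA in the 50-nt upstream window.

## Statistical primitives

Fisher's exact test is two-sided by the "sum of tables as or less
probable" rule with 1e-7 relative tolerance (scipy's convention, verified
exhaustively against a log-gamma enumeration oracle for all tables with
grand total ≤ 30).  The two-sided binomial is tail-doubling capped at 1 —
implemented directly, since the minlike convention of off-the-shelf
binomial tests differs.  BH adjustment is standard step-up with
monotonicity, order-preserving.  Fold changes use pseudocount 0.5 so
zero counts stay finite; the value is configurable.

## The synthetic-data generator

One mechanism drives everything: each transcript carries a per-condition
expression weight summing to 1 within its gene, and all four effect types
are planted by choosing those weights (promoter switch 0.8/0.2 ↔ 0.2/0.8,
PSI 0.7 → 0.3, PDUI 0.8 → 0.4, abundance 0.65 ↔ 0.35 by default; null
genes of the same structure keep their weights constant).  This gives the
truth manifest a single source of truth: planted PSI, PDUI, relative
activity and abundance are all deterministic functions of the weights.

Gene structures are templates realized on alternating strands (mirrored
for '−'): a cassette-exon pair for abundance/PSI genes, a two-first-exon
structure for promoter genes, a shared-chain tandem-PAS pair ≥ 200 nt
apart for APA genes, and a background cycle through all seven local event
types plus mono-exon and simple genes.  Upstream of every PAS the genome
carries AATAAA at offset −20 inside an A-enriched (p=0.6) −25..−1 window;
the 20 nt downstream are rejection-sampled to never look like internal
priming, so the artifact filter is exactly testable.  Elsewhere the
genome is i.i.d. uniform ACGT, which makes the profile-enrichment test
sharp.

Measurements: FLNC counts are one multinomial per condition at
`flnc_depth_per_gene` × n_genes total reads (default 2 000/gene, enough
that a Δabundance of 0.3 is ~20 standard errors); junction counts are
Poisson per sample around expression-weighted `junction_depth_per_gene`
(default 500/gene pooled per condition); coverage is per-base Poisson
around the uniform within-transcript expectation at `coverage_depth`
(default 50×); TPM replicates (default 3 per condition) multiply the true
TPM by mean-one lognormal noise (`tpm_noise_sd`, default 0.2); CAGE and
PAS evidence positions carry Gaussian jitter (`jitter_sd`, default 5 nt,
well inside the 50-nt windows); true PAS evidence gets ≥ 5 reads and
`n_decoy_pas` decoys get 1–4 reads placed > 50 nt from any true PAS, so
the read filter removes exactly the decoy set.  Everything is
deterministic given (config, seed), to the byte for emitted files.

What the generator does not emulate — and what passing tests therefore do
not show about real data: coverage has no 3' bias or positional ramps
(deliberate, so PDUI parameter-recovery is not confounded by a bias
model); junction and FLNC counts have no overdispersion beyond Poisson /
multinomial; there is no sequencing-error or alignment model (reads are
exon chains, not sequences); genes do not overlap; and evidence jitter is
symmetric Gaussian rather than the asymmetric 5'-degradation seen in real
long reads.  On real libraries the exact tests will be anticonservative
under overdispersion, and support rates will fall below the ~100 % the
clean scenarios produce.

## Problem sizes

The test suite and the acceptance script use scenarios of 20–200 genes
(genomes of ~50 kb–1 Mb), chosen so each recovery suite measures 40
planted effects against ≥ 60 nulls at the default depths while the whole
suite remains interactive (well under a minute excluding the exhaustive
Fisher sweep).  The noiseless-limit checks raise depths to 10^5 and set
jitter and TPM noise to 0; empirical PSI/PDUI/relative activity then sit
within 0.02 of the planted truth.

## Known limitations

* The exact conditioned tests pool replicates; real biological replicates
  with overdispersion would need a dispersion-aware model.
* ISM does not distinguish 5'-degradation fragments from genuine shorter
  isoforms beyond the TSS-support evidence.
* The two-PAS APA model ignores intermediate PASs and internal-exon APA.
* AS events are binary local events; nested or graph-structured event
  complexes are out of scope.
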