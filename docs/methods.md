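# Methods

## Scope and data model

`demethtf` operates on four kinds of input: per-CpG bisulfite methylation
calls (counts of methylated and total reads per CpG cytosine), a reference
genome with chromosome sizes, a collection of position probability
matrices (PWMs) with a many-to-many motif→TF mapping, and — for the array
arm — probe manifests with per-condition β- or M-value tables.  All
internal coordinates are 0-based, half-open; 1-based dialects (array
manifests) are converted on read.  Methylation percentages are always
recomputed from counts; a file's own percent column is ignored, because the
per-bin exact test needs counts, not rates.

## Binned methylome

The genome is tiled into fixed-width bins (default 200 bp; TF-driven
demethylation spans roughly 194 bp on either side of a binding site, so one
bin covers the expected footprint).  Trailing partial bins are dropped so
that the enrichment window geometry downstream (± 5 bins, center offsets)
stays exact.

Per bin:

- `percent` — unweighted mean of the per-CpG percentages in the bin.  This
  mirrors averaging a percent signal track over intervals; sequencing depth
  deliberately does not weight the mean.
- `tags per billion` — the bin's summed read count over the library-wide
  total, × 10⁹.  A bin is *covered* when this strictly exceeds 100
  (literal reading of "more than"); uncovered bins carry no percentage.
  The library total is Σ n_total over all calls when not supplied; whether
  "tags" should mean raw reads or CpG-report depth is not derivable from
  the inputs we accept, so summed call depth is used and documented here.

Replicates are averaged per bin over the replicates in which the bin is
covered; the result is covered when any replicate is (the permissive rule;
a strict all-covered rule would discard bins that a single shallow
replicate misses).  Aggregate counts are summed across replicates so the
differential test sees all evidence.

## Differential methylation

Because replicates are pre-averaged, each bin contributes one 2×2 table:
(methylated, unmethylated) × (reference, target).  The per-bin test is a
two-sided Fisher exact test: the hypergeometric support is enumerated and
all tables with probability ≤ the observed one (relative tie slack 10⁻⁷
against floating-point noise) are summed.  Log-probabilities come from
cached log-factorials, so per-bin totals in the thousands are exact and
fast.  This is the single-sample path of the standard differential-
methylation tools; no dispersion model is fitted, because the averaged
counts carry no replicate structure to estimate one from.

Multiple testing is Benjamini–Hochberg over all co-covered bins.  Emission
requires |Δ| > 50 percentage points AND q < 10⁻⁴, both strict; direction is
the sign of Δ = target − reference (negative = demethylated).  Bins covered
in only one profile are excluded rather than imputed.

## Central motif enrichment

Regions are demethylated bins ± 5 bins (11 × bin_size = 2,200 bp); regions
overrunning a chromosome end are discarded.

**Scanning.**  PWM probabilities are floored at 10⁻⁴ and renormalized, then
converted to log₂-odds against the motif's background model.  Both strands
are scanned (reverse strand via the reverse-complemented matrix).  A site's
*offset* is its midpoint (left-of-middle base for even lengths) minus the
window center.  Per region, the single best site above
`score_threshold_fraction` × (maximum achievable score) is kept; ties break
toward the smaller |offset|, then the forward strand, then the smaller
offset.  Regions that are more than half N are skipped and logged.  The
threshold fraction defaults to 0.7: a permissive scanner floods the curve
with noise sites, a strict one starves it; 0.7 keeps planted-motif recovery
stable and is exposed in the API and CLI.

**Site-probability curve.**  `prob[o]` is the fraction of scored regions
whose best site sits at offset `o`; each region contributes one site or
nothing, so the curve sums to at most 1.

**Indices.**

- *log_p / log_adj_p*: under the uniform null, each best site lands in the
  central bin with p₀ = bin_size / window = 1/11.  The one-sided upper tail
  P(X ≥ k | n, p₀) is summed term-by-term in log space from gammaln-based
  log-pmf values, so tails far below the smallest linear double (log-p
  near −1200 occurs already at n = 500) remain finite; this is required
  because the selection threshold, −500 in natural log, sits far below
  linear-underflow territory.  The adjustment is Bonferroni in log space
  (+ ln m for m motifs tested), capped at 0.
- *concentration*: k/n, the fraction of best sites inside the central bin.
- *C-value*: mean curve value over offsets (−100, −80] divided by
  (−120, −100] (strips scale proportionally with bin_size).  The strips are
  half-open with the bin boundary at −100 belonging to the outer strip;
  this is the convention under which a step curve that doubles inside
  ±100 gives exactly 2.0.  0/0 (no sites near the boundary at all) returns
  the neutral sentinel 1.0; a positive numerator over a zero denominator
  returns +inf.  CpG-containing motifs lose scorable sites just outside a
  demethylated bin in bisulfite data, producing C > 1.2.

Motifs with zero passing sites receive neutral indices (log_p 0,
concentration 0, C 1.0) instead of an error: uninformative motifs are a
normal, expected outcome and should stay visible in the per-dataset table.

## TFBM-TF selection

Across datasets, per motif: max concentration, min log_adj_p, mean of the
finite C-values (the +inf sentinel is excluded and logged; the 1.0
0/0-sentinel is included).  Per (motif, TF) pair, the four criteria are
evaluated with strict inequalities: concentration > 0.12 in any dataset;
log_adj_p < −500 in any dataset; average C-value < 1.2; mean expression
over all non-ESC samples > ESC expression.  TFs absent from the expression
table fail the expression criterion (logged).  "Non-ESC samples" is the
global complement of the ESC column — selection is not restricted to the
matched cell type, and the output table carries every intermediate so this
reading is auditable.

## Array validation arm

M = log₂(β/(1−β)) with β clamped to [ε, 1−ε], ε = 10⁻⁶.  Differential
probes satisfy |M_TF − M_mock| ≥ 2 (inclusive, matching the printed "≥");
*demethylated* means M decreased under TF overexpression — overexpressing a
demethylation-promoting TF removes methylation at its targets.

Overrepresentation compares motif match counts (all sites above 0.8 of the
maximum score, both strands — the conventional matchPWM-style floor) in
±5 kb around demethylated probes versus an equal number of uniformly
sampled background probes, excluding the foreground (overlap would dilute
the contrast).  Matches are located once genome-wide per motif and then
assigned to probes by binary search, which makes repeated judgements cheap.
The curve is the per-100-bp-offset-bin difference (foreground − background)
divided by the number of probes; probe pairs whose windows clip a
chromosome end are dropped pairwise so the two sets stay matched.

The activity judgement is a label-swap permutation test: the statistic is
the mean curve value over offset bins within ±500 bp; the null swaps
foreground/background labels independently per probe pair (sign-flip of the
pair's contribution), default 1,000 permutations, positive when the
empirical p (with the +1 correction) is below α = 0.01.  The test is exact
in level by construction; on 200 null resamplings its false-positive rate
sits at the nominal α.

Overlap matrices report 100 × |primary ∩ secondary| / |primary| per TF
pair (asymmetric by definition).  Original-methylation bias compares the
mock-condition M-values of demethylated probes against all probes with a
one-sided Mann–Whitney test, reporting the AUC-normalized statistic; a
demethylation-promoting TF preferentially targets probes that start out
hypermethylated.

## Synthetic fixtures

The generators are pure functions of (spec, seed); reruns are
byte-identical.

*Genome*: uniform base composition with accidental CG dinucleotides
removed, then CpG dinucleotides written at even positions with probability
2 × density (expected count = density × length; the even-slot restriction
prevents overlapping plantings).  Default density 0.04 gives ~8 CpGs per
200-bp bin.

*Methylomes*: per-CpG methylation is beta-binomial (concentration 60 —
real bisulfite data is overdispersed and the exact test should be exercised
against that) around 90% in the ESC-like reference, dropping to 20% in
planted demethylated bins; planted methylated bins are 20% islands in the
reference that rise to 90% in the target.  Depth is Poisson(30) with a
floor of one read.  Default planting: 400 demethylated + 100 methylated
bins (the 4:1 ratio of demethylation to methylation observed in
differentiating cells), sampled at least 6 bins apart — this spacing
guarantees that no planted motif falls inside another planted bin's
±5-bin enrichment window, keeping each region's best site attributable to
its own bin.

*Motifs*: the planted motif is a sharp 12-mer consensus PWM (consensus
probability 0.97) without CpG, written at the centers of 60% of
demethylated bins with ±10 bp jitter.  Decoys alternate between sharp
(effectively zero background matches) and soft (consensus probability 0.6,
scattered background matches), spanning the realistic range of curve
shapes.  Boundary-artifact fixtures plant a CpG-containing motif just
inside the upstream bin boundary (offsets −105…−85).

*Array*: mock M-values are a two-mode mixture (hypermethylated ≈ +3,
hypomethylated ≈ −3); planted probes shift by ΔM = −3 with σ = 0.3
measurement noise, so recovery at the |ΔM| ≥ 2 threshold is near-complete
while null assays produce essentially no calls.  Activity fixtures place
the assay motif within ±300 bp of 80% of foreground probes.

What the fixtures do *not* emulate: chromatin-state or replication-timing
structure, CpG islands and promoter architecture, strand-split CpG calls,
read-level errors and mapping bias, array probe cross-reactivity, and the
lineage structure of a real methylome corpus.  Passing tests therefore
demonstrate the correctness of the statistical machinery and the
recoverability of planted signals at realistic effect sizes and depths —
not performance on real IHEC-scale data, whose headline counts depend on
corpus composition.

## Numerical and design notes

- Fisher tie handling uses a 10⁻⁷ relative slack on the observed table's
  probability; the test-suite oracle applies the same rule in exact integer
  arithmetic.
- The binomial tail is validated against exact integer summation
  (p₀ = 1/11 makes the tail a ratio of integers) for all n ≤ 500;
  agreement is ~10⁻¹² in log space.
- All fixture problem sizes (1 Mb default genome, 240 kb mini preset for
  CLI round-trips, 4,000-probe activity fixture, 50,000-probe recovery
  fixture) were chosen so a full run completes in a few seconds on one
  CPU while keeping every planted effect several standard deviations from
  its decision threshold.
- Known limitations: no region merging of adjacent differential bins; no
  GC-matched backgrounds for enrichment; concentration is defined against
  a fixed central bin rather than a searched best window; selection
  averages expression globally rather than per matched cell type.
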