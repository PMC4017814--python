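# Methods

This note documents the models and procedures implemented in `equitx`, the
assumptions behind them, the tunable parameters and their defaults, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the underlying descriptions leave room.

## Read trimming

Trimming follows the running-sum ("modified Mott") scheme used by common
quality trimmers. A Phred score q maps to an error probability
p = 10^(−q/10); with limit L the per-base increment is L − p, accumulated as
s_i = max(0, s_{i−1} + (L − p_i)). The retained segment ends at the maximum
of s and starts at the beginning of the run of positive sums containing
that maximum; if s never leaves zero the read is discarded. Defaults: limit
0.2, at most 2 ambiguous (N) bases per kept read, minimum retained length
20 bp — the parameter set of the seven-sample equine study this pipeline
reconstructs. Reads are removed, not shortened, when they exceed the
ambiguity limit.

Two points are under-determined by the prose description of the algorithm
and are fixed here:

* **Tie-break.** When several positions attain the running-sum maximum, the
  RIGHTMOST is used, which retains the longest segment among score-equal
  choices.
* **Start rule.** The literal "first positive value" is ambiguous when the
  sum resets to zero between runs; the start is taken within the positive
  run containing the chosen maximum. This guarantees the retained segment's
  score Σ(L − p_i) equals max(s), and the test suite verifies optimality of
  that score against an independent best-substring oracle (prefix sums with
  a running prefix minimum).

Adapter clipping is exact-substring prefix/suffix removal of user-supplied
sequences, longest first (the original adapter list is instrument-specific
and not bundled); poly-N removal is subsumed by quality trimming plus the
N-count filter. Colour-space reads are not emulated — the simulator's reads
are base-space stand-ins, a documented limitation.

## Splice-junction pooling

Introns are extracted from transcript models (for consecutive exons
[a,b), [c,d) the junction is (chrom, donor=b, acceptor=c, strand)),
deduplicated, and pooled by set union — the operation feeding the second
pass of a two-pass alignment design. Junction identity includes strand:
coordinate-identical junctions on opposite strands are distinct, matching
the stranded-transcript framing of the comparison stages. Junction
discovery from spliced alignments is out of scope; the simulator supplies
"discovered" sets. The on-disk raw-juncs dialect is
`chrom TAB left TAB right TAB strand` with left = donor − 1 (0-based last
exonic base upstream) and right = acceptor (0-based first exonic base
downstream). Internally all coordinates are 0-based half-open; conversion
happens only at file boundaries (GTF is read and written 1-based
inclusive). Transcripts without strand are dropped at GTF parse time and
counted, since all downstream comparisons are defined for stranded
transcripts.

## Class codes and the consensus rule

The comparison engine assigns each query transcript one code from the
reduced vocabulary {=, c, j, o, i, x, u} with fixed precedence
`=` > `c` > `j` > `o` > `i` > `x` > `u`:

* `=` — identical intron chain (multi-exon; terminal-exon ends ignored).
  Single-exon pairs instead require reciprocal overlap ≥ 0.8 of both exons
  (configurable; the exact single-exon fuzz of the original comparison tool
  is undocumented).
* `c` — contained: same strand, query span within the reference span, the
  query's intron chain a contiguous sub-chain of the reference's, terminal
  exons overlapping the corresponding reference exons; a single-exon query
  must lie entirely within one reference exon.
* `j` — novel isoform: multi-exon query sharing ≥ 1 intron with the
  reference but neither `=` nor `c`.
* `o` / `x` — generic exonic overlap on the same / opposite strand.
* `i` — query span entirely inside one reference intron (checked regardless
  of strand; precedence places it below all same-strand exonic codes and
  above `x`, a choice fixed here since no precedence among the low codes is
  documented).
* `u` — no applicable relationship. The one span-overlap geometry with no
  code in this vocabulary — a reference entirely inside one intron of the
  query — also falls through to `u`.

Ties among references achieving the same code break deterministically:
most shared introns, then smallest reference span, then lexicographic id.

The consensus assembly keeps a primary-assembler transcript when some
secondary transcript either `=`-matches it or is contained/covered by it
with compatible intron structure (secondary-contained-in-primary, per the
direction of the phrase "contained or covered at least one … transcript";
a flag adds the reverse relation). The two corroborating subsets may
overlap — a terminal-jittered `=` match is also contained-compatible — so
the report exposes both subset sizes and their union, which is the same
arithmetic structure as the published counts (10,518 chain matches plus
18,152 containments giving a 28,230-transcript union).

## Quantification and enrichment

Counting consumes per-read assignment records (sample, gene-or-none,
n_hits): reads with n_hits ≠ 1 are excluded from both counts and totals
(the unique-alignment filter); uniquely aligned reads without a gene count
toward totals only. RPKM = 10⁹ · c / (N · L) with L the exon-union length
of the gene and N the per-sample total of uniquely aligned reads —
assigned or not. (Whether unassigned reads belong in the denominator is
genuinely ambiguous in the source description; including them is this
package's choice and the totals row of the TSV format makes the convention
explicit.)

A gene is enriched in a sample when RPKM > 5 there and RPKM > 10 × the mean
RPKM over the other samples, zeros included in the mean, both inequalities
strict as printed. With fold f over n samples, two enriched samples for one
gene would each need to exceed (f/(n−1)) × the other; for f/(n−1) > 1 this
is impossible, so with f = 10, n = 7 enrichment is mutually exclusive — the
test suite searches 10⁶ randomized expression rows for counterexamples and
finds none, and the proof explains why.

Report arithmetic: average coverage = aligned reads × mean read length /
genome size, rounded half-away-from-zero to 2 decimals; percentages rounded
half-away-from-zero to integers. The bundled seven-sample read-statistics
table (genome 2,428,790,173 bp, mean trimmed read length 47 bp) reproduces
the published derived columns exactly.

## Clustering and bootstrap support

Samples are clustered by complete linkage (inter-cluster distance = maximum
pairwise distance) on Euclidean distances between expression columns. The
agglomeration is implemented directly rather than via a library call
because the contract fixes a deterministic tie-break — among equal-distance
merges, the smallest lexicographic merged leaf set wins — so identical
inputs yield identical trees; on tie-free random inputs the tree is
verified against an independent library implementation. Clustering operates
on raw RPKM values by default (matching the source procedure); a log2(x+1)
transform sits behind a flag.

BP support: genes are resampled with replacement (default n = 1000) and
bp(clade) is the fraction of bootstrap trees containing the clade's exact
leaf set (no partial credit). AU support follows the multiscale-bootstrap
probit fit: for scales r = 0.5, 0.6, …, 1.4 (the conventional defaults)
resample size round(r·n_genes) gives bp_r; scales with 0 < bp_r < 1 enter
an unweighted least-squares fit of z_r = Φ⁻¹(1 − bp_r) to v√r + c/√r, and
AU = 1 − Φ(v − c), clipped to [0, 1]. Clades with bp_r ∈ {0, 1} at every
scale (e.g. exact-duplicate columns), or with fewer than two usable scales,
cannot be fitted: they keep AU = BP at scale 1 and are flagged degenerate.
BP is reported from the scale closest to 1. The newick export annotates
internal nodes "AU/BP" as integer percentages.

## The synthetic-data generator

The simulator stands in for the study's raw inputs (deposited reads and
the equine reference) and produces: annotations of non-overlapping gene
loci; an assembler-like transcript pair with planted class relationships;
negative-binomial count matrices with planted enriched genes; FASTQ reads
with a known intended retained interval. Every generator is a pure
function of (config, seed) with one RNG stream per generator split from
the master seed by a fixed label, so outputs are byte-reproducible and
adding a generator never perturbs the others.

Defaults mirror the study design where it states values: 7 samples, 50 bp
reads, trim limit 0.2; elsewhere they are fixed once at values realistic
for bulk RNA-seq — exon counts 2–6, exon lengths 100–400 bp, introns
0.2–2 kbp, intergenic gaps ≥ 1 kbp (which also guarantees planted
relationships cannot leak onto neighbouring loci), negative-binomial means
20–200 with dispersion 0.1 (variance m + φm²; Poisson at φ = 0), 5 %
enriched genes at fold 50, 10 % unassigned reads in the totals, quality
profile Q30 cores with Q2 tails of 0–15 bp and 1 % N injection.

Class planting is verified at generation time: each planted secondary
transcript is re-classified against the primary set and generation fails
loudly on any label impurity, so truth tables are exact. Reads are built so
the trimmer's answer is analytically known (core scores L − p > 0, tail
scores < 0, hence the retained interval is exactly the core); Ns are
injected at core quality so they test only the ambiguity filter.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: sequence content and alignment (no error model
beyond quality values and Ns, no mapping ambiguity beyond the declared
n_hits), colour-space chemistry, fragment-level coverage biases,
correlated gene expression, or biological replicate structure. Recovery
rates on simulated data are upper bounds on real-data behaviour.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data at
desk scale, chosen so the full suite completes in seconds: classifier
oracle cross-checks use 100 instances of 25-gene annotations; trimming
optimality uses 10⁴ random reads of length ≤ 60; enrichment recall uses
300–3,000 planted-truth genes across three seeds; mutual exclusivity
searches 10⁶ randomized rows; bootstrap checks use 1,000 replicates (300
per scale for AU) on 5–7 samples × 50–80 genes.

## Known limitations

* The enrichment recall of the fold-10 rule against planted fold-20
  enrichment under negative-binomial noise with dispersion 0.2 is ≈ 88 %,
  not higher: the enriched draw has CV ≈ √0.2 ≈ 0.45, so a non-trivial
  fraction falls below 10 × the mean of the other samples. This is a
  property of the statistic, not an implementation artefact; recall is
  100 % in the noise-free (dispersion 0, fold 50) setting.
* Headline counts of the original study (consensus size 28,230, 8,763
  novel isoforms, 507 exact matches, per-tissue enrichment counts) depend
  on its full-scale external data and are out of reach at desk scale; the
  pipeline reproduces the *procedures* and the report arithmetic, not
  those magnitudes.
* Single-exon `=` matching uses a 0.8 reciprocal-overlap heuristic; other
  fuzz conventions exist and the threshold is exposed in the API.
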