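# Methods

## The inference problem

A fragmented male genome assembly contains scaffolds from six autosome
pairs, the X and the Y (2n = 14). Three independent evidence streams
identify which scaffolds are sex-linked:

1. **Copy number via sexed coverage.** Map reads from one male and one
   female to the male assembly. Expected per-scaffold mean depth, with
   autosomal depth *c*: male — *c* on autosomes, *c*/2 on X and Y (one
   copy each); female — *c* on autosomes and X (two X copies at half
   male per-copy depth each), ~0 on Y. The normalized female:male
   ratio (AD-ratio) therefore concentrates at 1, 2 and 0 for
   autosomal, X and Y scaffolds.
2. **Homology.** Align scaffolds to a chromosome-level reference of a
   related species and assign each to its dominant chromosome.
3. **Marker genes.** Known Y genes with diverged X/autosomal homologs
   pin individual scaffolds to the Y even where the reference has no
   usable Y sequence.

The package computes each stream, cross-validates them, and emits a
consensus per-scaffold assignment.

## AD-ratio stage

Raw ratio F/M is normalized by factor *k* so autosomes centre at 1.

* `median` mode (default): *k* = 1 / (length-weighted lower median of
  raw ratios over scaffolds with male depth ≥ `min_male_depth`).
  Robust: sex-linked sequence is a small minority of genome length, so
  the weighted median is an autosomal scaffold. The weighted median is
  the smallest ratio whose cumulative length reaches half the total.
* `total` mode: *k* = Σ M·L / Σ F·L, the aligned-base (library-size)
  ratio. Provided for comparison; both factors are recorded in the QC
  output because the upstream normalization used on real data is a
  choice, not a given.

Bands follow their printed semantics exactly: open intervals for
autosome (0.7, 1.3) and X (1.7, 2.3), closed upper bound for Y
(r ≤ 0.3), so a ratio equal to 0.7, 1.3, 1.7 or 2.3 is unassigned.
`high_confidence_y` (r ≤ 0.01) is a flag on the Y class, not a separate
class: 0.3 is the decision rule, 0.01 an annotation of near-zero female
coverage. Scaffolds with male depth below `min_male_depth` (default
1×) get an undefined ratio and are reported as unassigned rather than
risking a division blow-up; the classifier never invents a class for
them.

The histogram of AD-ratios is length-weighted into half-open
0.025-wide bins (ratios at a decimal bin edge land in the upper bin; a
1e-9 quotient nudge absorbs binary-float representation error) with an
overflow bin at `range_max` (default 4). Bin totals always sum to the
total length of defined-ratio scaffolds.

## Anchoring stage

Parsers accept PAF (0-based half-open, taken as-is),
`show-coords -T` and BLAST outfmt 6 (both 1-based inclusive, possibly
reverse-ordered on the minus strand; normalized to 0-based half-open
with start < end — strand is irrelevant to occupancy). Per scaffold
and chromosome, query intervals are merged (union of half-open
intervals, adjacent intervals coalesced) before summing, so overlapping
local alignments from repeats are not double-counted.

Assignment: with merged bp B_c per chromosome and T = Σ B_c, assign
argmax B_c iff T > 0, B_best/T ≥ `dominance_min` (default 0.5; exact
ties are never assigned) and T/length ≥ `coverage_min` (default 0.05).
The three thresholds are surrogates for an undocumented filtering step;
they are deliberately transparent and exposed on the CLI. Failure
reasons (NO_HITS / NO_DOMINANT / LOW_COVERAGE) are recorded per
scaffold.

## Marker stage

Hits above `evalue_max` (default 1e-10) are discarded first. Per gene,
scaffolds are ranked by summed bitscore of surviving hits — bitscore
rather than e-value because it does not depend on database size, and
summing rewards consistent multi-exon support. The gene is placed only
when the best scaffold's score is ≥ `ambiguity_margin` (default 1.2)
times the runner-up's; multi-copy genes whose partial hits tie across
scaffolds come out UNPLACED_AMBIGUOUS, reproducing the classic ATRY
behaviour qualitatively (no numeric criterion exists for it; 1.2 is
this package's choice).

Confirmation requires (a) ≥ 1 placed Y gene, (b) AD-ratio ≤ `y_max`
(0.3 — the decision rule, not the observed 0.01), and (c) the
supporting gene's homolog *placed* on a different scaffold. The
homolog test uses the homolog's own placement under the same algorithm,
not raw hits, so one weak spurious homolog hit cannot veto a
confirmation; conversely "the homolog must be absent" is interpreted as
absence-of-placement, the defensible reading of an ambiguous rule.
Scaffolds the coverage classifier called Y but that carry no marker
gene are reported with reason NO_GENES — genome-scale putative-Y
sequence legitimately exceeds marker-confirmed sequence.

## Reconciliation

Agreement is computed at the autosome/X/Y group level because coverage
cannot distinguish among autosomes; chrX → X, chrY → Y, every other
chromosome → autosome. All accounting is length-weighted and
partitions the genome into agree / conflict / one-method-unassigned /
both-unassigned (asserted on every run). Both-unassigned is its own
category: it is excluded from the agreement numerator and included in
the denominator. Consensus precedence: marker-confirmed Y > agreement
> homology-only > coverage-only (autosome-group scaffolds stay
`autosome_unplaced`; coverage cannot name an autosome) > conflict
(left unassigned). Marker-confirmed Y overrides homology because
related-species references typically carry almost no Y sequence.

## The synthetic-data generator

The generator emulates the statistical structure of the real inputs at
toy scale with full truth labels; defaults are the study conditions.

* **Genome**: ~98 Mb; six autosomes totalling 95 Mb with sizes
  decreasing ~2:1, X 2.6 Mb, Y 0.3 Mb — the ~95 / 2.6 / 0.3 length
  split of the motivating 3.3 Gb genome, at 1/33 scale. Scaffold sizes
  are lognormal (median 80 kb, log-sd 0.8, minimum 10 kb), giving
  ~900 scaffolds, each chromosome exactly tiled.
* **Depths**: mean autosomal depth 55× in both sexes (the effective
  coverage regime of a deduplicated linked-read run). Per-scaffold
  depth is Gamma — strictly positive and right-skewed like real
  coverage — with total CV `depth_cv` = 0.10, decomposed as a
  scaffold-intrinsic multiplicative bias shared by both samples
  (`depth_shared_frac` = 0.8 of the variance) times an independent
  per-sample residual. The shared component models mappability/GC
  bias, which follows the sequence rather than the library and hence
  cancels in the female:male ratio; this is precisely why per-scaffold
  depth *ratios* are far tighter than per-scaffold depths and why the
  AD-ratio method works at all. With these defaults the residual ratio
  CV is ~0.06, placing ≳99.9% of autosomal length inside the (0.7,
  1.3) band while each sample's marginal depth CV remains 0.10. No
  per-scaffold dispersion is reported for the real data; these values
  are plausible, not fitted.
* **Female Y background** 0.02: mismapping from X/Y-homologous
  regions leaves observed Y ratios small but nonzero (~0.04 after
  normalization), consistent with confident Y calls sitting well below
  the 0.3 rule.
* **Alignments**: a scaffold receives 1–3 non-overlapping blocks on
  its true chromosome jointly covering 55–95% of its length with
  probability 1 − `aln_miss_prob` (default 0.05, the no-homology
  fraction), and an extra 3–18% block on a random wrong chromosome
  with probability `aln_chimera_prob` (default 0.05). Coordinates are
  0-based half-open.
* **Markers**: 20 real marsupial/therian Y-gene names with their
  homologs (SRY/SOX3, ATRY/ATRX, …). Unambiguous genes get one strong
  hit (e ≤ 1e-20) on a Y scaffold; with probability
  `y_gene_ambiguous_frac` (0.05) a gene instead scatters 2–4 partial
  hits with bitscores within 20% across scaffolds. Homologs land on X
  scaffolds (X-borne pairs) or autosomes.
* **Randomness**: one seed; each stage draws from a named substream
  (SeedSequence of (seed, crc32(stage))), so outputs are byte-identical
  per seed and stable regardless of which stages run.

What the generator does **not** model: read-level noise, GC-dependence
as an explicit covariate, assembly errors/chimeric scaffolds in the
depth signal, linked-read barcode structure, paralogy between Y genes
beyond the ambiguous-hit mechanism, or reference-genome divergence
beyond uniform alignment identity. Passing tests therefore demonstrate
correctness of the inference logic under the stated statistical
assumptions, not robustness to every artefact of real assemblies.

## Numerical and degenerate-input choices

* Weighted median: lower median (smallest value reaching half the
  cumulative weight); deterministic under ties.
* Histogram binning uses a 1e-9 quotient nudge so decimal edge values
  land in the upper (half-open) bin despite float representation.
* Dominance ties: exact equality of the top two merged-bp values is
  NO_DOMINANT regardless of thresholds; chromosome maps are sorted so
  results are order-invariant.
* Empty tables, disjoint scaffold sets, all-male-depth-below-floor and
  missing Y scaffolds raise typed errors (`ConfigError` for parameter
  problems, `InputError` for data problems) listing offenders.
* The pipeline's stage runner tags failures with the stage name and
  exits 2 (validation) / 3 (stage failure) from the CLI.

## Problem sizes

The test suite and the acceptance script run the default ~98 Mb /
~900-scaffold genome, 20 replicate seeds for recovery and confirmation
properties, and 1,000 random interval sets against the per-base merge
oracle; the full suite completes in well under a minute. These sizes
give binomial error bars comfortably inside the asserted margins (e.g.
the 99% recovery assertions are ~5 standard errors from the measured
means).

## Known limitations

* The coverage method cannot distinguish autosomes from each other,
  X-autosome translocations, or pseudoautosomal regions (which sit at
  intermediate ratios and are left unassigned).
* Anchoring thresholds are declared surrogates for an undocumented
  filtering criterion; on real cross-species data the dominance and
  coverage floors may need retuning.
* Confirmation treats "homolog absent" as "homolog placed elsewhere or
  unplaced"; a homolog that genuinely co-resides on a fused scaffold
  is indistinguishable from a chimeric assembly join.
* Single male/female samples only; no replicate-aware variance model.
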