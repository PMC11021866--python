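# Methods

## The index statistic and its null

At a biallelic site with per-pool read counts, the pool index is
`alt/(ref+alt)` and the scan statistic is `Δ = index_large − index_small`.
Under a 1:1 pseudo-testcross (marker heterozygous in one parent,
homozygous-reference in the other) a pool of n lines has true alternate
allele frequency `p = (# heterozygous lines)/(2n)`, with mean 0.25 and
variance `1/(16n)`; the observed index adds binomial read noise with
variance `E[p(1−p)]/d` at depth d. Δ therefore has mean 0 at unlinked loci
and a depth- and design-dependent spread — there is no useful closed form
once the site filters are applied, which is why the envelope is simulated.

### Site filters

A site is dropped iff (both pool indices < `min_index`, default 0.3) OR
(both pool depths < `min_depth`, default 7) OR (either index missing, i.e.
zero depth). The clauses are deliberately "both-sided": a site where only
the small pool is reference-like is exactly the signal QTL-seq looks for
and must survive. Filtering is idempotent and order-free.

### Simulated confidence envelope

For each nominal per-pool depth d on a geometric grid (ratio √2, spanning
the observed depths, floor 4): draw two pools of `pool_size` progeny under
the no-QTL segregation model, draw each pool's realized depth from
Poisson(d), sample alternate reads binomially at the pool's true frequency,
**apply the same site filters**, and take empirical (1±level)/2 quantiles
of Δ (default 10,000 draws/depth; fewer than 1,000 is rejected). Bounds at
arbitrary depth are interpolated linearly in 1/d (read variance is linear
in 1/d) and clamped at the grid ends.

Two details matter for calibration and were validated empirically on a
QTL-free synthetic genome (~52,000 filtered sites; site-level exceedance
4.5–5.0% across seeds):

* the envelope must be built on the *filtered* null distribution — the
  index filter removes central mass, so unfiltered quantiles are ~15% too
  narrow for surviving sites;
* depth variability must be inside the simulation. The index filter
  interacts with unequal depth pairs (the shallower pool's index is
  noisier), so surviving sites have heavier Δ tails than fixed balanced
  depth draws produce. Each site's envelope is looked up at the mean of its
  two pool depths, matching the simulation's Poisson conditioning.

For real libraries whose depth is overdispersed relative to Poisson the
envelope will be slightly narrow; a negative-binomial option was left out
deliberately (no overdispersion estimate is available from two pools at a
single site) and is a known limitation.

### Windows, significance and intervals

Windows of `window` bp (default 1 Mb) step every `step` bp (default 1 kb);
starts are 0, step, 2·step, … while `start + window ≤ L`, plus one final
truncated window when `L − window` is not a multiple of the step. Windows
are half-open `[start, end)`; the statistic is the unweighted mean Δ of the
sites inside (no kernel smoothing). Empty windows carry NaN and are never
significant. A window is significant when its mean lies outside the
envelope evaluated at the window's aggregate depth — harmonic mean of site
depths by default (`depth_stat="mean"` for arithmetic), with an optional
absolute-|Δ| floor (default 0, i.e. off). Comparing a window *mean* against
a *site-level* envelope is conservative by construction: read noise
averages over the window's sites while the envelope does not, so false
windows are rare and intervals only form around real linkage. Overlapping
or abutting significant windows merge into maximal intervals (no gap
tolerance); interval size is `(end − start)/1e6` Mb. SNP, InDel and
combined scans differ only in which sites enter.

## The synthetic cross

The generator emulates the study design end to end so that every stage is
testable without the deposited reads.

* **Design defaults** (the study conditions): 284 F1 lines, pools of 30,
  pooled depth 40× (the study's pools realized 55–82×; 40× is the
  recovery-experiment condition), parent depth 14×, SNP fraction 0.81 of
  markers (the called-variant ratio), segregation 1:1 with 1:2:1
  configurable. Default genome: 3 × 30 Mb chromosomes at 150 markers/Mb —
  deliberately scaled down from the ~350 Mb genome and ~2,400 markers/Mb of
  the real data; the package's statistical properties are density-robust
  (checked at 300/Mb) and these sizes keep a 20-replicate experiment under
  a minute.
* **Linkage**: the QTL-bearing chromosome is a single maternal linkage
  group — progeny inherit the informative parent's haplotype as a Markov
  chain along the marker positions with Haldane recombination at
  `cm_per_mb` (default 3 cM/Mb, a typical woody-perennial map density), and
  every alternate allele rides the divergent haplotype (coupling phase).
  This is the configuration under which the raw alternate-read fraction is
  informative; with random phases half the markers would sit in repulsion
  and window means would cancel. Real pseudo-testcross analyses achieve the
  same thing by building per-parent marker sets. All other chromosomes are
  unlinked background (independent marker draws per line), which makes
  null-calibration measurements effectively independent across sites.
* **Phenotype** (SD units): `effect × (dosage − E[dosage]) + polygenic +
  environment`, with the polygenic variance set to `h2 − effect²·Var(dosage)`
  (rejected if negative — a 1-SD effect under 1:1 already explains 25% of
  variance) and environmental variance `1 − h2`. Measurement-scale traits
  (single fruit weight g, fruit length/diameter mm) are affine images of
  the standardized phenotype anchored to the published F1 moments, with
  independent noise on length and diameter; fruit shape index =
  length/diameter.
* **Reads**: per site per sample, depth ~ Poisson(mean), alternate reads ~
  Binomial(depth, p), with an optional symmetric error rate (default 0 so
  analytic expectations stay exact). Parents are sampled from their known
  genotypes.
* **Not emulated**: FASTQ-level errors and quality profiles, alignment and
  duplicate artifacts, overdispersed depth, multi-QTL epistasis,
  recombination-map heterogeneity, the right-skew of the real single-fruit
  weight distribution (noise is Gaussian). Passing tests therefore certify
  the statistics downstream of a called VCF, not variant calling itself.

Pool selection ranks lines by phenotype with a deterministic id tie-break:
lines are ordered by (phenotype, id) and the two tails taken, so equal
phenotypes still give disjoint pools. The file-based screen
(`screen_extremes`) ranks on single fruit weight, with fruit length and
diameter available as auxiliary tail-consistency filters behind a slack
quantile (disabled by default — no published rule exists for them).

## Measured guarantees

The test suite and `scripts/acceptance.py` measure (rather than assume):
null site-level exceedance 4.5–5.0% at the 95% envelope over ≥50,000
filtered sites; planted-QTL interval coverage 100% over 20 replicates at
the default design; peak-window localization within 2 Mb in ~85–100% of
replicates. Localization is limited by the realized recombinations among
the 60 pooled lines — the Δ profile is a plateau whose argmax drifts — and
does not improve systematically with marker density or depth; the wide
intervals this produces match the behavior of real 30-line-pool BSA scans.

## Annotation

Gene models are single-transcript (multiple overlapping genes are allowed;
the most severe consequence is reported). Locations follow the precedence
exonic > splicing > intronic > upstream/downstream > intergenic, with
`flank` = 1,000 bp and `splice_window` = 2 bp (the conventional defaults of
ANNOVAR-class tools; the source data do not state the distances). A
within-gene position in an exon but outside the CDS falls through to
intronic — the location vocabulary has no UTR category and the bundled gene
models have none. Coding consequences are computed codon-locally in
spliced-mRNA coordinates (strand-aware); in-frame indels compare local stop
*positions*, so a deletion that destroys the terminal stop while creating
an earlier one is a stop gain, not a loss. The classifier is checked
against an independent brute-force oracle (edit the chromosome, shift the
gene model, re-translate both complete proteins) on ≥1,000 randomized
coding variants per run; a stated-reference mismatch against the genome is
a hard error, as it always indicates a coordinate bug. Multi-allelic VCF
records are split into biallelic rows on input. Transitions are A↔G and
C↔T; the Ts/Tv ratio is reported to 3 decimals with an infinity sentinel
when no transversions exist.

## Candidate genes

Tier 1: stop gain/loss, frameshift indels. Tier 2: nonsynonymous,
splice-site. Tier 3 (default on): upstream/downstream variants — published
candidate tables are dominated by them in practice, so they are included
with the tier label kept visible rather than silently promoted. Records
deduplicate by (gene, variant) and sort by tier then position; screening
runs genome-wide or interval-restricted (the latter is always a subset).
Gene descriptions come from an optional id→text sidecar; no live lookups.

## Reporting conventions

Reported tables round half-up (ties away from zero) at 2 decimals, with a
pre-snap at 10 decimals so binary-float noise cannot flip a true tie
(13.595 → 13.60). CV is undefined at zero mean and raises; kurtosis is
excess kurtosis and skewness the third-moment coefficient, both
bias-corrected; degenerate constant samples yield NaN shape statistics. An
interpretive `Ta = 100 − |R_Hm|` column is available but carries no
analytical weight (its defining formula is not standard). BED output is
0-based half-open; VCF/GFF3 and all internal coordinates are 1-based
inclusive. Pipeline outputs are byte-deterministic for a fixed seed and
config (fixed float formats, sorted JSON keys, no timestamps).
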