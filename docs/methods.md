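# Methods notes

## Scope and data model

`ampliqc` evaluates a PCR-amplicon target-enrichment platform from its
*post-mapping* artefacts: per-base depth tables (samtools-depth style),
nanowell qPCR reaction records (Cq, end-point fluorescence), and variant
calls with per-allele depths. Read-level processing — mapping, quality
recalibration, duplicate removal, variant calling — is upstream and out
of scope; the duplicate fraction is consumed as a given per-sample
number, and the simulator emits depth and calls directly rather than
reads.

Coordinates are 0-based half-open internally (BED-native); depth-table
positions and variant positions are 1-based, matching the two standards
touched. Positions absent from a depth table read as depth 0 inside
declared targets, because samtools depth omits zero rows. All coverage
statistics run over the *base union* of the supplied targets, so bases
under two tiling amplicons count once; attribution of coverage to a
single tiling assay is impossible, which is also why tiling assays are
excluded from the Cq–coverage association.

## Metric conventions

- Per-base coverage SD is a **population** SD (the target bases are a
  census); across-sample summaries (metrics-table columns, correlation
  pairs) use the **sample** SD. At the bundled dataset's sizes the
  distinction is below print precision, but the semantics differ.
- Capture success uses strict inequalities as stated: mean amplicon
  depth **> 20** in **more than** 80% of samples. Both thresholds are
  CLI flags.
- Spearman correlation uses average ranks for ties (the standard
  convention) and is computed on raw depths; because ranks are invariant
  to positive per-sample scaling, normalized depths give the identical
  matrix, which is asserted as a property test. A zero-variance track
  makes the pair undefined; it is reported missing and excluded (with a
  count) from the mean/SD summary.
- Reaction dropout is Cq **strictly greater than** 29. Dropout wells are
  excluded from the Cq–coverage regression (the sentinel Cq 40 would
  dominate an otherwise weak linear fit) but retained in the dropout
  rate itself. The regression pools all (sample, assay) pairs; per-chip
  fits are not implemented.
- The 2×2 chi-squared has 1 df and no continuity correction; counts at
  these sizes make the correction immaterial, and a flag marks results
  with any expected cell < 1.

## Deletion calling

A homozygous deletion is called for a (sample, assay) pair only when
both evidence arms agree:

1. qPCR: every replicate well shows no amplification — Cq ≥ `cq_max`
   (default 35) **or** end-point fluorescence < `fluor_min` (default
   100 RFU);
2. sequencing: mean depth over the amplicon < `cov_max` (default 2×).

`cq_max` defaults to 35 rather than the sentinel 40 so that
near-sentinel failed reactions also qualify; in the bundled dataset the
amplified reactions sit at Cq ≤ 23.7 and the deleted ones at 40.0, so
the default lies safely in the wide gap between the regimes. Discordant
evidence (one arm only) is flagged for review, never called. Large
*heterozygous* deletions are out of reach by construction — the
remaining allele amplifies normally — and complex rearrangements whose
variant allele cannot amplify surface as `not_detected`; neither is
specially recognized.

## Rediscovery classification

`classify_mutation` is a total, ordered function: large deletions are
judged by the dual-evidence call (qPCR evidence is mandatory for that
class); otherwise site depth below `min_callable_depth` (default 20) is
`low_coverage`; otherwise alt-supporting reads validate and their
absence is `not_detected`. `low_coverage` is **not** counted as
validated even when alt reads are visible — no reliable call could have
been made — which is what makes the bundled dataset's rate 23/25 rather
than 24/25.

## Replicate concordance

The site universe is every (chrom, pos, ref, alt) key called in at
least one replicate with callable depth in that replicate. Site
identity includes the alleles: one position with two different alts is
two sites, not one concordant one. Discordant sites are triaged by an
ordered, exclusive rule — coverage, then repeat context, then
allelic-ratio drift — so each site gets exactly one category and
replicate order cannot change it. The repeat definition is fixed at
homopolymer ≥ 5 bp or dinucleotide repeat ≥ 4 units (both
configurable); the scanner takes a short context string with the site
at a stated index, so no reference genome is needed.

## The simulator

The generator's statistical skeleton, and what each parameter controls:

| parameter | default | role |
|---|---|---|
| `n_genes` × `amplicons_per_gene` | 16 × 24 | panel size (~384 assays, near the bundled study's 371–376) |
| `amplicon_length_bounds`, `amplicon_length_mean` | (319, 745), 441 bp | truncated log-normal length sampler |
| `tiling_fraction` | 0.15 | fraction of amplicons overlapping a neighbour (~30% of their length) in a shared tiling group |
| `sample_depth_scale`, `sample_scale_sd` | 537×, 0.28 | log-normal per-sample library size (the study's mean amplicon coverage and its coefficient of variation) |
| `amplicon_effect_sd` | 0.6 | log-SD of the per-amplicon efficiency **shared across samples** — the driver of inter-sample coverage correlation |
| `noise_sd` | 0.25 | per-sample×amplicon log-normal noise — the degrader of that correlation |
| `duplicate_rate` | 0.15 | binomial duplicate draw in the metrics table |
| `dropout_rate` | 0.0116 | independent fraction of wells pushed into Cq (29, 40] |
| `cq_intercept`, `cq_slope`, `cq_noise_sd` | 21, 1.5, 0.8 | Cq = intercept − slope·log2(efficiency × relative sample scale) + noise |
| `vaf_het`, `vaf_hom` | 0.5, 0.98 | binomial allele-fraction targets for injected variants |
| `stray_depth` | 0.4 | Poisson stray-read depth over deleted amplicons |

Amplicon lengths are drawn from a log-normal truncated to the printed
range, with the log-spread pinned by treating that range as a ~4σ
window and the location solved so the truncated mean equals the
configured mean — the three summaries (min, mean, max) are the only
published constraints. Depth tapers linearly over one read length
(150 bp) at each amplicon end — reads must start inside the amplicon —
and is flat in the interior; this is the simplest shape consistent with
150 bp paired-end sequencing of 319–745 bp amplicons. With the defaults
the implied pairwise Spearman is ≈ σ²ₐ/(σ²ₐ+σ²ₙ) ≈ 0.85–0.9 on the log
scale, matching the reproducibility a good capture shows.

The Cq model uses the sample scale *relative* to `sample_depth_scale`,
so `cq_intercept` is the grand-mean Cq (≈ 21, the amplified regime of
the bundled reactions) rather than an offset at one unit of absolute
depth. The Cq noise SD is a free parameter: the observed weak
Cq–coverage association does not identify a unique noise decomposition,
so no value is fitted.

Deletions are specified per (sample, assay) and **closed over tiling
groups**: a genomic deletion removes the template of every overlapping
assay, so deleting one member of a tiling group deletes its partners
for that sample, in both the depth and the qPCR stages. The truth set
records the closed set, which is what recovery tests compare against.

Randomness uses one global seed with fixed per-stage sub-streams
(panel, depth, qPCR, variants, metrics), so identical parameters give
byte-identical outputs and any stage can be regenerated independently.

**What the simulator does not model:** read-level error, mapping
artefacts, GC bias, library-prep effects, melt curves, and real repeat
landscapes (repeat contexts are supplied as strings). Passing recovery
tests therefore demonstrates that the *metrics* behave as specified on
data with the assumed structure — not that the platform itself would
achieve those numbers on real libraries; the bundled dataset covers the
real-data surface.

## Problem sizes in the test suite

The suite runs simulations at reduced scale chosen to keep Monte-Carlo
error well inside the asserted tolerances: dropout recovery uses 10 000
wells (3 binomial SE ≈ 0.5 percentage points), allele-fraction checks
use 2 000 sites at 500× (half-normal SE bounds), deletion recovery uses
20 samples × 50 assays, and the correlation-monotonicity check averages
20 replicates per efficiency-spread level. Full-study-scale defaults
(384 assays × 24 samples) remain the package defaults for interactive
use.

## Known limitations

- The deletion rule needs qPCR data; sequencing-only deletion calling
  is deliberately unsupported (single-arm evidence is ambiguous).
- The discordance triage takes its repeat context as an input string;
  callers integrating a reference genome must extract the context
  themselves.
- The bundled dataset's correlation matrix is stored at the printed
  3-decimal precision; summaries inherit that granularity.
- Variant-call site identity is biallelic after decomposition; phased
  or symbolic VCF records are rejected upstream.
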