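# Methods

## Scope and model

`exrna-perf` is the statistics layer of a total-RNA-seq performance
assessment for low-input biofluid and EV samples. It consumes gene-by-sample
integer count tables with a feature annotation (endogenous vs ERCC/Sequin
spike, biotype, chromosome class, region class) and per-sample metadata
(biofluid, replicate structure, input volume, spike dilution). It never
touches reads or alignments: read-category and region tallies, where used,
are accepted as pre-tagged tables from upstream tools, and quantification is
the caller's responsibility (counts must already be integers; any rounding of
estimated counts happens upstream).

## Titration trueness

The titration design dilutes the two spike panels in opposing five-point
geometric series — Sequin 1/15 000, 1/21 277, 1/30 000, 1/42 433, 1/60 000
and ERCC 1/100 000, 1/70 721, 1/50 000, 1/35 461, 1/25 000 — so each step is
a factor ≈ 1.414 and the extreme pair a factor 4 for both mixes. Spike
concentration is taken proportional to the dilution factor (one stock per
mix), so the designed log₂ fold change between samples is `log2(d_a/d_b)`,
antisymmetric and telescoping along the series.

Choices that were genuinely open:

* **Normalisation.** Observed fold changes are computed after equal-depth
  subsampling of whole libraries (matching a processing chain that starts
  from a fixed number of reads), not after spike-sum scaling.
* **Zero-count spikes** are excluded from fold changes rather than
  pseudocounted — a pseudocount would fabricate a fold change exactly where
  the data say nothing — but they are reported in a separate table so nothing
  is silently dropped.
* **Regression** is ordinary least squares of observed on expected *with
  intercept* (statsmodels OLS); adjusted R² uses the standard n−2 correction.
* **Sample pairing.** Which pairs populate the regression is not dictated by
  the design; the default is every sample against the mid-dilution reference
  (4 pairs × 2 mixes), with `adjacent` and `extreme` modes exposed. Pooling
  is per mix; a pooled-over-mixes regression is not asserted as canonical.
* Spikes whose mean pair count falls below `trueness_min_count` (default 10)
  are flagged, not removed: low-count fold changes are reported but marked
  unreliable.

## Relative concentration

ρ = (Σ endogenous counts / Σ ERCC counts) × dilution / volume_ml. The
endogenous sum includes mitochondrial and rRNA genes (no exclusions beyond
the spikes); the volume is the *original* biofluid volume (e.g. 45 000 µl for
EVs concentrated from 45 ml urine, 200 µl for whole urine), which is what
makes per-ml concentrations comparable across preparations. Spike amount is
represented by the dilution factor alone — absolute molarity is out of scope,
so ρ is in arbitrary units, meaningful only relative to samples sharing the
spike stock. Zero spike reads raise an error (failed spike recovery) rather
than yielding an infinite ratio. The estimator is depth-invariant in
expectation because numerator and denominator scale together.

## Replicate precision and the count cutoff

Ratios are **absolute** log₂ ratios: the cumulative-distribution view starts
at 0 and an area statistic is only meaningful for a non-negative variable.
The ALC is implemented as the exact area left of the step CDF, which equals
the arithmetic mean of the ratios (verified against an independent
step-integration oracle to 1e−12). The common verbal reading — "half of the
genes replicate within this fold change" — describes a **median**; mean and
median coincide only for symmetric ratio distributions, so both are emitted
(`alc` and `median_ratio`) and the ambiguity is documented rather than
resolved.

A gene enters the pair statistics when its count reaches the detection cutoff
in **both** replicates — the operational meaning of "reproducibly detected".
Pearson correlation is computed on log₂ counts of the retained genes.

Single positives (count > 0 in exactly one replicate) are treated as noise.
For each candidate cutoff c the removed fraction is the share of single
positives with nonzero count < c; the chosen cutoff is the smallest c
reaching the removal target (default 0.95). With no single positives the
report is flagged and the smallest candidate returned. The double-positive
column reports the share of double positives a both-replicates rule at c
would drop, for context.

**Subsampling** draws exactly `depth` reads per sample without replacement
(multivariate hypergeometric across features, numpy's `marginals` method):
column sums equal the depth exactly, expectations are proportional to input
composition, and per-sample generators are spawned from one seed sequence so
results are bit-reproducible.

## Composition and overlap

Each fraction family (read category, chromosome class, region, biotype) is
normalised by its own total and sums to 1 ± 1e−9; an all-zero family is
reported as *absent*, never as 0/0. Biotype fractions are computed over
exonic endogenous counts (falling back to all endogenous counts when the
annotation carries no exonic tags). Top-N consumption excludes spikes and
breaks count ties by feature id for determinism. Gene-body percentile
coverage treats each base as a uniform interval of the rescaled gene body and
integrates the step function over 100 equal-width bins (exact for any input
length, identity for length-100 input), then normalises to mean 1; an
all-zero vector returns zeros with a logged flag. Overlap reports shared and
unique detected-gene counts, the Jaccard index (0 with a flag when both sets
are empty), and the counts of each side's unique genes — on synthetic data,
as in real comparisons of EVs with their parent fluid, those unique genes sit
in the low-abundance tail.

## Synthetic data: what it emulates, and what it does not

* **Spike panels** are synthetic: 92 + 78 members with stock concentrations
  log-spaced over 6 log₂ units by default — wide enough to probe
  count-dependent deviation, narrow enough that every spike is countable at
  10⁶ reads. Real concentration sheets can be supplied as a TSV instead.
* **Titration**: one endogenous background (log-normal abundances, constant
  across aliquots, as aliquots of one pool) plus spikes with expected count
  ∝ stock × dilution, each mix scaled to 5 % of the library at its highest
  dilution. Noise models: `none` (expectations rounded half-to-even),
  `poisson`, `nb` (gamma-Poisson with given overdispersion). With `none`,
  deviations are bounded by integer rounding, ≈ 1/(2·μ·ln 2) — exact for all
  practical purposes at large μ but not literally zero for irrational
  dilution ratios.
* **Replicates**: genes share a true expression vector; counts are
  negative-binomial with per-replicate-level dispersion — RNA-isolation
  replicates default to 0.05, library-prep replicates to 0.01, encoding the
  observed ordering (library-prep replication is more precise); the
  magnitudes are free parameters, not estimates from any dataset. A planted
  fraction of genes (default 15 %) are single-positive noise with 1–3 counts
  in exactly one replicate. Biofluid presets (`ePRP` mito-heavy at 77 %
  mitochondrial reads, `ePFP` protein-coding-dominated, `urine` gene-rich at
  12 000 genes) assign few genes to the mitochondrial and rRNA classes and
  then match the planted biotype × chromosome *read* fractions exactly in
  expectation by iterative proportional fitting on the class-cell totals —
  so mito-heavy fluids concentrate reads in a handful of genes, as real
  platelet-rich plasma does.
* **Concentration sets**: endogenous read weight ∝ concentration × volume,
  spike weight ∝ dilution, Poisson counts — the estimator recovers planted
  ratios by construction plus counting noise.

Not emulated: read-level artefacts (duplication, fragment length, coverage
bias along transcripts), cross-gene correlation, compositional coupling
between biofluids sharing a gene universe, batch effects, and any absolute
scale. Passing tests therefore demonstrate correctness of the statistics
under the declared generative assumptions, not performance on any particular
real dataset.

A note on the composition-recovery test: it runs in the Poisson regime
(dispersion 0) because gene-level overdispersion legitimately moves a single
library's *realized* composition away from the ensemble expectation — that is
generative variation, not estimator error; the estimator is exact for the
realized library.

## Determinism and reporting

Every randomised operation takes an explicit seed; per-sample and per-stage
generators are spawned from `numpy.random.SeedSequence` so adding samples
does not perturb others. Reports are TSV tables plus a JSON summary; floats
are serialised at full precision (round-trip well beyond 12 significant
digits). The run manifest records the config snapshot, input SHA-256 digests,
seed, version and a wall-clock timestamp; reproducibility is defined over the
analysis outputs, which are bit-identical across same-seed reruns, while the
manifest is run metadata.

## Problem sizes

Defaults were chosen at the scale the statistics are used: libraries of 10⁶
reads, thousands of endogenous genes (2 000 in titration backgrounds,
6 000–12 000 per biofluid preset), 170 spikes. The exactness check of the
noise-free titration uses a deliberately huge library (2 × 10¹⁰ expected
reads) so integer rounding is negligible; the deviation-fraction check uses
2 × 10⁶ reads with an 8 % spike share and a 3-log₂ panel range so every
spike's expected count exceeds 100, the regime in which fold changes are
reliable. The combined `assess` demonstration uses 5 titration samples plus
three replicate pairs at 1.3 × 10⁶ reads, subsampled to 10⁶.

## Known limitations

* The ALC mean/median ambiguity above; both numbers are reported.
* Concentration estimates assume identical spike stocks and complete spike
  recovery; degraded recovery (seen in practice for conditioned medium)
  biases ρ upward and is only detectable here as an anomalous ratio.
* Fraction families are as good as the upstream annotation; region-boundary
  assignment rules for reads are upstream's, not defined here.
* Overlap statistics depend on the detection cutoff and sequencing depth;
  Jaccard indices are comparable only at matched depth.
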