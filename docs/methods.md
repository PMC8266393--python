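# Methods

## Scope and model

`spikequant` quantifies depletion experiments in which an auxin-inducible
degron removes a protein of interest (IAA-treated samples) against a
vehicle control (DMSO), with a foreign-genome spike-in as the internal
standard. Three assays share one quantification skeleton:

1. **Normalization by spike totals.** For RNA-seq, per-gene signal is
   `count / spike_reads × scale` with `scale = 10,000` (an arbitrary
   rescaling constant; it cancels from every ratio). ChEC-seq coverage is
   normalized per base the same way against the *D. melanogaster* spike.
   ChIP-seq adds an input correction:
   `value = raw / Spombe(IP) × (Spombe(input)/Scer(input)) × scale`,
   which corrects for variation in the spike:experimental chromatin
   ratio between IP and input libraries. When the input ratio is 1 the
   ChIP formula degenerates to the ChEC formula — an identity the tests
   assert. An RPM mode exists for re-analysis of public datasets that
   carry no spike; which datasets use it is sample metadata, not code.
2. **Pipeline order** is fixed as normalize → filter → average → log2
   change. The detectability filter (raw count > 0 in every sample)
   guarantees positive denominators, which is why the default log2
   pseudocount is 0; a pseudocount is accepted for exploratory use.
3. **Ratios are spike-independent.** The traveling ratio, the
   phospho/Rpb1 ratio and the log2 TR change are ratios within or across
   tracks of one normalization state, so they are invariant to the
   normalization factor; tests pin this invariance exactly.

## Coordinates and gene model

Internally all coordinates are 0-based half-open; GFF3 (1-based
inclusive) is converted on read, bedGraph is taken as is. TSS and PAS
are stored as *transcription-direction boundaries* of the half-open
transcribed interval: for a `-` strand gene the TSS is the interval's
exclusive end. One convention then serves every consumer: the promoter
window is `[TSS−300, TSS+100)` in transcription direction on both
strands, the transcribed region is `[min(tss,pas), max(tss,pas))`, and
a missing TSS falls back to 100 bp upstream of the start codon
(`cds_start − 100` on `+`, `cds_start + 100` on `-`), flagged per gene.

The TATA classification scans the sense strand of a −200..TSS window
for the TATAWAW consensus (W ∈ {A,T}); `N` never matches. The window
and strand are configurable because the consensus is standard but the
scan extent is a convention; the default is deliberately conservative
(core promoter only).

## Peak calling

The caller implements three published criteria directly rather than
reproducing any specific peak-calling program: a candidate window must
be (i) ≥ 2-fold over the depth-matched control, (ii) ≥ 2-fold over the
local IP background (±5 kb), and (iii) significant under a Poisson tail
test at Benjamini–Hochberg FDR 0.1%. Windows are 200 bp at 50 bp
stride; passing windows merge when overlapping; the summit is the
mid-range of the merged borders.

Two numerical choices matter:

* **Scale invariance.** A Poisson test on normalized signal would
  change with the normalization constant. Both tracks are therefore
  rescaled internally to a fixed effective depth (10⁶ pseudo-reads)
  before scoring, making the peak list invariant to joint rescaling of
  IP and control — the property spike normalization requires.
* **Continuous tail.** Normalized window sums are not integers; the
  Poisson tail is evaluated as the regularized-gamma continuous
  extension `P[X ≥ x] = gammainc(x, λ)`, which equals the discrete tail
  at integer `x`. Empty control regions get a floor of a quarter of the
  genome-average window count so folds stay finite; the floor is
  expressed in effective-depth units and preserves scale invariance.

Promoter assignment takes the peak whose summit lies in the −300..+100
window; with several candidates the summit closest to the TSS wins and
an exact distance tie goes to the upstream peak (deterministic). A
promoter with no assigned peak falls back to the argmax of the 21-bp
moving-average signal inside the promoter window; plateau ties (the
smoothing of a sharp maximum) break by raw signal, then TSS distance.
Occupancy is the signal sum in a 200 bp window centered on the summit.
Zero occupancies in the log2 change receive a pseudocount of half the
smallest positive occupancy in the experiment — scale-aware, avoids
infinities. Replicates are compared pairwise (IAA vs DMSO by replicate
index) and the per-pair log2 changes averaged.

## Elongation metrics

The traveling ratio anchors its 100-bp windows at `[TSS, TSS+100)` and
`[PAS−100, PAS)`. The anchor positions are a documented assumption
(window width is standard; exact insets are not), exposed as arguments.
Genes must exceed 300 bp with annotated TSS and PAS; zero 3′ signal
leaves TR undefined and the gene excluded and counted. Metagene
profiles average coverage per TSS-relative offset (−200..+1000) across
the genes of a group per condition and report `log2(mean_IAA /
mean_DMSO)` — log of group means rather than mean of per-gene logs, so
per-gene zero coverage cannot produce infinities; genes must exceed
1 kb. Quintiles of the transcription change are equal-size (±1) with
stable gene-id tie-breaking; orientation is fixed with Q5 = most
depletion-dependent (most negative log2 change). Kinase and
elongation-factor occupancy changes normalized to Rpb1 reuse the
phospho-ratio code path verbatim; there is no separate implementation.

## Statistics

Spearman (average ranks), Welch's t (two-sided, Welch–Satterthwaite
df), and the one-sided hypergeometric over-representation tail
`P[X ≥ |A∩B|]` are delegated to scipy; tests cross-check them against a
Pearson-on-ranks oracle, the closed-form Welch statistic, and exact
combinatorial enumeration for universes ≤ 25. Degenerate conventions:
zero variance with equal means reports t=0, p=1; a constant vector
makes Spearman undefined (NaN, reported as such); an overlap that could
not be smaller is reported as p=1 with a note. The one-sided tail for
set overlaps is a choice — over-representation is the question these
Venn comparisons ask — and is documented here because two-sided
alternatives exist. Significance stars use ≤ cutoffs: 0.0001, 0.001,
0.01, 0.05. The hypergeometric universe defaults to the annotated,
filtered promoter set and is configurable.

## The synthetic generator

The generator produces data with the statistical structure the
quantification assumes, plus the ground truth needed for recovery
tests. Defaults are the study conditions.

* **Annotation**: non-overlapping genes on both strands of one
  chromosome, lognormal lengths (median 1.4 kb, clipped 0.5–4 kb),
  700–1100 bp intergenic gaps, class labels 87% TFIID-dependent / 13%
  CR, TATA fractions 0.1 / 0.6 per class. TATA-flagged promoters get a
  planted TATAWAW in the scan window; chance matches in unflagged
  windows are scrubbed, so flags are exactly recoverable by a motif
  scan.
* **Counts**: gene abundances lognormal (median 200, σ=1); injected
  log2 fold changes per class, Normal(median, sd) with defaults
  (−2.0, 0.4) for TFIID and (−log2 1.3, 0.25) for CR. Read allocation
  mimics the cell mix: the spike RNA mass is fixed relative to the
  *control* transcriptome (ratio 1:8), so when depletion shrinks the
  experimental transcriptome, the spike fraction of a fixed sequencing
  depth grows — the mechanism that lets spike normalization reveal
  global collapses. Per-sample depth is lognormal with CV 0.2
  (replicate jitter); spike reads are Binomial(depth, spike fraction),
  co-varying with depth; gene counts are negative binomial with
  dispersion 0.05. The dispersion of nascent counts is not an
  empirically fixed quantity here — 0.05 is a typical
  technical-plus-labeling value that yields replicate CVs near 20%,
  under the <30% reproducibility regime these experiments target; it is
  exposed in the config. With `replicate_cv = 0` and `nb_dispersion =
  0` the generator is fully deterministic (rounded means), giving a
  zero-noise limit for tests.
* **Promoter tracks**: uniform background (1 read/bp expectation),
  bound promoters (60% by default) receive a discretized Gaussian
  pileup (σ = 75 bp, qualitatively matching the −1/+1 nucleosome span)
  whose mass makes the 200-bp summit window 8-fold over background.
  The depletion response is parameterized on the *measured* quantity:
  `iaa_log2_change` (default −log2 1.7) is the change of the 200-bp
  summit-window signal including background, and the peak-mass factor
  is solved from it. Controls are uniform Poisson. Summits are uniform
  within an inset of the promoter window so occupancy windows stay
  inside it.
* **Pol II tracks**: expression-scaled flat coverage TSS→PAS plus a 5′
  accumulation in IAA, `1 + strength·exp(−d/400 bp)`, with strength
  proportional to the injected transcription loss (and optionally a
  fixed extra strength on a random gene subset, for contrasting shifted
  vs unshifted sets under a null effect). A kinase-style track applies
  a uniform 1.4-fold IAA gain on top of the Pol II profile; an input
  track is uniform. The decay length 400 bp makes the metagene excess
  of shifted genes fade by ~1 kb.

All randomness flows from one integer seed; identical config + seed is
byte-identical, which the CLI determinism tests assert at the file
level.

## What the generator does not emulate

Sequence-composition and GC bias, fragment-size structure, read-level
artifacts, mappability, multiple TSSs per gene, isoforms and UTRs,
chromatin domain structure, and correlated biological replicate
variation. Passing recovery tests therefore demonstrates that the
quantification is correct under the stated statistical model — not that
it is robust to alignment or library-preparation pathologies, which are
upstream of this package.

## Problem sizes

The test suite and the acceptance script run at desk scale: 2000 genes
× 3 replicates for count recovery, 200 planted peaks on a ~0.5 Mb
genome for the peak pipeline, 400 genes for elongation metrics, and
1000 simulations for the Welch type-I calibration. These sizes were
chosen so that median-recovery error (≲2%) is far below the 10%
acceptance bands while the whole suite stays fast.

## Known limitations

* The peak caller implements the published enrichment criteria, not any
  specific external program's internals; bound-promoter counts on real
  data may differ from lists produced by other callers, and the
  thresholds are exposed for calibration.
* Consensus binding (k of n) treats replicates symmetrically; there is
  no weighting by peak strength.
* The fallback-summit rule depends on the smoothing width (21 bp
  default); very flat promoters resolve ties toward the TSS by
  construction.
* Medians of folds are computed as folds of medians (valid because the
  median commutes with monotone transforms); means would not commute
  and are not offered on the fold scale.
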