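# Methods

This note documents the models, parameter choices and numerical decisions
behind `misasm`, and what the synthetic test bench does and does not show.

## Read-depth model

Read depth (RD) for a bin is the number of reads whose overlap with the bin
is at least half the read length, each read counting in at most one bin and
exact 50/50 splits assigned to the earlier bin (deterministic and
order-independent). With 100 bp reads on 100 bp bins this reproduces the
standard read-depth CNV convention. Bins record the GC fraction of their
non-N bases and their N fraction; bins that are majority-N are excluded
from all normalisation statistics but still receive RD values.

GC correction scales each bin's count by (mean count over bins in
qualifying GC strata) / (its stratum's mean count), with strata of one GC
percentage point and a 30-bin minimum per stratum. Strata below the minimum
or with zero mean are left uncorrected. Taking the normalising mean over
qualifying-stratum bins only (rather than all bins) makes the correction
conserve the global total exactly and makes it idempotent — a second
application is a no-op to machine precision. The stratum width is our
choice; published read-depth callers do not expose theirs.

Normalisation divides by the genome-wide median corrected count of non-N
bins, so background RD ≈ 1 and the RD of a collapsed k-copy duplication
≈ k. Median (not mean) keeps the scale robust to the heavy upper tail of
duplicated regions.

Bin-size selection follows the mean/SD ratio criterion: the smallest
candidate whose per-bin count mean/SD ratio lands in [4, 5] is chosen
(Poisson counts give ratio √mean, so this targets means of roughly 16–25
per bin); if none lands inside, the candidate closest to 4.5 wins, and the
full ratio table is reported.

## Region calling

Candidate high/low regions are maximal runs of bins with RD above 1.5 /
below 0.5 (≈ 3.4 Poisson standard deviations from background at 46×,
100 bp bins). A run may bridge at most one *neutral* bin between concordant
neighbours; an opposite-state bin always terminates a run, so high and low
candidates can never overlap and candidates tile each chromosome. Runs need
at least two concordant bins: a single-bin Poisson outlier has no
multi-bin support, and without this requirement the uniform-genome control
(below) would produce spurious one-bin low-coverage calls. This
threshold-run segmentation replaces mean-shift segmentation of CNV callers;
it is simpler, oracle-testable on noiseless input, and the downstream
analysis depends on the thresholding layer, not on exact change-point
placement.

Each candidate gets a two-sided one-sample *t*-test of its bins' RD against
the global non-N mean; degenerate candidates (zero variance) get p = 1 when
their RD equals the population mean and p = 0 otherwise. P-values are BH
adjusted over all candidates. q0 is the fraction of multi-mapping reads in
the region (0 when the region has no reads). High/low candidates are kept
iff q < 0.08 and q0 < 0.5; background candidates are never q-filtered.
Final classes use strict dual thresholds (defaults 0.72 / 1.76): candidates
failing their own class's threshold — and background candidates drifting
outside [low, high] — become "other", so the dual-threshold scheme is the
sole source of that class. The default cuts are the published reference
values for this procedure; `select_thresholds` re-derives cuts for new data
by grid search (0.01 resolution) minimising the inter-class overlap
objective, breaking ties toward the midpoint of the tying interval.

## Misassembly categories

Alignment blocks come from a show-coords-style table (1-based inclusive,
converted at the I/O boundary; reverse subject intervals normalised with an
orientation flag) and are filtered at ≥ 95 % identity. Query intervals that
overlap ≥ 50 % reciprocally form one query region; subject intervals are
clustered genome-wide the same way before duplicate counting (the
deduplication rule for near-identical subject hits is our choice — the
reciprocal-50 % criterion is the field's usual one). A query region is
*duplicated* iff ≥ 2 merged subject regions remain, on any chromosomes.

A duplicated query region is misassembled (M2/M3) iff (1) it is ≥ 100 bp,
(2) the union of pairwise overlaps among its subject regions is < 50 % of
the query length — "union" resolves an ambiguity in the verbal rule, and is
the stricter reading — and (3) its subject regions align to no other query
region. Local (2) requires all subjects on one subject chromosome; any
mixed case is non-local (3). Query regions whose shared subjects outnumber
the query copies are labelled `complex` and excluded from the six-way
scheme (multi-copy-to-more-copies cases have no natural category).

For non-duplicated regions, "misassembled" (M1) is operationalised as: off
the length-weighted longest-increasing-subsequence chain of one-to-one
anchors on the chromosome's dominant subject chromosome, or on a different
subject chromosome altogether. The underlying criterion ("aligned to a
different location") is only stated verbally in the literature; the LIS
chain is a standard anchor-consistency test.

Coverage classes and categories intersect three ways: per class the length
fraction in each category, per category the fraction overlapped by
HC/BG/LC/other (normalised over those four classes, rows summing to 1),
and per region a majority label (`M2/M3` or `C2/C3`) where a strict > 50 %
length majority exists — the label consumed by the misassembly
discriminator models.

## Features and models

Densities are union-based (fraction of region length covered), so
overlapping track entries cannot exceed 1. Flanking features use the
union of the upstream and downstream windows of each size
(0.5/1/2/4/8/16/32 kb), clipped at chromosome ends; whether sides should be
pooled is not specified anywhere we know of, so pooling is the default and
separable in code. k-mer densities are single-strand with no
reverse-complement collapsing (AT and TA are distinct features), windows
containing N excluded from numerator and denominator. The SSR finder
reports exact adjacent repeats of 2–64 bp units with ≥ 2 copies, maximal
extension, smallest-period motif, and suppression of larger periods that
are multiples of an already-reported period over the same span; it is an
exact-match detector — mismatch-tolerant tandem-repeat detection (e.g. TRF
with Match = 2, Mismatch = 7, Delta = 7, PM = 80, PI = 10, Minscore = 50,
Maxperiod = 500) is out of scope, and per-motif SSR features use distinct
uncollapsed motif strings. Tandem duplicates are paralogs adjacent in gene
order or separated by ≤ 10 non-homologous genes, with transitive closure
merging chains into clusters.

Model training balances classes by downsampling to the minority class
(100 balanced datasets by default), holds out 10 % per class before any
fitting (optionally as two genomic spans per chromosome, a leakage
control), grid-searches random-forest hyperparameters (max_depth
{3, 5, 10, None}, max_features {sqrt, 0.25, 0.5}, trees {100, 500} — the
grid values are our defaults) by 10-fold cross-validated macro-F1 on the
first 10 balanced datasets, and reports averages over all datasets.
Forests split on entropy so importances are information-gain based; top-k
feature selection is per family (k-mers and SSRs separately), ties broken
lexicographically. Functional annotations enter as presence/absence flags
(count encoding is an available switch). The model catalog names the full
family grid: base-features-only (1), flank-only per size (2–8), base+flank
(9), +top-100/500/1000 k-mers and SSRs (10/18/26), all-inclusive (34),
+functional (35), functional-only (36), binary HC-vs-BG variants (1B, 34B,
35B, 36B), and the misassembly discriminators HC_M2/M3 vs HC_C2/C3 (37)
and HC_M2/M3 vs BG_M2/M3 (38).

## Statistics

The log-likelihood ratio is computed as a difference of per-cell log10
terms, which keeps the antisymmetry llr(a,b,c,d) = −llr(c,d,a,b) bit-exact;
any zero cell triggers a flagged Haldane +0.5 correction on all four cells
rather than returning ±∞. Enrichment uses two-sided Fisher tests with BH
correction within each annotation family. The reshuffle z-score permutes
region class *labels* (counts preserved, coordinates fixed) — the
alternative of re-placing coordinates is implemented separately as the
matched-random sampler, which draws non-overlapping intervals with exactly
the observed length multiset inside the background space by rejection
sampling (10⁴-retry cap per interval; simple and exact on the non-overlap
constraint). Permutation p-values use the add-one estimator, so they are
never zero and calibrate to uniform under the null.

## Synthetic test bench

The generator emulates the real workflow's inputs: duplicate copies are
created by copy-then-point-mutate at a configurable rate (default 1 %, so
copies clear the 95 % identity filter by construction); collapse events
remove all but one copy, giving the retained copy expected RD = k and truth
category M2 (one truth chromosome) or M3 (several); gaps become N runs with
expected RD 0; reads are Poisson-sampled per bin at rate
expected_RD × coverage × bin/read-length, with an optional logistic GC-bias
multiplier centred on genome-mean GC, and never start on an N base.
Multi-mapping is emulated, not aligned: reads originating in a *retained*
duplicated tract (category C2/C3 — both copies present, so a real aligner
would be ambiguous) are flagged with a configurable probability (default
0.9); reads over a collapsed copy map uniquely, as they do in reality.
Alignment blocks are emitted directly from the construction, one block per
(collapsed interval, truth copy) pair.

Defaults define the study conditions: 46-fold coverage, 100 bp reads,
100 bp bins, 1 % copy divergence. The duplication size spectrum of the demo
genome (2–4 kb units, 2–3 copies) is a free choice — no published
size/identity spectrum exists for the motivating genome — sized so that
planted events span many bins at desk scale.

What the bench does *not* model: sequencing errors and quality scores,
paired-end structure, mapping artefacts, real repeat landscapes, and
alignment breakpoint noise. Passing tests therefore demonstrate the
correctness of the pipeline's logic and its statistical calibration, not
performance on real libraries, where mapping ambiguity and repeat structure
will erode the clean separations seen here.

## Problem sizes and reproducibility

The bundled checks run at desk scale by design: 2 Mb single-chromosome
genomes for the resampling-fidelity and uniform-null analyses, 2 × 300 kb
for the full-pipeline dataset, 500-replicate calibrations for permutation
type-I error, and 10-ish balanced datasets in pipeline model runs. The
resampling-fidelity comparison uses the caller's segment-mean RD per bin —
the RD a read-depth region caller actually reports — because per-bin
Poisson noise at 46× (SD ≈ 0.15 around RD 1) bounds the raw per-bin
correlation below what segment-level RD achieves; the input RD is
piecewise-constant over segments, so segment means are the faithful
comparison. Every stochastic step takes an explicit seed, and identical
seeds reproduce byte-identical outputs, including the pipeline's JSON
report.

## Known limitations

* The segmentation is a threshold-run method; region boundaries are
  bin-quantised and will not match mean-shift change points on real data.
* The M1 rule depends on the anchor chain; translocation-dense genomes
  would need a more global synteny model.
* The exact-match SSR finder undercounts degenerate repeats relative to
  mismatch-tolerant detectors.
* `classify_tandem` counts intervening non-homologous genes using the
  supplied paralog relation only; unrelated homology (e.g. shared family
  membership without a listed pair) is not recognised.
* The matched-random sampler is rejection-based; extremely fragmented
  background spaces can hit the retry cap.
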