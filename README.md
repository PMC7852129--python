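# misasm

Read-coverage based misassembly audit for short-read genome assemblies.

Short-read assemblies routinely collapse near-identical duplicated sequence
into a single copy. When the sequencing reads are mapped back, such collapsed
regions attract the reads of every original copy and show up as
**high-coverage (HC)** regions; assembly gaps and poorly sequenced tracts show
up as **low-coverage (LC)** regions; everything else is **background (BG)**.
`misasm` implements the full audit around this signal for researchers
assessing the quality of draft plant (or other) genome assemblies:

1. **Read depth (RD).** The assembly is tiled with fixed-width bins
   (default 100 bp). A read counts in the single bin holding ≥ 50 % of its
   length (50/50 ties go to the earlier bin). Counts are corrected for GC
   bias by per-stratum scaling (1 GC-percentage-point strata, 30-bin
   minimum) and normalised so the genome-wide median RD of non-N bins is 1.
2. **Region calling.** Runs of bins with RD consistently above/below
   background become candidate high/low regions (bridging ≤ 1 neutral bin);
   each candidate receives a two-sided one-sample *t*-test p-value against
   the genome mean, Benjamini–Hochberg adjusted to q-values, plus
   q0 = the fraction of multi-mapping reads. High/low candidates survive
   only with q < 0.08 and q0 < 0.5, and the final classes come from dual RD
   thresholds: HC ⇔ RD > 1.76, LC ⇔ RD < 0.72, BG ⇔ 0.72 ≤ RD ≤ 1.76,
   with threshold-failing candidates labelled *other*.
3. **Misassembly categories.** Given whole-genome alignment blocks against
   a truth (e.g. long-read) assembly (show-coords-style table, identity
   ≥ 95 %), every query region is classified as
   C1/C2/C3 (correct; non-duplicated / locally duplicated / non-locally
   duplicated) or M1/M2/M3 (misassembled counterparts). A duplicated query
   is misassembled iff it is ≥ 100 bp, its duplicated subject regions
   overlap < 50 % of the query length, and those subjects align to no other
   query region — the signature of a collapsed duplication.
4. **Features + models.** Per-region GC, densities of genes / tandem genes /
   non-tandem genes / pseudogenes / TEs / SSRs, the same in flanking windows
   (0.5–32 kb), k-mer (1–6 bp) and per-motif SSR densities, and functional
   presence flags feed balanced random-forest classifiers of region class
   (with grid search, stratified or genomic-span hold-outs, and
   entropy-based feature importances).
5. **Statistics.** Gene-set enrichment with Fisher's exact test, BH
   correction and the log-likelihood ratio
   LLR = log10((a/b)/(c/d)) of the 2×2 table; windowed density
   correlations (Spearman ρ); label-reshuffle z-scores; z-scores against
   10 000 length-matched random background placements; and standard
   two-sample comparisons (rank-sum, KS, variance-F, Kruskal–Wallis).

Everything is exercisable without external data through the bundled
**synthetic-genome generator**: it plants tandem/interchromosomal duplicate
clusters, genes, TEs, SSR tracts and pseudogenes in a truth genome, derives
a "collapsed" assembly with known misassemblies and N gaps, simulates
Poisson read placements at a chosen fold coverage (default 46×, 100 bp
reads, optional GC bias and multi-mapping flags), and emits the per-base
truth labels every stage is scored against.

## Worked example

Simulate a 2 × 300 kb genome with collapsed duplications and gaps, call
coverage regions and classify assembly categories:

```bash
$ misasm simulate --seed 7 --chrom-length 300000 --out demo_sim
wrote 270671 reads and truth labels to demo_sim

$ misasm call-regions --assembly demo_sim/assembly.fa \
    --placements demo_sim/placements.tsv --out demo_regions.bed
coverage_class
BG    13
HC     7
LC     4

$ misasm classify --coords demo_sim/coords.tsv --out demo_cats.tsv
C1    17
M2     6
C2     3
C3     2
M3     1
```

The 7 HC calls are the collapsed duplicate clusters (reads of two or three
truth copies pile onto one retained copy, RD ≈ 2–3); the 4 LC calls are the
planted N gaps (RD ≈ 0); M2/M3 are the locally/non-locally collapsed
clusters recovered from the assembly-to-truth alignment, while C2/C3 are
duplications present in both assemblies (correct). `misasm run-all` executes
the whole chain — including feature extraction, model training and the
randomisation statistics — and writes a single JSON report.

The coords table consumed by `misasm classify` is tab-separated with a
header and columns `S1 E1 S2 E2 LEN1 LEN2 IDY QCHR SCHR`: 1-based inclusive
query (S1/E1) and subject (S2/E2) coordinates, S2 > E2 marking a
reverse-orientation subject interval, percent identity in IDY. All internal
coordinates are 0-based half-open (BED convention).

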