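# bivalentia

Analysis toolkit for bivalent-promoter biology and FACS-sorted CRISPR
screens:

- **genome_model** — 0-based half-open interval arithmetic, BED and gene-table
  IO, strand-aware TSS windows and gene scoring regions.
- **quantification** — reads-in-peaks tabulation, per-sample RPM
  normalization, per-gene summed signal over the gene body + 1 kb promoter
  extension, and knockout-vs-control log2 fold change.
- **bivalency** — promoter chromatin-state classification (bivalent /
  k4_only / k27_only / unmarked) from paired H3K4me3 and H3K27me3 peak sets
  within ±2 kb of the TSS.
- **redistribution** — occupancy-redistribution analysis for a chromatin
  factor: RPM coverage filter (≥1 RPM in the factor and H3K4me3 samples),
  per-peak reduced/increased/unchanged classification at a 1-RPM delta,
  gene-level rollup via TSS windows, bivalent-composition and mark-shift
  summaries.
- **screen_analysis** — sgRNA counting from FASTQ by exact spacer match
  after constant-prefix trimming, sorted-vs-unsorted RPM enrichment scores,
  RSA hypergeometric gene ranking, confidence tiers
  (high/moderate/low, requiring ≥4 enriched guides), and dual-screen
  intersection.
- **integration** — Benjamini–Hochberg adjustment, differential-expression
  gene sets (q < 0.05, |log2FC| > 1, strict), venn-style overlap summaries,
  bivalent fractions, and gene-effect co-dependency correlation.
- **synthetic_data** — generators for all of the above with planted ground
  truth: toy genome with designed promoter classes, negative-binomial
  multi-mark counts in control/knockout conditions with a planted factor
  redistribution, screen counts/FASTQ with planted repressors, and
  block-correlated effect matrices. Every generator is a pure function of
  (config, seed).

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(oracle equivalence, planted-signal recovery, determinism). One test,
`test_criterion_2a_screen_null_ks_uniformity`, fails by design: the RSA
gene statistic is a minimum over hypergeometric tail probabilities and is
not uniform under the null, so a KS uniformity test necessarily rejects;
the assertion is kept as specified rather than weakened.

## CLI

All stages are exposed under one entry point (run `bivalentia --help`):

```sh
bivalentia simulate genome --n-genes 1000 --seed 1 --out-prefix sim
bivalentia simulate marks --genes sim.genes.tsv --truth sim.truth.json \
    --condition control --depth 1000000 --replicates 3 --seed 1 --out-prefix ctrl
bivalentia simulate screen --truth sim.truth.json --seed 1 --fastq --out-prefix scr

bivalentia regions --genes sim.genes.tsv --tss-window 2000 --promoter-ext 1000 --out regions.bed
bivalentia quantify --peaks peaks.bed --fragments s1.bed --fragments s2.bed \
    --genes sim.genes.tsv --out signal.tsv
bivalentia lfc --signal signal.tsv --samples samples.tsv --ko knockout --ctrl control --out lfc.tsv
bivalentia bivalency --genes sim.genes.tsv --k4 k4.bed --k27 k27.bed --out calls.tsv
bivalentia redistribute --sites sites.bed --ctrl-rpm ctrl.tsv --ko-rpm ko.tsv \
    --k4-rpm k4.tsv --genes sim.genes.tsv --bivalency calls.tsv --out-prefix redist

bivalentia screen count --library scr.library.tsv --prefix ACCG \
    --sorted-fastq scr.sorted.fastq --unsorted-fastq scr.unsorted.fastq --out counts.tsv
bivalentia screen score --counts counts.tsv --out scores.tsv
bivalentia screen rank --scores scores.tsv --library scr.library.tsv --out logp.tsv
bivalentia screen tiers --logp logp.tsv --scores scores.tsv --library scr.library.tsv --out hits.tsv
bivalentia screen intersect --a hits_a.tsv --b hits_b.tsv --out shared.tsv

bivalentia de-sets --de de.tsv --out-prefix sets
bivalentia overlap --set up=sets.up.txt --set other=other.txt --out overlap.tsv
bivalentia bivalent-fraction --genes sets.up.txt --bivalency calls.tsv --out frac.tsv
bivalentia codep --matrix effects.tsv --query EZH2 -k 20 --out codep.tsv
```

Rerunning any command with identical arguments (including `--seed`)
produces byte-identical outputs.

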