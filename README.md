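# pitanga

Analysis toolkit for studying microsatellite (SSR) landscapes and
drought-stress expression in *Eugenia uniflora* (pitanga) sampled from two
contrasting Brazilian environments — Restinga (RE: sandy, saline,
nutrient-poor) and Riparian Forest (RF: moist, nutrient-rich). The package
re-implements the analytical core of such a study as a tested, reusable
pipeline, and ships a synthetic-data generator with planted ground truth in
place of the raw sequencing data, so every method can be validated against
known answers.

## What it computes

- **SSR landscape** (`pitanga.ssr_landscape`) — detection of perfect
  tandem repeats of primitive 1–6 bp motifs (MISA-convention minimums
  10/6/5/5/5/5 repeats; compound SSRs within 100 bp interruptions),
  canonical strand/phase-invariant motif classes `X/Y` (e.g. `AG/CT`),
  merging of same-sequence SSRs within 100 bp into loci, transcribed
  classification by transcript overlap, and identification-metrics
  summaries (density in units/Mb) with per-class chi-square deviation tests
  at 0.01 confidence for classes above 0.5 % representation.
- **Population diversity** (`pitanga.ssr_population`) — per-locus allele
  (repeat-count) sets per population, classified as exclusive / equal /
  preferential (ambiguous when undecidable), with a one-df chi-square on
  the exclusive-locus split.
- **Differential expression** (`pitanga.expression_stats`) — median-of-
  ratios size factors, negative-binomial maximum likelihood
  (variance μ + αμ²), a two-group likelihood-ratio test with a single
  shared dispersion estimated by Cox–Reid adjusted profile likelihood
  (df = 1), DEG calling at |FC| ≥ 1.5 and p < 0.05, shared/unique Venn
  partitioning, and Benjamini–Hochberg adjustment. This NB test is a
  self-contained stand-in for an off-the-shelf DE package, validated on
  planted synthetic truth.
- **Transcriptogram** (`pitanga.transcriptogram`) — genes with at least one
  association above combined score 800 are arranged on a line by simulated
  annealing so that positional distance reflects association likelihood;
  expression is projected onto the ordering with radius-30 window averages
  (61 genes at interior positions), compared drought-vs-control per
  position (Welch, radius 30 and radius 0), peaks called at p < 0.01, GO
  term density tracked over 61-gene windows, and candidate genes selected
  by the combined rule (R30 p < 0.01, R0 p < 0.05, per-gene DE p < 0.05).
- **SSR–expression links** (`pitanga.ssr_expression_link`) — loci linked to
  genes within 2 kbp, samples split by SSR presence, per-link NB LRT with
  BH adjustment, and hypergeometric term overrepresentation of SSR-proximal
  genes.
- **Synthetic data** (`pitanga.synthetic_data`) — genomes with planted
  SSRs recoverable at exact coordinates, the 12-library
  2-population × 2-condition × 3-replicate count design with planted DE and
  SSR-linked effects, diversity-scenario SSR call tables, and block-modular
  scored interaction graphs.

## Worked example

Run the numbered analyses (each a thin driver over the library) in order:

```sh
python analysis/01_simulate_dataset.py
python analysis/02_ssr_landscape.py
python analysis/03_population_diversity.py
python analysis/04_differential_expression.py
python analysis/05_transcriptogram.py
python analysis/06_ssr_expression_link.py
python analysis/07_report.py
```

With the default parameters (400 kb genome, ~200 planted SSRs, 200 genes,
seed 1) the drivers print:

```
200 SSR records (0 compound), 200 merged loci, 51 transcribed
density 462.5 u/Mb over 400,000 bp
200 loci with calls; exclusive RE=36, RF=39, equal=30, preferential RE=41 RF=44, ambiguous=10
RE: 11 DEGs (7 up, 4 down); recovered 7/20 planted (power is replicate-limited at n=3)
RF: 7 DEGs (6 up, 1 down); recovered 4/20 planted (power is replicate-limited at n=3)
RE: 5 peaks at p < 0.01; 2 combined candidate genes
RF: 1 peaks at p < 0.01; 0 combined candidate genes
493 links (405 testable); 0 genes at q < 0.05
```

Reading this: all 200 planted SSRs are found and merged into loci, a
quarter of which overlap transcripts; population diversity spreads over
the five classes the call simulator plants; at three replicates per
condition the calibrated NB test recovers the strongest planted fold
changes; the transcriptogram shows the planted stress-responsive gene
neighborhood of the RE population as radius-30 peaks; and the per-link
SSR tests, BH-corrected over 405 links, find no hit at this replicate
level — the dedicated power analysis below shows the same test recovers
96 % of 2-fold effects at 9-vs-9 samples.

The same run is available as one command: `eu-pipe run --out DIR --seed 1`
(byte-identical bundles for a fixed seed).

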