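# Methods

## SSR detection and canonicalization

A simple SSR is a maximal perfect tandem run of a primitive motif (1–6 bp;
"primitive" = not a whole-number power of a shorter string), kept when it
meets the per-length minimum repeat number. The defaults follow the MISA
convention — mono 10, di 6, tri 5, tetra 5, penta 5, hexa 5 — and are
configurable (`PipelineConfig.ssr_min_repeats`). The scanner walks each
period k = 1..6 over the match array `s[j] == s[j+k]`; a maximal run of
matches of length ℓ is a tandem region of span ℓ + k, reported once with
repeat number ⌊span/k⌋ (partial trailing units truncated, so interval
length is always motif length × repeats). `N` never matches, so ambiguity
bases break runs. Non-primitive motifs are skipped at their own period and
picked up at the primitive period, which is what assigns each run its
shortest motif. Two or more SSRs separated by ≤ 100 bp (configurable) are
additionally reported as a compound record; compound members are not
double-counted in per-length totals, so per-length counts plus the
compound count add to the total, matching the additivity of the study's
identification-metrics table. A quadratic reference scanner
(`detect_ssrs_bruteforce`) re-derives the same records independently and
is used to verify precision on sequences up to ~10 kb.

Motif classes collapse strand and phase: the label is `X/Y` where X is the
lexicographic minimum over all rotations of the motif and of its reverse
complement, and Y the minimal rotation of reverse-complement(X).
Exhaustively, the 12 primitive dinucleotides fall into 4 classes
(AC/GT, AG/CT, AT/AT, CG/CG) and the 60 primitive trinucleotides into 10.

Same-sequence SSRs (identical motif string, not merely same class) within
100 bp on the same sequence merge into one locus by single linkage; the
locus interval is the envelope. A locus is transcribed when its interval
overlaps (half-open semantics) at least one supplied transcript interval;
this coordinate-overlap proxy replaces re-detecting SSRs in assembled
transcripts, which would require the raw data.

Per-class transcription bias is a one-df goodness-of-fit chi-square of
each class's (transcribed, untranscribed) split against its motif-length
division's pooled split, without continuity correction; classes at or
below 0.5 % of their division are excluded from testing and flagged.

## Population diversity classes

An allele is a repeat count at a locus; per-population allele sets are the
union over samples. Classification is presence-based: *exclusive* when
only one population shows alleles; *equal* when both sets are identical;
*preferential* toward the population with strictly more distinct alleles.
Differing sets of equal size admit no defensible direction (each side then
holds at least one private allele) and are reported in an explicit
*ambiguous* bin rather than forced into a class. The exclusive-locus split
is tested against an even 50/50 expectation with a one-df chi-square.

## Negative-binomial testing

Counts are modeled NB(μ, α) with variance μ + αμ²; α = 0 degenerates to
Poisson, and the fitter may return the boundary. Library size enters as
per-sample offsets s_i (E[x_i] = μ s_i) from median-of-ratios size factors
(reference: per-gene geometric mean over samples, restricted to genes
nonzero everywhere), keeping the integer likelihood valid.

The two-group test compares group-specific means against a common mean.
With equal offsets the mean MLE is the sample mean in closed form; with
offsets it solves the score equation by fixed-point iteration. The
dispersion is estimated **once, under the pooled (null) model, by
Cox–Reid adjusted profile likelihood** (the profile likelihood minus half
the log Fisher information of the fitted mean), and then held fixed in
both likelihoods; the statistic 2(ℓ_alt − ℓ_null) ≥ 0 is referred to
χ²₁. This design choice is deliberate: re-estimating the dispersion under
each hypothesis by joint ML is markedly anticonservative at RNA-seq
replicate numbers (empirical null rejection ≈ 0.09 at nominal 0.05 with
6 samples per group, 95th percentile of the statistic ≈ 5.0 against the
χ²₁ 3.84), because chance group separation deflates the alternative's
dispersion estimate exactly when the statistic is large. Fixing the
null-model CR estimate restores calibration (empirical rejection ≈ 0.05,
95th percentile ≈ 3.8 in the same simulation). The cost is power against
large effects at very small n, since a true group difference inflates the
pooled dispersion: at 3 vs 3 replicates a 2-fold change is detected ~35 %
of the time — no calibrated test does much better there (an
oracle-dispersion LRT reaches ~73 %) — while at 9 vs 9 samples 2-fold
effects are recovered ≈ 95 % of the time. A separate-dispersions mode
(df = 2, plain ML per group) is available.

DEG calling: fold change is the ratio of normalized drought to control
means with a 0.5 pseudo-count on both; *up* requires FC ≥ 1.5 and
p < 0.05, *down* FC ≤ 1/1.5 and p < 0.05 (thresholds configurable). The
p-value threshold is applied raw, with BH q-values attached for reference.
Venn partitioning puts genes significant in both populations with opposite
directions into a *discordant* bin instead of any shared set.
Benjamini–Hochberg is the standard step-up, computed in-package and
cross-checked in the tests against an independent brute force and
statsmodels.

This NB machinery is the package's own two-group test, not an emulation
of any external DE tool; agreement with such tools gene-for-gene is out
of scope, and validation is against planted synthetic truth.

## Transcriptogram

Edges with combined score strictly above 800 (0–1000 scale) define the
association graph; genes without a retained edge are excluded from the
ordering universe. The ordering minimizes the total edge positional
distance Σ_(u,v)∈E |pos(u) − pos(v)| by simulated annealing: start from
the sorted-id identity order, propose random pairwise position swaps with
incremental cost updates, geometric cooling from T₀ = cost/N by 0.995 per
sweep of N proposals, and stop after `n_iterations` sweeps without
improving the best cost; the best arrangement seen is returned, so the
result never costs more than the identity order, and a fixed seed is
fully reproducible. On two disjoint cliques the annealer attains the
block-contiguous analytic optimum; on stochastic-block-model graphs it
brings same-block genes to well under half their random-permutation
distance.

Projection takes per-gene expression (size-factor-normalized counts,
log2(x+1)-transformed for testing; untransformed normalized scale for
ratio profiles) to per-position window means over positions i ± 30
(61 genes at interior positions; edge windows truncate rather than wrap).
Per position, drought and control replicate values are compared with a
Welch t-test, both on the radius-30 windowed means (R30) and on the
unsmoothed per-gene values (R0); both-zero-variance ties return p = 1.
Peaks are maximal runs of consecutive positions with p below the
threshold (0.01 by default); no cross-position multiplicity correction is
applied at peak level, matching the raw-threshold presentation, with BH
available as an option. Note the peak *count* is not monotone in the
threshold (runs can merge as the threshold rises); the covered position
count is. GO density is the windowed fraction of term-annotated genes.
Candidate genes require R30 p < 0.01, R0 p < 0.05 and per-gene DE
p < 0.05 simultaneously.

## SSR–gene linking and overrepresentation

A locus links to a gene when it overlaps the gene span (side *within*,
distance 0) or lies within 2000 bp of it, boundary inclusive, measured
between spans (not TSS); upstream/downstream follow the gene's strand.
For each link the expression libraries split by the locus's per-sample
presence call; groups of ≥ 2 each are tested with the shared-dispersion
NB LRT (size-factor offsets), smaller groups are reported untestable with
a reason, and BH runs over exactly the testable set. Term
overrepresentation of SSR-proximal genes is a one-sided hypergeometric
tail against the full gene universe with log2 fold-enrichment
(−∞ sentinel for zero study hits), replacing any external annotation
service with a self-contained test on a user-supplied term map.

## Synthetic data

The generator produces every input with known planted truth and is a pure
function of (params, seed); identical inputs give byte-identical files.

* **Genome** — i.i.d. uniform {A,C,G,T} background (no GC-skew model);
  planted SSRs rejection-sampled ≥ 300 bp apart with motif lengths drawn
  ~ di 65 % / tri 22 % / mono 5 % / rest 8 % and repeat numbers at the
  detection minimum plus a geometric tail (mean 3). Flanking bases are
  forced to break each planted run so every plant is maximal and
  recoverable at exact coordinates; chance background repeats are allowed
  and handled by recall-based evaluation with brute-force-verified
  precision. Gene models (800 bp) are placed partly within the 2 kbp
  linking window of planted SSRs, the rest uniformly; a 60 % subset of
  gene bodies serves as transcript intervals.
* **Counts** — the study's 12-library design (2 populations × control/
  drought × 3 replicates). Baseline means are log-normal(log 100, 1) and
  dispersions log-normal(log 0.1, 0.5) — chosen so that n = 3 power is
  realistic, not to match any unpublished data moments; library factors
  log-normal(0, 0.15) and recorded in the truth. 10 % of genes per
  population are planted DE with fold changes from {1.5, 2, 3}; 60 % of
  them are drawn from one population-specific "responsive" graph block and
  up-regulated coherently, emulating the stress-responsive functional
  neighborhoods that transcriptograms detect, the rest scattered with
  random direction. SSR-linked genes get an extra 2-fold multiplier in
  SSR-present libraries.
* **Association graph** — stochastic block model, 5 blocks × 40 genes,
  intra-block edge probability 0.3 with scores uniform 801–1000 (all
  survive the > 800 filter), inter-block probability 0.005 with scores
  600–900 straddling the threshold so filtering is exercised.
* **SSR call tables** — 9 transcriptome-style samples per population
  (parameterized independently of the 12 expression libraries, mirroring
  the study's separate evidence sets); each locus draws a diversity
  scenario (exclusive/equal/preferential per population presence
  probabilities) and alleles jitter ±1 around the planted repeat count
  with probability 0.3.

What passing on this generator shows — and what it does not: recovery and
calibration results demonstrate correctness of the algorithms under an
idealized genome (uniform base composition, perfect repeats only, no
sequencing error, no mapping ambiguity) and an idealized count model
(exact NB, gene-independent). Real genomes have compositional structure,
imperfect/interrupted repeats and correlated expression, so measured
power and false-positive rates here do not transfer to real data.

## Problem sizes and numerics

Default analysis scale is a 400 kb genome (4 chromosomes), 200 genes and
a 200-node graph — large enough to exercise every code path and planted
structure while keeping the full pipeline run in seconds. Validation
suites use 2000-replicate null simulations for test calibration, 100
planted loci for link power, and 10 annealing seeds for ordering quality.

Numerical choices: dispersion optimization is bounded golden-section
search over log α ∈ [−12, 6] with the Poisson boundary checked
explicitly; mean solutions under offsets iterate a fixed point to 1e-12
relative tolerance; LRT statistics are floored at 0; p-values are clipped
into (0, 1]; percentages print round-half-up to 2 decimals; BH uses a
stable mergesort so ties keep input order. All randomness flows from
numpy `default_rng` seeds; derived seeds stay below 2³¹.

## Known limitations

* Imperfect (interrupted or approximate) SSRs are out of scope; only
  perfect tandem runs are detected.
* Dispersion is estimated per gene with no information sharing across
  genes; at n = 3 per group the test is calibrated but power-limited (see
  above), so DEG counts on 3-replicate data are conservative.
* The diversity classes are presence-based; allele frequencies and
  population-genetic statistics (heterozygosity, F-statistics) are not
  modeled.
* The annealed ordering is a heuristic minimizer; global optimality is
  only guaranteed (and tested) on small instances.
* Transcribed classification relies on supplied transcript intervals, not
  on independent transcriptome SSR detection.
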