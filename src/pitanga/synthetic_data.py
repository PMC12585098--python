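"""Synthetic datasets with planted ground truth for every pipeline input.

Emulates the study's data shapes: a genome with planted perfect SSRs of
known motif/length/position, gene models at known distances from those
SSRs, the 12-library 2-population x 2-condition x 3-replicate RNA-seq
count design with planted differentially expressed genes and planted
SSR-linked expression effects, per-sample SSR presence/allele call tables
(transcriptome-style, parameterized independently of the expression
libraries), and a block-modular scored association graph. Every generator
is a pure function of (params, seed): same inputs, byte-identical outputs.

Background sequence is i.i.d. uniform {A,C,G,T}; chance background repeats
are possible and expected — evaluation against the planted truth is
recall-based, with precision checked by an independent brute-force scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pitanga.io_formats import (
    GenomicInterval, PipelineConfig, POPULATIONS, write_counts, write_edges,
    write_fasta, write_gff3_genes,
)

BASES = np.array(list("ACGT"))


@dataclass
class SimParams:
    """Generator parameters; defaults are the study's design constants
    (12 libraries: 2 populations x 2 conditions x 3 replicates) at desk
    scale for everything the study does not pin down."""

    # genome
    genome_length: int = 400_000
    n_chromosomes: int = 4
    ssr_rate: float = 5e-4  # planted SSRs per bp
    motif_length_weights: dict[int, float] = field(default_factory=lambda: {
        1: 0.05, 2: 0.65, 3: 0.22, 4: 0.04, 5: 0.02, 6: 0.02,
    })
    extra_repeats_mean: float = 3.0  # geometric tail above the minimum
    min_plant_separation_bp: int = 300
    # gene models
    n_genes: int = 200
    gene_length_bp: int = 800
    n_ssr_adjacent_genes: int = 30
    transcribed_gene_fraction: float = 0.6
    # counts
    replicates: int = 3
    baseline_log_mean: float = np.log(100.0)
    baseline_log_sd: float = 1.0
    dispersion_log_mean: float = np.log(0.1)
    dispersion_log_sd: float = 0.5
    library_factor_log_sd: float = 0.15
    de_fraction: float = 0.1
    fc_grid: tuple[float, ...] = (1.5, 2.0, 3.0)
    ssr_effect_fc: float = 2.0
    # fraction of each population's planted DE genes drawn from one
    # "responsive" graph block and up-regulated coherently, emulating the
    # stress-responsive functional neighborhoods transcriptograms detect
    de_block_fraction: float = 0.6
    responsive_block: dict[str, int] = field(
        default_factory=lambda: {"RE": 0, "RF": 1})
    # association graph
    n_blocks: int = 5
    block_size: int = 40
    p_intra: float = 0.3
    p_inter: float = 0.005
    # SSR call tables (transcriptome-style; independent of the 12 libraries)
    call_samples_per_population: int = 9
    allele_jitter_p: float = 0.3

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(1, self.n_genes + 1)]


@dataclass
class SimTruth:
    """Planted features, recoverable by id."""

    planted_ssrs: list[tuple[str, int, str, int]] = field(default_factory=list)
    de_genes: list[tuple[str, str, float, str]] = field(default_factory=list)
    ssr_linked_genes: list[tuple[str, str, float]] = field(default_factory=list)
    blocks: dict[str, int] = field(default_factory=dict)
    library_factors: dict[str, float] = field(default_factory=dict)
    locus_scenarios: dict[str, str] = field(default_factory=dict)


def _random_motif(rng: np.random.Generator, length: int) -> str:
    from pitanga.ssr_landscape import is_primitive

    while True:
        motif = "".join(rng.choice(BASES, size=length))
        if is_primitive(motif):
            return motif


def simulate_genome(params: SimParams, seed: int
                    ) -> tuple[list[tuple[str, str]], SimTruth,
                               dict[str, GenomicInterval], list[GenomicInterval]]:
    """Uniform-background genome with planted SSRs and gene models.

    Returns (fasta entries, truth, gene models, transcript intervals).
    Planted SSRs are rejection-sampled to be well separated; their flanking
    bases are forced to break the repeat so each plant is a maximal run
    recoverable at exact coordinates. A configured number of genes is
    placed within the 2 kbp linking window of planted SSRs, the rest
    elsewhere; transcript intervals cover a fraction of gene bodies.
    """
    rng = np.random.default_rng(seed)
    config = PipelineConfig()
    chrom_len = params.genome_length // params.n_chromosomes
    chroms = {f"chr{i + 1}": rng.choice(BASES, size=chrom_len)
              for i in range(params.n_chromosomes)}
    truth = SimTruth()

    n_plants = int(round(params.ssr_rate * params.genome_length))
    sep = params.min_plant_separation_bp
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    lengths = np.array(sorted(params.motif_length_weights))
    weights = np.array([params.motif_length_weights[k] for k in lengths], float)
    weights /= weights.sum()

    planted = 0
    attempts = 0
    while planted < n_plants:
        attempts += 1
        if attempts > 200 * n_plants:
            raise ValueError("genome too short for requested SSR plants")
        k = int(rng.choice(lengths, p=weights))
        reps = config.ssr_min_repeats[k] + int(rng.geometric(
            1.0 / params.extra_repeats_mean)) - 1
        span = k * reps
        chrom = f"chr{int(rng.integers(params.n_chromosomes)) + 1}"
        seq = chroms[chrom]
        start = int(rng.integers(sep, chrom_len - span - sep))
        if any(start - sep < e and s < start + span + sep
               for s, e in occupied[chrom]):
            continue
        motif = _random_motif(rng, k)
        unit = np.array(list(motif))
        seq[start:start + span] = np.tile(unit, reps)
        # break the repeat at both flanks so the planted run is maximal
        left_partner = seq[start - 1 + k]
        seq[start - 1] = rng.choice([b for b in "ACGT" if b != left_partner])
        right_partner = seq[start + span - k]
        seq[start + span] = rng.choice([b for b in "ACGT" if b != right_partner])
        occupied[chrom].append((start, start + span))
        truth.planted_ssrs.append((chrom, start, motif, reps))
        planted += 1

    truth.planted_ssrs.sort()

    # gene models: some deliberately within the linking window of a plant
    genes: dict[str, GenomicInterval] = {}
    gene_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    gene_ids = params.gene_ids()
    gi = 0
    for chrom, start, motif, reps in truth.planted_ssrs:
        if gi >= min(params.n_ssr_adjacent_genes, len(gene_ids)):
            break
        ssr_end = start + len(motif) * reps
        gap = int(rng.integers(50, 1500))
        g_start = ssr_end + gap
        g_end = g_start + params.gene_length_bp
        if g_end >= chrom_len - 1:
            continue
        if any(g_start < e and s < g_end for s, e in gene_spans[chrom]):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        genes[gene_ids[gi]] = GenomicInterval(chrom, g_start, g_end, strand)
        gene_spans[chrom].append((g_start, g_end))
        gi += 1
    attempts = 0
    while gi < len(gene_ids):
        attempts += 1
        if attempts > 200 * len(gene_ids):
            raise ValueError("genome too short for requested gene models")
        chrom = f"chr{int(rng.integers(params.n_chromosomes)) + 1}"
        g_start = int(rng.integers(0, chrom_len - params.gene_length_bp - 1))
        g_end = g_start + params.gene_length_bp
        if any(g_start < e and s < g_end for s, e in gene_spans[chrom]):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        genes[gene_ids[gi]] = GenomicInterval(chrom, g_start, g_end, strand)
        gene_spans[chrom].append((g_start, g_end))
        gi += 1

    transcripts = [iv for g, iv in sorted(genes.items())
                   if rng.random() < params.transcribed_gene_fraction]
    entries = [(name, "".join(arr)) for name, arr in chroms.items()]
    return entries, truth, genes, transcripts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             alpha: np.ndarray) -> np.ndarray:
    """NB(mean, alpha) draws; alpha -> 0 falls back to Poisson."""
    mean = np.asarray(mean, float)
    alpha = np.broadcast_to(np.asarray(alpha, float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = alpha <= 1e-12
    out[pois] = rng.poisson(mean[pois])
    r = 1.0 / alpha[~pois]
    p = r / (r + mean[~pois])
    out[~pois] = rng.negative_binomial(r, p)
    return out


def sample_names(params: SimParams) -> list[str]:
    return [f"{pop}_{cond}_{rep}" for pop in POPULATIONS
            for cond in ("control", "drought")
            for rep in range(1, params.replicates + 1)]


def simulate_counts(params: SimParams, seed: int,
                    ssr_effects: dict[str, tuple[str, float, set[str]]] | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Gene x sample NB counts for the 2x2x`replicates` design.

    Baseline means and dispersions are log-normal across genes; library
    size factors are log-normal and recorded in the truth. A `de_fraction`
    of genes per population gets a fold change from `fc_grid` (direction
    50/50) applied in that population's drought libraries. `ssr_effects`
    (gene -> (locus, fold change, present sample set)) multiplies the mean
    in SSR-present samples, planting SSR-linked expression.
    """
    rng = np.random.default_rng(seed)
    genes = params.gene_ids()
    names = sample_names(params)
    sheet = pd.DataFrame(
        [{"population": s.split("_")[0], "condition": s.split("_")[1],
          "replicate": int(s.split("_")[2])} for s in names],
        index=pd.Index(names, name="sample"),
    )
    truth = SimTruth()
    mu = rng.lognormal(params.baseline_log_mean, params.baseline_log_sd,
                       size=len(genes))
    alpha = rng.lognormal(params.dispersion_log_mean, params.dispersion_log_sd,
                          size=len(genes))
    lib = rng.lognormal(0.0, params.library_factor_log_sd, size=len(names))
    truth.library_factors = dict(zip(names, lib.tolist()))

    fc_mult = np.ones((len(genes), len(names)))
    n_de = int(round(params.de_fraction * len(genes)))
    gene_index = {g: i for i, g in enumerate(genes)}
    n_in_blocks = min(params.n_blocks * params.block_size, len(genes))
    for pop in POPULATIONS:
        block = params.responsive_block.get(pop)
        block_pool = [i for i in range(n_in_blocks)
                      if block is not None
                      and i // params.block_size == block]
        n_block = min(int(round(params.de_block_fraction * n_de)),
                      len(block_pool))
        in_block = (rng.choice(block_pool, size=n_block, replace=False)
                    if n_block else np.array([], dtype=int))
        rest_pool = [i for i in range(len(genes)) if i not in set(in_block)]
        scattered = rng.choice(rest_pool, size=n_de - n_block, replace=False)
        drought_cols = [j for j, s in enumerate(names)
                        if sheet.iloc[j]["population"] == pop
                        and sheet.iloc[j]["condition"] == "drought"]
        for gi in in_block:
            # coherent up-regulation: one stress-responsive neighborhood
            fc = float(rng.choice(params.fc_grid))
            fc_mult[gi, drought_cols] *= fc
            truth.de_genes.append((genes[gi], pop, fc, "up"))
        for gi in scattered:
            fc = float(rng.choice(params.fc_grid))
            direction = "up" if rng.random() < 0.5 else "down"
            mult = fc if direction == "up" else 1.0 / fc
            fc_mult[gi, drought_cols] *= mult
            truth.de_genes.append((genes[gi], pop, fc, direction))

    if ssr_effects:
        for gene, (locus_id, fc, present) in ssr_effects.items():
            gi = gene_index[gene]
            cols = [j for j, s in enumerate(names) if s in present]
            fc_mult[gi, cols] *= fc
            truth.ssr_linked_genes.append((gene, locus_id, fc))

    mean = mu[:, None] * fc_mult * lib[None, :]
    counts = _nb_draw(rng, mean, alpha[:, None])
    matrix = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                          columns=names)
    return matrix, sheet, truth


def simulate_ppi(params: SimParams, seed: int
                 ) -> tuple[list[tuple[str, str, int]], SimTruth]:
    """Stochastic-block-model scored edge list over the gene universe.

    Intra-block edges (probability `p_intra`) score uniformly in 801-1000,
    so all survive the > 800 filter; inter-block edges (probability
    `p_inter`) score uniformly in 600-900, straddling the threshold so
    filtering is exercised. Block membership is recorded in the truth.
    """
    if params.block_size < 2:
        raise ValueError("block size must be >= 2")
    rng = np.random.default_rng(seed)
    genes = params.gene_ids()
    n_in_blocks = params.n_blocks * params.block_size
    if n_in_blocks > len(genes):
        raise ValueError("n_blocks x block_size exceeds the gene universe")
    truth = SimTruth()
    for i, g in enumerate(genes[:n_in_blocks]):
        truth.blocks[g] = i // params.block_size
    edges = []
    for i in range(n_in_blocks):
        for j in range(i + 1, n_in_blocks):
            same = truth.blocks[genes[i]] == truth.blocks[genes[j]]
            if same and rng.random() < params.p_intra:
                score = int(rng.integers(801, 1001))
            elif not same and rng.random() < params.p_inter:
                score = int(rng.integers(600, 901))
            else:
                continue
            edges.append((genes[i], genes[j], score))
    return edges, truth


#: presence probability per population for each planted diversity scenario
SCENARIOS = {
    "exclusive_RE": (0.95, 0.0),
    "exclusive_RF": (0.0, 0.95),
    "equal": (0.9, 0.9),
    "preferential_RE": (0.95, 0.5),
    "preferential_RF": (0.5, 0.95),
}


def simulate_ssr_calls(params: SimParams, seed: int,
                       loci: list[tuple[str, int]],
                       samples: list[tuple[str, str]] | None = None
                       ) -> tuple[pd.DataFrame, SimTruth]:
    """Per-sample SSR presence/allele calls over the given loci.

    ``loci`` is a list of (locus_id, planted repeat count); ``samples`` a
    list of (sample, population), defaulting to
    `call_samples_per_population` transcriptome-style samples per
    population. Each locus is assigned a diversity scenario whose
    population-specific presence probabilities force exclusive / equal /
    preferential structure by construction; observed alleles jitter around
    the planted repeat count.
    """
    rng = np.random.default_rng(seed)
    if samples is None:
        samples = [(f"{pop}_T{i:02d}", pop)
                   for pop in POPULATIONS
                   for i in range(1, params.call_samples_per_population + 1)]
    truth = SimTruth()
    names = list(SCENARIOS)
    rows = []
    for locus_id, planted_reps in loci:
        scenario = names[int(rng.integers(len(names)))]
        truth.locus_scenarios[locus_id] = scenario
        p_re, p_rf = SCENARIOS[scenario]
        for sample, pop in samples:
            p = p_re if pop == "RE" else p_rf
            if rng.random() < p:
                allele = planted_reps
                if rng.random() < params.allele_jitter_p:
                    allele = max(1, allele + int(rng.choice([-1, 1])))
                rows.append((sample, pop, locus_id, allele))
    calls = pd.DataFrame(rows, columns=["sample", "population", "locus_id",
                                        "repeat_count"])
    return calls, truth


def simulate_term_map(params: SimParams, seed: int,
                      blocks: dict[str, int]) -> dict[str, set[str]]:
    """Gene -> term map with one block-aligned term per graph block (80%
    coverage inside the block) plus a diffuse background term."""
    rng = np.random.default_rng(seed)
    term_map: dict[str, set[str]] = {}
    for gene in params.gene_ids():
        terms = set()
        block = blocks.get(gene)
        if block is not None and rng.random() < 0.8:
            terms.add(f"TERM:{block:04d}")
        if rng.random() < 0.2:
            terms.add("TERM:broad")
        if terms:
            term_map[gene] = terms
    return term_map


def presence_table(calls: pd.DataFrame,
                   samples: list[str]) -> dict[str, dict[str, bool]]:
    """Collapse allele calls into per-locus {sample: present} tables over
    the given sample universe."""
    by_locus: dict[str, dict[str, bool]] = {}
    for locus_id, grp in calls.groupby("locus_id"):
        seen = set(grp["sample"])
        by_locus[str(locus_id)] = {s: s in seen for s in samples}
    return by_locus


def simulate_all(params: SimParams, outdir, seed: int) -> dict[str, str]:
    """Write one complete self-consistent dataset plus truth tables.

    Produces genome.fasta, genes.gff3, counts.tsv + samples.tsv, edges.tsv,
    term_map.tsv, ssr_calls.tsv (transcriptome samples) and
    expression_presence.tsv (expression libraries), with truth_*.tsv files
    alongside. Returns the path map.
    """
    from pathlib import Path

    from pitanga.ssr_landscape import detect_ssrs, merge_loci

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=5)]

    entries, g_truth, genes, transcripts = simulate_genome(params, sub[0])
    paths = {"genome": str(outdir / "genome.fasta"),
             "genes": str(outdir / "genes.gff3"),
             "transcripts": str(outdir / "transcripts.tsv"),
             "counts": str(outdir / "counts.tsv"),
             "samples": str(outdir / "samples.tsv"),
             "edges": str(outdir / "edges.tsv"),
             "term_map": str(outdir / "term_map.tsv"),
             "ssr_calls": str(outdir / "ssr_calls.tsv"),
             "expression_presence": str(outdir / "expression_presence.tsv")}
    write_fasta(entries, paths["genome"])
    write_gff3_genes(genes, paths["genes"])
    with open(paths["transcripts"], "w") as fh:
        fh.write("seq_id\tstart\tend\n")
        for iv in transcripts:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\n")

    # loci from the planted genome drive the call tables
    config = PipelineConfig()
    records = [r for name, seq in entries for r in detect_ssrs(name, seq, config)]
    loci = merge_loci([r for r in records if not r.is_compound],
                      config.merge_window_bp)
    locus_reps = [(l.locus_id, l.n_repeats) for l in loci]
    calls, call_truth = simulate_ssr_calls(params, sub[1], locus_reps)
    calls.to_csv(paths["ssr_calls"], sep="\t", index=False)

    # expression-library presence for SSR-linked effect planting
    expr_samples = [(s, s.split("_")[0]) for s in sample_names(params)]
    expr_calls, _ = simulate_ssr_calls(params, sub[2], locus_reps, expr_samples)
    expr_calls.to_csv(paths["expression_presence"], sep="\t", index=False)

    # plant SSR-linked expression effects for genes near planted SSRs
    from pitanga.ssr_expression_link import link_ssrs_to_genes

    links = link_ssrs_to_genes(loci, genes, config.link_window_bp)
    presence = presence_table(expr_calls, [s for s, _ in expr_samples])
    ssr_effects = {}
    for link in links[:params.n_ssr_adjacent_genes]:
        if link.gene_id in ssr_effects or link.locus_id not in presence:
            continue
        present = {s for s, flag in presence[link.locus_id].items() if flag}
        if 2 <= len(present) <= len(expr_samples) - 2:
            ssr_effects[link.gene_id] = (link.locus_id, params.ssr_effect_fc,
                                         present)
    counts, sheet, c_truth = simulate_counts(params, sub[3], ssr_effects)
    write_counts(counts, sheet, paths["counts"], paths["samples"])

    edges, p_truth = simulate_ppi(params, sub[4])
    write_edges(edges, paths["edges"])
    term_map = simulate_term_map(params, sub[4] + 1, p_truth.blocks)
    with open(paths["term_map"], "w") as fh:
        for gene in sorted(term_map):
            for term in sorted(term_map[gene]):
                fh.write(f"{gene}\t{term}\n")

    # truth tables
    pd.DataFrame(g_truth.planted_ssrs,
                 columns=["seq_id", "start", "motif", "n_repeats"]
                 ).to_csv(outdir / "truth_ssrs.tsv", sep="\t", index=False)
    pd.DataFrame(c_truth.de_genes,
                 columns=["gene_id", "population", "fold_change", "direction"]
                 ).to_csv(outdir / "truth_de_genes.tsv", sep="\t", index=False)
    pd.DataFrame(c_truth.ssr_linked_genes,
                 columns=["gene_id", "locus_id", "fold_change"]
                 ).to_csv(outdir / "truth_ssr_linked.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(p_truth.blocks.items()), columns=["gene_id", "block"]
                 ).to_csv(outdir / "truth_blocks.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(call_truth.locus_scenarios.items()),
                 columns=["locus_id", "scenario"]
                 ).to_csv(outdir / "truth_locus_scenarios.tsv", sep="\t",
                          index=False)
    return paths
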