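"""End-to-end orchestration: simulate or load inputs, run every stage,
write one report bundle.

Stages communicate only through serialized files, so each stage can be
re-run in isolation and every number in the summary can be recomputed from
the stage outputs shipped in the bundle. Outputs carry no timestamps:
a fixed seed and config reproduce the bundle byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from pitanga import io_formats, ssr_landscape, ssr_population, \
    expression_stats, transcriptogram, ssr_expression_link, synthetic_data
from pitanga.io_formats import GenomicInterval, PipelineConfig, POPULATIONS

logger = logging.getLogger("pitanga")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config: PipelineConfig, outdir: str | Path, seed: int = 1,
             input_dir: str | Path | None = None,
             sim_params: synthetic_data.SimParams | None = None,
             ordering_sweeps: int = 60) -> dict:
    """Run every stage on a simulated (or supplied) dataset and write the
    report bundle under ``outdir``. Returns the summary dictionary.

    Stage order: simulate -> SSR scan/merge/transcribed -> landscape +
    class bias -> population diversity -> DEG calling per population ->
    Venn partition -> transcriptogram (order, project, test, peaks,
    candidate selection) -> SSR-gene linking -> per-link NB LRT + BH ->
    term overrepresentation -> summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data_dir = Path(input_dir) if input_dir else outdir / "inputs"

    if input_dir is None:
        sim_params = sim_params or synthetic_data.SimParams()
        paths = synthetic_data.simulate_all(sim_params, data_dir, seed)
    else:
        paths = {k: str(data_dir / v) for k, v in {
            "genome": "genome.fasta", "genes": "genes.gff3",
            "transcripts": "transcripts.tsv", "counts": "counts.tsv",
            "samples": "samples.tsv", "edges": "edges.tsv",
            "term_map": "term_map.tsv", "ssr_calls": "ssr_calls.tsv",
            "expression_presence": "expression_presence.tsv",
        }.items()}
        missing = [k for k, p in paths.items() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input(s): {missing}")

    # --- SSR landscape ---------------------------------------------------
    entries = io_formats.read_fasta(paths["genome"])
    genome_size = sum(len(s) for _, s in entries)
    records = [r for name, seq in entries
               for r in ssr_landscape.detect_ssrs(name, seq, config)]
    loci = ssr_landscape.merge_loci(
        [r for r in records if not r.is_compound], config.merge_window_bp)
    transcripts = [
        GenomicInterval(row.seq_id, int(row.start), int(row.end))
        for row in pd.read_csv(paths["transcripts"], sep="\t").itertuples()
    ]
    loci = ssr_landscape.classify_transcribed(loci, transcripts)
    seq_lengths = {name: len(seq) for name, seq in entries}
    io_formats.write_gff3_ssr(loci, outdir / "ssr_loci.gff3", seq_lengths)

    summary = ssr_landscape.landscape_summary(records, loci, genome_size)
    bias = ssr_landscape.chi2_class_bias(
        summary.counts_by_class, config.min_class_representation,
        config.chi2_alpha)
    pd.DataFrame([vars(b) for b in bias]).to_csv(
        outdir / "class_bias.tsv", sep="\t", index=False)

    # --- population diversity -------------------------------------------
    calls_df = pd.read_csv(paths["ssr_calls"], sep="\t")
    table = ssr_population.tabulate_alleles(
        list(calls_df.itertuples(index=False, name=None)))
    motif_len = {l.locus_id: len(l.motif) for l in loci}
    transcribed = {l.locus_id: l.transcribed for l in loci}
    div = ssr_population.diversity_summary(table, motif_len, transcribed)
    div.to_csv(outdir / "diversity_summary.tsv", sep="\t")
    e_re = int(div["exclusive_RE"].sum())
    e_rf = int(div["exclusive_RF"].sum())
    if e_re + e_rf > 0:
        excl_stat, excl_p = ssr_population.chi2_exclusive_bias(e_re, e_rf)
    else:
        excl_stat, excl_p = None, None

    # --- differential expression ----------------------------------------
    counts, sheet = io_formats.read_counts(paths["counts"], paths["samples"])
    deg_results = {}
    deg_counts = {}
    for pop in POPULATIONS:
        res = expression_stats.call_degs(
            counts, sheet, pop, config.fc_threshold, config.p_deg)
        deg_results[pop] = res
        pd.DataFrame([vars(r) for r in res]).to_csv(
            outdir / f"deg_{pop}.tsv", sep="\t", index=False)
        deg_counts[pop] = {
            "up": sum(r.direction == "up" for r in res),
            "down": sum(r.direction == "down" for r in res),
        }
        deg_counts[pop]["total"] = deg_counts[pop]["up"] + deg_counts[pop]["down"]
    venn = expression_stats.venn_partition(deg_results["RE"], deg_results["RF"])
    with open(outdir / "venn.json", "w") as fh:
        json.dump({k: sorted(v) for k, v in venn.items()}, fh, indent=1,
                  sort_keys=True)

    # --- transcriptogram --------------------------------------------------
    edges = io_formats.read_edges(paths["edges"])
    graph = transcriptogram.filter_graph(edges, config.score_threshold)
    peak_counts = {}
    selected = {}
    if graph.number_of_nodes() > 2 * config.window_radius + 1:
        ordering = transcriptogram.build_ordering(
            graph, seed=seed, n_iterations=ordering_sweeps)
        pd.Series(ordering, name="gene_id").to_csv(
            outdir / "gene_ordering.tsv", sep="\t", index_label="position")
        sf = expression_stats.size_factors(counts)
        norm = counts / sf
        log_norm = np.log2(norm + 1.0)
        for pop in POPULATIONS:
            cols = {cond: [s for s in counts.columns
                           if sheet.loc[s, "population"] == pop
                           and sheet.loc[s, "condition"] == cond]
                    for cond in ("control", "drought")}
            prof = {}
            for r, tag in ((config.window_radius, "r30"), (0, "r0")):
                prof[tag] = {
                    cond: np.vstack([
                        transcriptogram.project(
                            ordering, log_norm[c].to_dict(), radius=r)
                        for c in cols[cond]])
                    for cond in cols
                }
            p_r30 = transcriptogram.profile_tests(prof["r30"]["drought"],
                                                  prof["r30"]["control"])
            p_r0 = transcriptogram.profile_tests(prof["r0"]["drought"],
                                                 prof["r0"]["control"])
            lin = {cond: np.vstack([
                transcriptogram.project(ordering, norm[c].to_dict(),
                                        radius=config.window_radius)
                for c in cols[cond]]) for cond in cols}
            ratio, band = transcriptogram.relative_profile(
                lin["drought"], lin["control"])
            pd.DataFrame({
                "position": np.arange(len(ordering)), "gene_id": ordering,
                "relative_expression": ratio, "band_sd": band,
                "p_r30": p_r30, "p_r0": p_r0,
            }).to_csv(outdir / f"transcriptogram_{pop}.tsv", sep="\t",
                      index=False)
            peaks = transcriptogram.call_peaks(p_r30, config.p_r30, ordering)
            peak_counts[pop] = len(peaks)
            pd.DataFrame([{"start": p.start, "end": p.end, "min_p": p.min_p,
                           "n_genes": len(p.genes)} for p in peaks],
                         columns=["start", "end", "min_p", "n_genes"]
                         ).to_csv(outdir / f"peaks_{pop}.tsv", sep="\t",
                                  index=False)
            gene_p = {r.gene_id: r.p for r in deg_results[pop]}
            selected[pop] = transcriptogram.select_candidate_degs(
                ordering, p_r30, p_r0, gene_p,
                config.p_r30, config.p_r0, config.p_deg)
            pd.Series(selected[pop], name="gene_id").to_csv(
                outdir / f"candidates_{pop}.tsv", sep="\t", index=False)
    else:
        logger.warning("association graph too small for transcriptogram")

    # --- SSR-expression linking ------------------------------------------
    gene_models = {gid: iv for gid, iv, _ in
                   io_formats.read_gff3(paths["genes"], "gene")}
    links = ssr_expression_link.link_ssrs_to_genes(
        loci, gene_models, config.link_window_bp)
    expr_calls = pd.read_csv(paths["expression_presence"], sep="\t")
    presence = synthetic_data.presence_table(expr_calls, list(counts.columns))
    tests = ssr_expression_link.run_all_ssr_tests(links, counts, presence)
    pd.DataFrame([vars(t) for t in tests]).to_csv(
        outdir / "ssr_expression_tests.tsv", sep="\t", index=False)

    term_map = io_formats.read_term_map(paths["term_map"])
    study = sorted({l.gene_id for l in links})
    enrich = ssr_expression_link.fisher_overrepresentation(
        set(study), set(counts.index), term_map)
    pd.DataFrame([vars(e) for e in enrich]).to_csv(
        outdir / "ssr_gene_enrichment.tsv", sep="\t", index=False)

    # --- report -----------------------------------------------------------
    n_sig_links = sum(1 for t in tests if t.testable and t.q < config.p_deg)
    report = {
        "config": config.snapshot(),
        "seed": seed,
        "genome_size_bp": genome_size,
        "ssr": {
            "total": summary.total_ssrs,
            "n_compound": summary.n_compound,
            "by_motif_length": summary.counts_by_motif_length,
            "density_per_mb": summary.density_per_mb,
            "n_loci": len(loci),
            "n_transcribed_loci": sum(l.transcribed for l in loci),
        },
        "diversity": {
            "exclusive_RE": e_re, "exclusive_RF": e_rf,
            "exclusive_chi2_stat": excl_stat, "exclusive_chi2_p": excl_p,
        },
        "deg": deg_counts,
        "venn": {k: len(v) for k, v in venn.items()},
        "peaks": peak_counts,
        "candidates": {pop: len(genes) for pop, genes in selected.items()},
        "ssr_link": {
            "n_links": len(links),
            "n_testable": sum(t.testable for t in tests),
            "n_significant_q": n_sig_links,
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)

    manifest = {
        "config": config.snapshot(),
        "seed": seed,
        "inputs": {k: _sha256(Path(p)) for k, p in sorted(paths.items())},
        "stages": ["ssr", "population", "deg", "venn", "transcriptogram",
                   "link", "enrich", "report"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return report


def report_summary(report: dict) -> str:
    """Human-readable summary of a report bundle."""
    ssr = report["ssr"]
    lines = [
        "SSR landscape",
        f"  total SSRs (monomers excluded): {ssr['total']}",
        f"  in compound formation: {ssr['n_compound']}",
    ]
    for k, v in sorted(ssr["by_motif_length"].items()):
        lines.append(f"  motif length {k}: {v}")
    lines += [
        f"  density (u/Mb): {ssr['density_per_mb']}",
        f"  loci: {ssr['n_loci']} ({ssr['n_transcribed_loci']} transcribed)",
        "Differential expression",
    ]
    for pop, d in report["deg"].items():
        lines.append(f"  {pop}: {d['total']} DEGs ({d['up']} up, {d['down']} down)")
    lines.append("Transcriptogram peaks (p < 0.01, radius 30)")
    for pop, n in report.get("peaks", {}).items():
        lines.append(f"  {pop}: {n}")
    for pop, n in report.get("candidates", {}).items():
        lines.append(f"  {pop} candidate genes: {n}")
    link = report["ssr_link"]
    lines += [
        "SSR-expression links",
        f"  links: {link['n_links']}, testable: {link['n_testable']}, "
        f"q < 0.05: {link['n_significant_q']}",
    ]
    return "\n".join(lines)
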