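"""Transcriptogram profiling: order genes by association, project expression.

Filters the scored network at combined score > 800, arranges the retained
genes on a line by simulated annealing, projects log2 normalized
expression with radius-30 window averages, compares drought to control
per position (Welch test at radius 30 and radius 0), calls p < 0.01
peaks, and applies the combined candidate-gene selection. Writes the
ordering, per-position profiles, peaks and candidate lists under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pitanga import expression_stats, io_formats, transcriptogram
from pitanga.io_formats import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    cfg = PipelineConfig()
    edges = io_formats.read_edges(ROOT / "dataset" / "edges.tsv")
    graph = transcriptogram.filter_graph(edges, cfg.score_threshold)
    ordering = transcriptogram.build_ordering(graph, seed=SEED)
    pd.Series(ordering, name="gene_id").to_csv(
        ROOT / "gene_ordering.tsv", sep="\t", index_label="position")
    print(f"graph: {graph.number_of_nodes()} genes, "
          f"{graph.number_of_edges()} edges above {cfg.score_threshold}")

    counts, sheet = io_formats.read_counts(ROOT / "dataset" / "counts.tsv",
                                           ROOT / "dataset" / "samples.tsv")
    sf = expression_stats.size_factors(counts)
    norm = counts / sf
    log_norm = np.log2(norm + 1.0)

    for pop in ("RE", "RF"):
        cols = {cond: [s for s in counts.columns
                       if sheet.loc[s, "population"] == pop
                       and sheet.loc[s, "condition"] == cond]
                for cond in ("control", "drought")}
        win = {}
        for radius, tag in ((cfg.window_radius, "r30"), (0, "r0")):
            win[tag] = {cond: np.vstack([
                transcriptogram.project(ordering, log_norm[c].to_dict(), radius)
                for c in cols[cond]]) for cond in cols}
        p_r30 = transcriptogram.profile_tests(win["r30"]["drought"],
                                              win["r30"]["control"])
        p_r0 = transcriptogram.profile_tests(win["r0"]["drought"],
                                             win["r0"]["control"])
        lin = {cond: np.vstack([
            transcriptogram.project(ordering, norm[c].to_dict(),
                                    cfg.window_radius)
            for c in cols[cond]]) for cond in cols}
        ratio, band = transcriptogram.relative_profile(lin["drought"],
                                                       lin["control"])
        pd.DataFrame({"position": np.arange(len(ordering)),
                      "gene_id": ordering, "relative_expression": ratio,
                      "band_sd": band, "p_r30": p_r30, "p_r0": p_r0}
                     ).to_csv(ROOT / f"transcriptogram_{pop}.tsv", sep="\t",
                              index=False)

        peaks = transcriptogram.call_peaks(p_r30, cfg.p_r30, ordering)
        pd.DataFrame([{"start": p.start, "end": p.end, "min_p": p.min_p,
                       "n_genes": len(p.genes)} for p in peaks],
                     columns=["start", "end", "min_p", "n_genes"]).to_csv(
            ROOT / f"peaks_{pop}.tsv", sep="\t", index=False)

        deg = pd.read_csv(ROOT / f"deg_{pop}.tsv", sep="\t")
        gene_p = dict(zip(deg["gene_id"], deg["p"]))
        selected = transcriptogram.select_candidate_degs(
            ordering, p_r30, p_r0, gene_p, cfg.p_r30, cfg.p_r0, cfg.p_deg)
        pd.Series(selected, name="gene_id").to_csv(
            ROOT / f"candidates_{pop}.tsv", sep="\t", index=False)
        print(f"{pop}: {len(peaks)} peaks at p < {cfg.p_r30}; "
              f"{len(selected)} combined candidate genes")


if __name__ == "__main__":
    main()
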