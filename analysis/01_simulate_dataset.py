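"""Generate the synthetic study dataset with planted ground truth.

Writes a genome with planted SSRs, gene models, the 12-library count
matrix (2 populations x control/drought x 3 replicates) with planted DE
and SSR-linked effects, per-sample SSR call tables, a block-modular
scored association network and a gene-term map to results/dataset/,
with truth_*.tsv tables alongside.
"""

from pathlib import Path

from pitanga.synthetic_data import SimParams, simulate_all

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "dataset"


def main() -> None:
    params = SimParams()
    paths = simulate_all(params, OUT, SEED)
    print(f"dataset written to {OUT} (seed {SEED})")
    for key, path in sorted(paths.items()):
        print(f"  {key}: {Path(path).name}")
    print(f"genome: {params.genome_length:,} bp on {params.n_chromosomes} "
          f"chromosomes; {params.n_genes} genes; "
          f"~{int(params.ssr_rate * params.genome_length)} planted SSRs")


if __name__ == "__main__":
    main()
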