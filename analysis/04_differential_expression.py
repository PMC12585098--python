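"""Call drought-vs-control DEGs per population and partition the Venn bins.

Per population: size-factor normalization, per-gene NB likelihood-ratio
test, DEG call at |FC| >= 1.5 and p < 0.05. The two populations' DEG sets
are partitioned into shared / unique / discordant bins. Writes per-gene
result tables and the Venn partition under results/, and reports recovery
of the planted DE truth.
"""

import json
from pathlib import Path

import pandas as pd

from pitanga import expression_stats, io_formats

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts, sheet = io_formats.read_counts(ROOT / "dataset" / "counts.tsv",
                                           ROOT / "dataset" / "samples.tsv")
    truth = pd.read_csv(ROOT / "dataset" / "truth_de_genes.tsv", sep="\t")
    results = {}
    for pop in ("RE", "RF"):
        res = expression_stats.call_degs(counts, sheet, pop)
        results[pop] = res
        pd.DataFrame([vars(r) for r in res]).to_csv(
            ROOT / f"deg_{pop}.tsv", sep="\t", index=False)
        up = sum(r.direction == "up" for r in res)
        down = sum(r.direction == "down" for r in res)
        planted = set(truth.loc[truth["population"] == pop, "gene_id"])
        called = {r.gene_id for r in res if r.direction != "ns"}
        print(f"{pop}: {up + down} DEGs ({up} up, {down} down); "
              f"recovered {len(called & planted)}/{len(planted)} planted "
              f"(power is replicate-limited at n=3)")

    venn = expression_stats.venn_partition(results["RE"], results["RF"])
    with open(ROOT / "venn.json", "w") as fh:
        json.dump({k: sorted(v) for k, v in venn.items()}, fh, indent=1,
                  sort_keys=True)
    print("venn:", {k: len(v) for k, v in venn.items()})


if __name__ == "__main__":
    main()
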