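"""Collect the stage outputs into one summary report.

Recounts every headline number directly from the stage TSVs written by
scripts 02-06 and prints a study-style summary; also reproduces the
published report arithmetic (SSR density, DEG totals, gene filter
accounting) from the printed table inputs as a self-check of the
reporting utilities.
"""

import json
from pathlib import Path

import pandas as pd

from pitanga.io_formats import filter_accounting, percent_report
from pitanga.ssr_landscape import density_per_mb

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    landscape = pd.read_csv(ROOT / "landscape_summary.tsv", sep="\t",
                            index_col=0)["value"]
    print("SSR landscape (simulated genome)")
    for metric, value in landscape.items():
        print(f"  {metric}: {value}")

    div = pd.read_csv(ROOT / "diversity_summary.tsv", sep="\t", index_col=0)
    print("population diversity class totals:",
          {c: int(div[c].sum()) for c in
           ("exclusive_RE", "exclusive_RF", "equal",
            "preferential_RE", "preferential_RF", "ambiguous")})

    for pop in ("RE", "RF"):
        deg = pd.read_csv(ROOT / f"deg_{pop}.tsv", sep="\t")
        up = int((deg["direction"] == "up").sum())
        down = int((deg["direction"] == "down").sum())
        peaks = pd.read_csv(ROOT / f"peaks_{pop}.tsv", sep="\t")
        print(f"{pop}: {up + down} DEGs ({up} up + {down} down), "
              f"{len(peaks)} transcriptogram peaks")
    venn = json.loads((ROOT / "venn.json").read_text())
    print("venn bins:", {k: len(v) for k, v in venn.items()})

    tests = pd.read_csv(ROOT / "ssr_expression_tests.tsv", sep="\t")
    print(f"SSR-expression: {len(tests)} links, "
          f"{int(tests['testable'].sum())} testable, "
          f"{int(((tests['q'] < 0.05) & tests['testable']).sum())} at q<0.05")

    print("\npublished-table arithmetic self-check")
    total = 38239 + 13243 + 1533 + 607 + 465 + 932
    print(f"  SSR total {total}, density "
          f"{density_per_mb(total, 385104457)} u/Mb")
    print(f"  DEG totals RE {5906 + 5232}, RF {4657 + 2650}")
    print(f"  protein-coding genes {filter_accounting(32201, [95, 414, 245, 784])}")
    print(f"  annotated specific genes {percent_report(888, 2219)}%")


if __name__ == "__main__":
    main()
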