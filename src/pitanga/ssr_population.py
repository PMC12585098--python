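"""Population comparison of SSR allele content.

Each locus's allelic diversity (allele = repeat count) observed in the two
source populations — Restinga (RE) and Riparian Forest (RF) — is classified
as exclusive to one population, equal (identical allele sets), or
preferential (strictly more distinct alleles in one population). Differing
sets of equal size carry no direction and land in an explicit "ambiguous"
bin rather than being forced into a class.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd
from scipy import stats

from pitanga.io_formats import POPULATIONS


class DiversityClass(str, Enum):
    exclusive_RE = "exclusive_RE"
    exclusive_RF = "exclusive_RF"
    equal = "equal"
    preferential_RE = "preferential_RE"
    preferential_RF = "preferential_RF"
    ambiguous = "ambiguous"


@dataclass
class AlleleTable:
    """Per-locus allele sets (repeat counts) observed in each population."""

    loci: dict[str, dict[str, set[int]]]

    def alleles(self, locus_id: str, population: str) -> set[int]:
        return self.loci.get(locus_id, {}).get(population, set())


def tabulate_alleles(
    per_sample_calls: list[tuple[str, str, str, int]]
) -> AlleleTable:
    """Union per-sample allele calls (sample, population, locus, repeat
    count) into per-(locus, population) allele sets."""
    loci: dict[str, dict[str, set[int]]] = {}
    for sample, population, locus_id, repeat_count in per_sample_calls:
        if population not in POPULATIONS:
            raise ValueError(
                f"unknown population {population!r} for sample {sample!r}"
            )
        if repeat_count < 1:
            raise ValueError(
                f"repeat count must be >= 1, got {repeat_count} at {locus_id}"
            )
        entry = loci.setdefault(
            locus_id, {p: set() for p in POPULATIONS}
        )
        entry[population].add(repeat_count)
    return AlleleTable(loci)


def classify_diversity(re_alleles: set[int], rf_alleles: set[int]) -> DiversityClass:
    """Classify one locus's allele distribution across the two populations."""
    if not re_alleles and not rf_alleles:
        raise ValueError("cannot classify a locus with no observed alleles")
    if not rf_alleles:
        return DiversityClass.exclusive_RE
    if not re_alleles:
        return DiversityClass.exclusive_RF
    if re_alleles == rf_alleles:
        return DiversityClass.equal
    if len(re_alleles) > len(rf_alleles):
        return DiversityClass.preferential_RE
    if len(rf_alleles) > len(re_alleles):
        return DiversityClass.preferential_RF
    # differing sets of equal size: each population holds at least one
    # private allele, so no direction is defensible
    return DiversityClass.ambiguous


def diversity_summary(table: AlleleTable,
                      locus_motif_length: dict[str, int],
                      locus_transcribed: dict[str, bool] | None = None) -> pd.DataFrame:
    """Cross-tabulate diversity classes by motif length.

    Returns a DataFrame indexed by motif length with one column per
    DiversityClass plus, when transcribed flags are supplied, a
    ``<class>_transcribed`` column restricted to transcribed loci.
    """
    classes = [c.value for c in DiversityClass]
    lengths = sorted(set(locus_motif_length.values())) or [1]
    cols = list(classes)
    if locus_transcribed is not None:
        cols += [f"{c}_transcribed" for c in classes]
    out = pd.DataFrame(0, index=pd.Index(lengths, name="motif_length"), columns=cols)
    for locus_id, pops in table.loci.items():
        if locus_id not in locus_motif_length:
            continue
        cls = classify_diversity(pops.get("RE", set()), pops.get("RF", set())).value
        mlen = locus_motif_length[locus_id]
        out.loc[mlen, cls] += 1
        if locus_transcribed is not None and locus_transcribed.get(locus_id, False):
            out.loc[mlen, f"{cls}_transcribed"] += 1
    return out


def chi2_exclusive_bias(e_re: int, e_rf: int) -> tuple[float, float]:
    """One-df goodness-of-fit of the exclusive-locus split against 50/50."""
    total = e_re + e_rf
    if total <= 0:
        raise ValueError("no exclusive loci to test")
    expected = total / 2
    stat = (e_re - expected) ** 2 / expected + (e_rf - expected) ** 2 / expected
    return float(stat), float(stats.chi2.sf(stat, df=1))
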