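"""Linking SSR loci to nearby genes and testing SSR-expression association.

A locus is linked to a gene when it overlaps the gene body or lies within
2 kbp (inclusive) of the gene span. For each link, samples are split by
SSR presence/absence and the gene's counts are compared between the two
groups with the shared-dispersion negative-binomial LRT (size factors as
offsets), followed by Benjamini-Hochberg adjustment over all testable
links. Term overrepresentation of SSR-proximal genes uses a one-sided
hypergeometric (Fisher) test against a background gene set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pitanga.expression_stats import bh_adjust, nb_lrt_two_group, size_factors
from pitanga.io_formats import GenomicInterval
from pitanga.ssr_landscape import SSRLocus


@dataclass
class GeneSSRLink:
    gene_id: str
    locus_id: str
    distance_bp: int  # 0 when overlapping
    side: str  # upstream | downstream | within


@dataclass
class SSRExpressionTest:
    locus_id: str
    gene_id: str
    n_present: int
    n_absent: int
    stat: float = float("nan")
    df: int = 1
    p: float = float("nan")
    q: float = float("nan")
    testable: bool = True
    reason: str = ""


def link_ssrs_to_genes(loci: list[SSRLocus],
                       genes: dict[str, GenomicInterval],
                       link_window_bp: int = 2000) -> list[GeneSSRLink]:
    """Link each locus to every gene it overlaps or flanks within
    ``link_window_bp`` (inclusive boundary, measured between spans).

    Side is relative to the gene's strand: a locus before the gene start of
    a + strand gene (or past the end of a - strand gene) is upstream.
    """
    links = []
    for gene_id, gene_iv in sorted(genes.items()):
        for locus in loci:
            iv = locus.interval
            if iv.seq_id != gene_iv.seq_id:
                continue
            if iv.overlaps(gene_iv):
                links.append(GeneSSRLink(gene_id, locus.locus_id, 0, "within"))
                continue
            gap = iv.gap_to(gene_iv)
            if gap is None or gap > link_window_bp:
                continue
            before_gene = iv.end <= gene_iv.start
            if gene_iv.strand == "-":
                side = "downstream" if before_gene else "upstream"
            else:
                side = "upstream" if before_gene else "downstream"
            links.append(GeneSSRLink(gene_id, locus.locus_id, gap, side))
    return links


def group_by_presence(presence: dict[str, bool],
                      samples: list[str]) -> tuple[list[str], list[str]]:
    """Split samples into (present, absent) by per-sample SSR presence calls.

    Every sample must carry a call; the two groups partition the sample set.
    """
    missing = [s for s in samples if s not in presence]
    if missing:
        raise ValueError(f"no presence call for sample(s): {missing}")
    present = [s for s in samples if presence[s]]
    absent = [s for s in samples if not presence[s]]
    return present, absent


def lrt_ssr_expression(locus_id: str, gene_id: str, gene_counts: pd.Series,
                       present: list[str], absent: list[str],
                       offsets: pd.Series | None = None) -> SSRExpressionTest:
    """NB LRT of a gene's counts between SSR-present and SSR-absent samples
    (shared dispersion, df = 1, size-factor offsets)."""
    test = SSRExpressionTest(locus_id, gene_id, len(present), len(absent))
    if len(present) < 2 or len(absent) < 2:
        test.testable = False
        test.reason = (
            f"group too small (present={len(present)}, absent={len(absent)})"
        )
        return test
    samples = present + absent
    counts = gene_counts[samples].to_numpy(dtype=float)
    labels = np.array([1] * len(present) + [0] * len(absent))
    off = None if offsets is None else offsets[samples].to_numpy(dtype=float)
    stat, df, p = nb_lrt_two_group(counts, labels, shared_dispersion=True,
                                   offsets=off)
    test.stat, test.df, test.p = stat, df, p
    return test


def run_all_ssr_tests(links: list[GeneSSRLink], counts: pd.DataFrame,
                      presence_calls: dict[str, dict[str, bool]]
                      ) -> list[SSRExpressionTest]:
    """Run the per-link SSR-expression LRT for every link, BH-adjusting the
    p-values over exactly the testable set.

    ``presence_calls`` maps locus_id -> {sample: present}. Untestable links
    (a group below 2 samples, or no presence table for the locus) are
    returned with ``testable=False`` and a reason.
    """
    sf = size_factors(counts)
    samples = list(counts.columns)
    results: list[SSRExpressionTest] = []
    for link in links:
        calls = presence_calls.get(link.locus_id)
        if calls is None:
            results.append(SSRExpressionTest(
                link.locus_id, link.gene_id, 0, 0, testable=False,
                reason="no presence calls for locus"))
            continue
        present, absent = group_by_presence(calls, samples)
        results.append(lrt_ssr_expression(
            link.locus_id, link.gene_id, counts.loc[link.gene_id],
            present, absent, offsets=sf))
    testable = [r for r in results if r.testable]
    if testable:
        qvals = bh_adjust([r.p for r in testable])
        for r, q in zip(testable, qvals):
            r.q = float(q)
    return results


@dataclass
class EnrichmentResult:
    term: str
    study_hits: int
    study_size: int
    background_hits: int
    background_size: int
    p: float
    q: float
    log2_fold_enrichment: float


def fisher_overrepresentation(study: set[str], background: set[str],
                              term_map: dict[str, set[str]]
                              ) -> list[EnrichmentResult]:
    """One-sided hypergeometric overrepresentation test per term.

    P(X >= study_hits) drawing ``study_size`` genes from a background with
    ``background_hits`` term-annotated genes. Terms with zero study hits
    are reported at p = 1 with a -inf log2 fold enrichment sentinel. BH
    adjustment spans all tested terms.
    """
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    n_bg = len(background)
    n_study = len(study)
    terms = sorted({t for g in background for t in term_map.get(g, ())})
    results = []
    for term in terms:
        annotated = {g for g in background if term in term_map.get(g, ())}
        k_bg = len(annotated)
        k_study = len(annotated & study)
        if k_study == 0:
            p = 1.0
            lfc = -math.inf
        else:
            p = float(stats.hypergeom.sf(k_study - 1, n_bg, k_bg, n_study))
            study_frac = k_study / n_study
            bg_frac = k_bg / n_bg
            lfc = math.log2(study_frac / bg_frac)
        results.append(EnrichmentResult(term, k_study, n_study, k_bg, n_bg,
                                        min(p, 1.0), 1.0, lfc))
    qvals = bh_adjust([r.p for r in results]) if results else []
    for r, q in zip(results, qvals):
        r.q = float(q)
    return results
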