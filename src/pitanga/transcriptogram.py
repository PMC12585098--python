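"""Transcriptogram profiling over a protein-association gene ordering.

Genes sharing at least one high-confidence association (combined score
> 800 on the STRING 0-1000 scale) are arranged on a line so that
positional distance reflects association likelihood; the arrangement is
found by simulated annealing on the total edge positional distance.
Expression projected onto the ordering and averaged in sliding windows
(radius 30, i.e. 61 genes at interior positions) gives a smoothed profile;
case-vs-control comparisons per position yield peaks of coherently
responding gene neighborhoods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

logger = logging.getLogger("pitanga")


def filter_graph(edges: list[tuple[str, str, int]],
                 score_threshold: int = 800) -> nx.Graph:
    """Keep edges with combined score strictly above the threshold; nodes
    without any retained edge drop out of the ordering universe."""
    g = nx.Graph()
    for a, b, score in edges:
        if a != b and score > score_threshold:
            g.add_edge(a, b, score=score)
    return g


def arrangement_cost(graph: nx.Graph, position: dict[str, int]) -> int:
    """Total edge positional distance of a linear arrangement."""
    return sum(abs(position[u] - position[v]) for u, v in graph.edges)


def build_ordering(graph: nx.Graph, seed: int = 0,
                   n_iterations: int = 200,
                   cooling: float = 0.995) -> list[str]:
    """Linear gene arrangement minimizing total edge distance by simulated
    annealing.

    Starts from the identity (sorted gene id) order; proposes pairwise
    position swaps; geometric cooling from T0 = cost/N by ``cooling`` per
    sweep of N proposals; stops after ``n_iterations`` sweeps without
    improvement of the best cost. Fixed seed gives a reproducible ordering,
    and the returned (best-seen) arrangement never costs more than the
    identity arrangement.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes)
    n = len(nodes)
    pos = {g: i for i, g in enumerate(nodes)}
    order = list(nodes)
    adj = {g: list(graph.neighbors(g)) for g in nodes}

    cost = arrangement_cost(graph, pos)
    best_cost = cost
    best_order = list(order)
    if n == 1 or graph.number_of_edges() == 0:
        return best_order

    temp = max(cost / n, 1e-9)
    sweeps_since_improvement = 0
    while sweeps_since_improvement < n_iterations and temp > 1e-6:
        improved = False
        for _ in range(n):
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            u, v = order[i], order[j]
            delta = 0
            for nb in adj[u]:
                if nb != v:
                    delta += abs(j - pos[nb]) - abs(i - pos[nb])
            for nb in adj[v]:
                if nb != u:
                    delta += abs(i - pos[nb]) - abs(j - pos[nb])
            if delta <= 0 or rng.random() < math.exp(-delta / temp):
                order[i], order[j] = v, u
                pos[u], pos[v] = j, i
                cost += delta
                if cost < best_cost:
                    best_cost = cost
                    best_order = list(order)
                    improved = True
        temp *= cooling
        sweeps_since_improvement = 0 if improved else sweeps_since_improvement + 1
    return best_order


def project(ordering: list[str], expression: dict[str, float] | np.ndarray,
            radius: int = 30) -> np.ndarray:
    """Windowed mean of an expression vector along the ordering.

    Position i averages positions max(0, i-radius)..min(N-1, i+radius);
    interior windows cover exactly 2*radius + 1 genes; edge windows are
    truncated, not wrapped. Genes missing from the expression mapping are
    imputed as 0 with a warning.
    """
    n = len(ordering)
    if radius >= n:
        raise ValueError(f"radius {radius} >= ordering length {n}")
    if isinstance(expression, dict):
        missing = [g for g in ordering if g not in expression]
        if missing:
            logger.warning("project: %d gene(s) missing expression, imputed 0",
                           len(missing))
        vec = np.array([expression.get(g, 0.0) for g in ordering], dtype=float)
    else:
        vec = np.asarray(expression, dtype=float)
        if vec.size != n:
            raise ValueError("expression vector length != ordering length")
    csum = np.concatenate([[0.0], np.cumsum(vec)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - radius)
    hi = np.minimum(n - 1, idx + radius) + 1
    return (csum[hi] - csum[lo]) / (hi - lo)


def window_sizes(n: int, radius: int) -> np.ndarray:
    """Number of genes in each position's window."""
    idx = np.arange(n)
    return (np.minimum(n - 1, idx + radius) - np.maximum(0, idx - radius) + 1)


def relative_profile(case_profiles: np.ndarray, control_profiles: np.ndarray,
                     pseudo_count: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Per-position relative expression, control as baseline.

    ``case_profiles``/``control_profiles`` are (replicates x positions)
    windowed profiles. Returns (ratio, band): ratio of case to control
    replicate means (pseudo-count on both), and a +-1 SD band across the
    case replicates' individual ratios to the control mean.
    """
    case = np.atleast_2d(np.asarray(case_profiles, float))
    ctrl = np.atleast_2d(np.asarray(control_profiles, float))
    if case.shape[0] < 2 or ctrl.shape[0] < 2:
        raise ValueError("need >=2 replicates per condition")
    ctrl_mean = ctrl.mean(axis=0)
    ratio = (case.mean(axis=0) + pseudo_count) / (ctrl_mean + pseudo_count)
    rep_ratios = (case + pseudo_count) / (ctrl_mean + pseudo_count)
    band = rep_ratios.std(axis=0, ddof=1)
    return ratio, band


def window_test(case_values: np.ndarray, control_values: np.ndarray) -> float:
    """Welch two-sample t-test on per-replicate (windowed) values at one
    position; returns the two-sided p-value. Zero variance in both groups
    with equal means gives p = 1."""
    case = np.asarray(case_values, float)
    ctrl = np.asarray(control_values, float)
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("need >=2 replicates per condition")
    if case.std() == 0.0 and ctrl.std() == 0.0:
        return 1.0 if case.mean() == ctrl.mean() else 0.0
    p = stats.ttest_ind(case, ctrl, equal_var=False).pvalue
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def profile_tests(case_profiles: np.ndarray,
                  control_profiles: np.ndarray) -> np.ndarray:
    """Vectorized Welch test per position over replicate profiles."""
    case = np.atleast_2d(np.asarray(case_profiles, float))
    ctrl = np.atleast_2d(np.asarray(control_profiles, float))
    res = stats.ttest_ind(case, ctrl, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    flat = (case.std(axis=0) == 0) & (ctrl.std(axis=0) == 0)
    p[flat] = np.where(case.mean(axis=0)[flat] == ctrl.mean(axis=0)[flat], 1.0, 0.0)
    p = np.nan_to_num(p, nan=1.0)
    return np.clip(p, np.finfo(float).tiny, 1.0)


@dataclass
class Peak:
    """Maximal run of consecutive positions with p below threshold."""

    start: int
    end: int  # half-open
    min_p: float
    genes: list[str]


def call_peaks(p_profile: np.ndarray, threshold: float,
               ordering: list[str] | None = None) -> list[Peak]:
    """Maximal runs of consecutive positions with p < threshold, one peak
    per run."""
    p = np.asarray(p_profile, float)
    below = p < threshold
    peaks = []
    i = 0
    n = p.size
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        genes = list(ordering[i:j]) if ordering is not None else []
        peaks.append(Peak(i, j, float(p[i:j].min()), genes))
        i = j
    return peaks


def go_density(ordering: list[str], term_map: dict[str, set[str]], term: str,
               window: int = 61) -> np.ndarray:
    """Fraction of each window's genes annotated with ``term``.

    ``window`` is the full interior window width (2*radius + 1). Unknown
    terms give an all-zero profile with a warning; unmapped genes count as
    unannotated.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd (2*radius + 1)")
    known = set().union(*term_map.values()) if term_map else set()
    if term not in known:
        logger.warning("go_density: term %r annotates no gene", term)
    member = np.array(
        [1.0 if term in term_map.get(g, ()) else 0.0 for g in ordering]
    )
    return project(ordering, member, radius=window // 2)


def select_candidate_degs(ordering: list[str], p_r30: np.ndarray,
                          p_r0: np.ndarray, gene_p: dict[str, float],
                          p_r30_threshold: float = 0.01,
                          p_r0_threshold: float = 0.05,
                          p_gene_threshold: float = 0.05) -> list[str]:
    """Combined selection: a gene qualifies when its position's windowed
    p (radius 30) < 0.01, its unsmoothed position p (radius 0) < 0.05, and
    its per-gene DE test p < 0.05. Genes absent from the ordering are
    excluded with a warning."""
    missing = [g for g in gene_p if g not in set(ordering)]
    if missing:
        logger.warning("select_candidate_degs: %d gene(s) not in ordering",
                       len(missing))
    selected = []
    for i, gene in enumerate(ordering):
        if gene not in gene_p:
            continue
        if (p_r30[i] < p_r30_threshold and p_r0[i] < p_r0_threshold
                and gene_p[gene] < p_gene_threshold):
            selected.append(gene)
    return selected
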