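"""Perfect-microsatellite (SSR) detection and genomic landscape summaries.

Detection follows the MISA convention: a simple SSR is a maximal perfect
tandem run of a primitive 1-6 bp motif meeting a per-length minimum repeat
number (defaults 10/6/5/5/5/5); runs are broken at ambiguity (N) bases;
two or more SSRs separated by at most a fixed interruption distance are
additionally reported as one compound record. Motifs are collapsed to
canonical strand/phase-invariant classes labelled "X/Y" (e.g. AG/CT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from scipy import stats

from pitanga.io_formats import GenomicInterval, PipelineConfig

logger = logging.getLogger("pitanga")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True if the motif is not a whole-number power of a shorter string."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_class(motif: str) -> str:
    """Canonical "X/Y" class label of a motif.

    X is the lexicographically smallest string among all cyclic rotations of
    the motif and of its reverse complement; Y is the smallest rotation of
    reverse_complement(X). The label is invariant under rotation and reverse
    complementation and idempotent under re-canonicalization.
    """
    if not motif or len(motif) > 6 or set(motif) - set("ACGT"):
        raise ValueError(f"invalid motif {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")

    def rotations(s: str) -> list[str]:
        return [s[i:] + s[:i] for i in range(len(s))]

    rc = reverse_complement(motif)
    x = min(rotations(motif) + rotations(rc))
    y = min(rotations(reverse_complement(x)))
    return f"{x}/{y}"


@dataclass(frozen=True)
class SSRRecord:
    """A detected perfect microsatellite (simple or compound)."""

    interval: GenomicInterval
    motif: str
    n_repeats: int
    is_compound: bool = False
    members: tuple["SSRRecord", ...] = ()

    def __post_init__(self) -> None:
        if not self.is_compound:
            if len(self.interval) != len(self.motif) * self.n_repeats:
                raise ValueError(
                    f"interval length {len(self.interval)} != "
                    f"{len(self.motif)} x {self.n_repeats}"
                )

    @property
    def motif_class(self) -> str:
        return canonical_class(self.motif)


@dataclass
class SSRLocus:
    """One or more same-motif SSRs within the merge window, as one locus."""

    locus_id: str
    members: list[SSRRecord]
    interval: GenomicInterval
    motif: str
    motif_class: str
    transcribed: bool = False

    @property
    def n_repeats(self) -> int:
        return max(m.n_repeats for m in self.members)


def detect_ssrs(seq_id: str, sequence: str,
                config: PipelineConfig | None = None) -> list[SSRRecord]:
    """Detect every maximal perfect tandem repeat of a primitive 1-6 bp motif.

    A run is reported once, assigned to its (shortest) primitive motif;
    partial trailing units are truncated, so interval length is always
    motif length x repeat number. N never matches, so runs break at
    ambiguity bases. Compound records (inter-SSR gap <= the configured
    interruption) are appended after the simple records.
    """
    config = config or PipelineConfig()
    n = len(sequence)
    simple: list[SSRRecord] = []
    for k in range(1, 7):
        min_rep = config.ssr_min_repeats[k]
        if n < k * min_rep:
            continue
        j = 0
        limit = n - k
        while j < limit:
            a, b = sequence[j], sequence[j + k]
            if a != b or a == "N":
                j += 1
                continue
            # maximal run of period-k matches starting at j
            run_start = j
            while j < limit and sequence[j] == sequence[j + k] != "N":
                j += 1
            span = j - run_start + k  # length of the tandem region
            repeats = span // k
            motif = sequence[run_start:run_start + k]
            if repeats >= min_rep and is_primitive(motif):
                end = run_start + k * repeats
                simple.append(SSRRecord(
                    GenomicInterval(seq_id, run_start, end),
                    motif, repeats,
                ))
    simple.sort(key=lambda r: (r.interval.start, r.interval.end, r.motif))

    compounds: list[SSRRecord] = []
    group: list[SSRRecord] = []
    group_end = -1
    for rec in simple:
        if group and rec.interval.start - group_end \
                <= config.compound_max_interruption_bp:
            group.append(rec)
            group_end = max(group_end, rec.interval.end)
        else:
            if len(group) >= 2:
                compounds.append(_make_compound(group))
            group = [rec]
            group_end = rec.interval.end
    if len(group) >= 2:
        compounds.append(_make_compound(group))
    return simple + compounds


def _make_compound(members: list[SSRRecord]) -> SSRRecord:
    iv = GenomicInterval(
        members[0].interval.seq_id,
        members[0].interval.start,
        max(m.interval.end for m in members),
    )
    return SSRRecord(iv, members[0].motif, sum(m.n_repeats for m in members),
                     is_compound=True, members=tuple(members))


def detect_ssrs_bruteforce(seq_id: str, sequence: str,
                           config: PipelineConfig | None = None) -> list[SSRRecord]:
    """Quadratic reference scanner for simple SSRs (validation only).

    Tries every (start, motif length) pair independently and keeps maximal
    runs; intended for sequences of at most a few kb.
    """
    config = config or PipelineConfig()
    n = len(sequence)
    out = []
    for k in range(1, 7):
        min_rep = config.ssr_min_repeats[k]
        for start in range(0, n - k + 1):
            motif = sequence[start:start + k]
            if "N" in motif or not is_primitive(motif):
                continue
            # left-maximal: the unit before must not continue the run
            if start >= 1 and sequence[start - 1] == sequence[start - 1 + k] != "N":
                continue
            reps = 1
            while sequence[start + reps * k: start + (reps + 1) * k] == motif:
                reps += 1
            if reps >= min_rep:
                out.append(SSRRecord(
                    GenomicInterval(seq_id, start, start + reps * k), motif, reps))
    out.sort(key=lambda r: (r.interval.start, r.interval.end, r.motif))
    return out


def merge_loci(records: list[SSRRecord], merge_window_bp: int = 100,
               locus_prefix: str = "SSR") -> list[SSRLocus]:
    """Single-linkage merge of same-sequence, identical-motif simple SSRs
    whose gap is at most ``merge_window_bp`` into loci.

    Compound records are ignored (their members are merged individually if
    supplied). Input order does not matter; records are sorted internally.
    """
    simple = [r for r in records if not r.is_compound]
    key = lambda r: (r.interval.seq_id, r.interval.start, r.interval.end, r.motif)
    if simple != sorted(simple, key=key):
        logger.warning("merge_loci: input not sorted; sorting internally")
        simple = sorted(simple, key=key)

    chains: dict[tuple[str, str], list[list[SSRRecord]]] = {}
    for rec in simple:
        k = (rec.interval.seq_id, rec.motif)
        groups = chains.setdefault(k, [])
        if groups and rec.interval.start - groups[-1][-1].interval.end <= merge_window_bp:
            groups[-1].append(rec)
        else:
            groups.append([rec])

    loci = []
    ordered = sorted(
        (g for groups in chains.values() for g in groups),
        key=lambda g: (g[0].interval.seq_id, g[0].interval.start, g[0].motif),
    )
    for i, group in enumerate(ordered, 1):
        iv = GenomicInterval(
            group[0].interval.seq_id,
            group[0].interval.start,
            max(m.interval.end for m in group),
        )
        loci.append(SSRLocus(
            locus_id=f"{locus_prefix}{i:06d}",
            members=group,
            interval=iv,
            motif=group[0].motif,
            motif_class=canonical_class(group[0].motif),
        ))
    return loci


def classify_transcribed(loci: list[SSRLocus],
                         transcript_intervals: list[GenomicInterval]) -> list[SSRLocus]:
    """Flag loci whose interval overlaps at least one transcript interval.

    Half-open semantics: touching intervals do not overlap.
    """
    by_seq: dict[str, list[GenomicInterval]] = {}
    for iv in transcript_intervals:
        by_seq.setdefault(iv.seq_id, []).append(iv)
    out = []
    for locus in loci:
        hit = any(locus.interval.overlaps(t)
                  for t in by_seq.get(locus.interval.seq_id, ()))
        out.append(replace_locus(locus, transcribed=hit))
    return out


def replace_locus(locus: SSRLocus, **changes) -> SSRLocus:
    data = dict(
        locus_id=locus.locus_id, members=locus.members, interval=locus.interval,
        motif=locus.motif, motif_class=locus.motif_class,
        transcribed=locus.transcribed,
    )
    data.update(changes)
    return SSRLocus(**data)


@dataclass
class LandscapeSummary:
    """Genome-wide SSR tallies in the layout of an identification-metrics table."""

    total_ssrs: int
    n_compound: int
    counts_by_motif_length: dict[int, int]
    counts_by_class: dict[str, tuple[int, int]]  # class -> (transcribed, untranscribed)
    density_per_mb: float
    n_sequences_with_ssr: int
    n_sequences_with_multiple: int
    include_monomers: bool = False


def landscape_summary(records: list[SSRRecord], loci: list[SSRLocus],
                      genome_size_bp: int,
                      include_monomers: bool = False) -> LandscapeSummary:
    """Tally the SSR landscape: per-length and per-class counts, compound
    count, density in units per Mb.

    Monomeric (single-base) simple repeats are excluded from all totals
    unless ``include_monomers``; SSRs absorbed into a compound record are
    counted once via the compound tally, not per length. Density is
    total / (genome size / 1e6), rounded to 2 decimals.
    """
    if genome_size_bp <= 0:
        raise ValueError("genome_size_bp must be positive")

    compounds = [r for r in records if r.is_compound]
    in_compound = {id(m) for c in compounds for m in c.members}
    countable = [
        r for r in records
        if not r.is_compound and id(r) not in in_compound
        and (include_monomers or len(r.motif) > 1)
    ]
    counted_compounds = [
        c for c in compounds
        if include_monomers or any(len(m.motif) > 1 for m in c.members)
    ]

    by_len: dict[int, int] = {k: 0 for k in range(1, 7)}
    for r in countable:
        by_len[len(r.motif)] += 1
    if not include_monomers:
        by_len.pop(1)

    by_class: dict[str, list[int]] = {}
    for locus in loci:
        if not include_monomers and len(locus.motif) == 1:
            continue
        pair = by_class.setdefault(locus.motif_class, [0, 0])
        pair[0 if locus.transcribed else 1] += 1

    total = len(countable) + len(counted_compounds)
    seqs: dict[str, int] = {}
    for r in countable:
        seqs[r.interval.seq_id] = seqs.get(r.interval.seq_id, 0) + 1
    for c in counted_compounds:
        seqs[c.interval.seq_id] = seqs.get(c.interval.seq_id, 0) + 1

    return LandscapeSummary(
        total_ssrs=total,
        n_compound=len(counted_compounds),
        counts_by_motif_length=by_len,
        counts_by_class={k: (v[0], v[1]) for k, v in sorted(by_class.items())},
        density_per_mb=round(total / (genome_size_bp / 1e6), 2),
        n_sequences_with_ssr=len(seqs),
        n_sequences_with_multiple=sum(1 for v in seqs.values() if v > 1),
        include_monomers=include_monomers,
    )


def density_per_mb(total_ssrs: int, genome_size_bp: int) -> float:
    """SSR density in units per Mb, rounded to 2 decimals."""
    if genome_size_bp <= 0:
        raise ValueError("genome_size_bp must be positive")
    return round(total_ssrs / (genome_size_bp / 1e6), 2)


@dataclass
class ClassBiasTest:
    """Chi-square deviation of one class's transcribed/untranscribed split
    from its motif-length division's overall split."""

    motif_class: str
    transcribed: int
    untranscribed: int
    representation: float
    tested: bool
    stat: float = float("nan")
    df: int = 1
    p: float = float("nan")
    significant: bool = False


def chi2_class_bias(counts_by_class: dict[str, tuple[int, int]],
                    min_class_representation: float = 0.005,
                    alpha: float = 0.01) -> list[ClassBiasTest]:
    """Per-class goodness-of-fit chi-square against the division-wide
    transcribed/untranscribed proportions.

    Classes are grouped into motif-length divisions (by label length);
    within each division the pooled transcribed fraction gives the expected
    split for every class. Classes at or below the representation floor
    (fraction of the division total) are excluded from testing and reported
    with ``tested=False``. One degree of freedom, no continuity correction.
    """
    divisions: dict[int, list[tuple[str, int, int]]] = {}
    for label, (t, u) in counts_by_class.items():
        motif_len = len(label.split("/")[0])
        divisions.setdefault(motif_len, []).append((label, t, u))

    results = []
    for motif_len, rows in sorted(divisions.items()):
        div_t = sum(t for _, t, _ in rows)
        div_u = sum(u for _, _, u in rows)
        div_total = div_t + div_u
        if div_total == 0:
            raise ValueError(f"division of motif length {motif_len} has zero total")
        frac_t = div_t / div_total
        for label, t, u in sorted(rows):
            total = t + u
            rep = total / div_total
            if rep <= min_class_representation:
                results.append(ClassBiasTest(label, t, u, rep, tested=False))
                continue
            expected = [total * frac_t, total * (1 - frac_t)]
            if 0 in expected:
                # degenerate division: every locus on one side; no deviation possible
                results.append(ClassBiasTest(label, t, u, rep, tested=True,
                                             stat=0.0, p=1.0))
                continue
            stat = sum((o - e) ** 2 / e for o, e in zip((t, u), expected))
            p = float(stats.chi2.sf(stat, df=1))
            results.append(ClassBiasTest(label, t, u, rep, tested=True,
                                         stat=stat, p=p,
                                         significant=p < alpha))
    return results
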